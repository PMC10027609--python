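"""End-to-end BSR-seq pipeline: simulate → ΔSNP statistic → region calls.

Also houses the replicate harness used to measure how reliably the
window statistic recovers the two causal loci under the study design
(384 F2 plants, pools of 19 necrotic / 89 healthy, mean depth 150).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import bsa, simdata

__all__ = [
    "stage_seed",
    "BsrRunResult",
    "run_bsr_replicate",
    "evaluate_recovery",
    "recovery_summary",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed by hashing.

    Adding a pipeline stage never perturbs the RNG streams of existing
    stages.  Result is < 2**31.
    """
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class BsrRunResult:
    """All artefacts of one simulated BSR-seq mapping run."""

    gmap: simdata.GenomeMap
    cohort: simdata.F2Cohort
    sites: pd.DataFrame
    filter_stats: bsa.FilterStats
    track: pd.DataFrame
    thresholds: bsa.QuantileThresholds
    windows: pd.DataFrame
    regions: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "necromap_version": __version__,
            "seed": self.seed,
            "params": self.params,
            "thresholds": {
                "lower_01": self.thresholds.lower_01,
                "lower_05": self.thresholds.lower_05,
                "upper_95": self.thresholds.upper_95,
                "upper_99": self.thresholds.upper_99,
            },
            "quantile_definition": "linear interpolation",
            "filter": self.filter_stats.__dict__,
            "n_windows": int(len(self.windows)),
            "n_regions": int(len(self.regions)),
        }


def run_bsr_replicate(
    seed: int,
    n_f2: int = 384,
    markers_per_chromosome: int = 2000,
    model: simdata.EpistasisModel | None = None,
    pool_spec: simdata.PoolSpec | None = None,
    min_depth: int = 100,
    min_spacing_bp: int = 100,
    window_snps: int = 100,
    min_proportion: float = 0.5,
) -> BsrRunResult:
    """Simulate one F2 + pooled-sequencing experiment and map the loci."""
    gmap = simdata.default_genome_map(markers_per_chromosome)
    model = model or simdata.EpistasisModel.default()
    pool_spec = pool_spec or simdata.PoolSpec()
    cohort = simdata.simulate_f2(
        gmap, model, n=n_f2, rng=np.random.default_rng(stage_seed(seed, "f2"))
    )
    raw = simdata.simulate_pool_counts(
        cohort, gmap, pool_spec, rng=np.random.default_rng(stage_seed(seed, "pools"))
    )
    sites, stats = bsa.filter_sites(raw, min_depth, min_spacing_bp, return_stats=True)
    track = bsa.allele_frequencies(sites)
    thresholds = bsa.genome_thresholds(track)
    windows = bsa.window_proportions(track, thresholds, window_snps)
    regions = bsa.call_regions(windows, min_proportion)
    params = {
        "n_f2": n_f2,
        "markers_per_chromosome": markers_per_chromosome,
        "necrotic_size": pool_spec.necrotic_size,
        "healthy_size": pool_spec.healthy_size,
        "mean_depth": pool_spec.mean_depth,
        "error_rate": pool_spec.error_rate,
        "min_depth": min_depth,
        "min_spacing_bp": min_spacing_bp,
        "window_snps": window_snps,
        "min_proportion": min_proportion,
    }
    return BsrRunResult(
        gmap, cohort, sites, stats, track, thresholds, windows, regions, seed, params
    )


def evaluate_recovery(result: BsrRunResult, min_proportion: float = 0.5) -> dict:
    """Did the two top regions hit Chr2/Chr7 and contain the causal loci?

    Also reports whether any *other* chromosome has a window with outlier
    proportion >= ``min_proportion`` (a false-positive signal).
    """
    truth = {
        name: (locus.chromosome, result.gmap.locus_bp(name))
        for name, locus in result.gmap.causal_loci.items()
    }
    causal_chroms = {chrom for chrom, _ in truth.values()}
    top = result.regions.head(2)
    top_chroms = set(top["chrom"])
    contains = {}
    for name, (chrom, bp) in truth.items():
        hit = top[(top["chrom"] == chrom) & (top["start_bp"] <= bp) & (top["end_bp"] >= bp)]
        contains[name] = len(hit) > 0
    off_target = result.windows[
        ~result.windows["chrom"].isin(causal_chroms)
        & (result.windows["prop_05_95"] >= min_proportion)
    ]
    return {
        "top_chromosomes": sorted(top_chroms),
        "top_two_correct": top_chroms == causal_chroms,
        "contains_causal": contains,
        "n_off_target_windows": int(len(off_target)),
        "success": top_chroms == causal_chroms
        and all(contains.values())
        and len(off_target) == 0,
    }


def recovery_summary(
    base_seed: int, n_replicates: int = 20, **kwargs
) -> dict:
    """Success rate of causal-locus recovery over seeded replicates."""
    outcomes = []
    for i in range(n_replicates):
        try:
            result = run_bsr_replicate(stage_seed(base_seed, f"replicate{i}"), **kwargs)
        except simdata.InsufficientPoolError as exc:
            outcomes.append(
                {
                    "top_chromosomes": [],
                    "top_two_correct": False,
                    "contains_causal": {},
                    "n_off_target_windows": 0,
                    "success": False,
                    "error": str(exc),
                }
            )
            continue
        outcomes.append(evaluate_recovery(result))
    n_success = sum(o["success"] for o in outcomes)
    return {
        "n_replicates": n_replicates,
        "n_success": n_success,
        "success_rate": n_success / n_replicates,
        "n_top_two_correct": sum(o["top_two_correct"] for o in outcomes),
        "n_with_off_target_windows": sum(o["n_off_target_windows"] > 0 for o in outcomes),
        "outcomes": outcomes,
    }
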
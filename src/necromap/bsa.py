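"""Bulked-segregant ΔSNP mapping statistic.

Given per-site allele depths for a necrotic and a healthy pool, this
module implements the BSR-seq mapping procedure: depth/spacing filtering,
per-pool alternate-allele frequencies and their difference (ΔSNP,
necrotic − healthy), genome-wide empirical quantile thresholds, the
proportion of threshold-exceeding SNPs in 100-SNP stepping windows, and
candidate-region calling from runs of high-proportion windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantileThresholds",
    "FilterStats",
    "filter_sites",
    "allele_frequencies",
    "genome_thresholds",
    "window_proportions",
    "call_regions",
]

SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "necrotic_ref",
    "necrotic_alt",
    "healthy_ref",
    "healthy_alt",
]

_SNP_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class FilterStats:
    """Sites dropped by each rule of :func:`filter_sites`."""

    n_input: int
    n_non_snp: int
    n_low_depth: int
    n_spacing: int
    n_kept: int


@dataclass(frozen=True)
class QuantileThresholds:
    """Genome-wide ΔSNP quantiles used as outlier thresholds."""

    lower_01: float
    lower_05: float
    upper_95: float
    upper_99: float

    def __post_init__(self) -> None:
        if not (self.lower_01 <= self.lower_05 <= self.upper_95 <= self.upper_99):
            raise ValueError("quantile thresholds must be ordered")

    def pair(self, which: str) -> tuple[float, float]:
        if which == "05_95":
            return self.lower_05, self.upper_95
        if which == "01_99":
            return self.lower_01, self.upper_99
        raise ValueError(f"unknown threshold pair {which!r}")


def _check_sorted(sites: pd.DataFrame) -> None:
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"sites not sorted / not unique within chromosome {chrom}")


def filter_sites(
    sites: pd.DataFrame,
    min_depth: int = 100,
    min_spacing_bp: int = 100,
    return_stats: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, FilterStats]:
    """Retain biallelic SNPs deep enough in *each* pool and spaced apart.

    A site passes if ref and alt are single A/C/G/T bases, the summed
    allele depth is >= ``min_depth`` in both pools, and (greedily, in
    coordinate order) it lies >= ``min_spacing_bp`` from the last kept
    site on the same chromosome.  Idempotent.
    """
    sites = sites.reset_index(drop=True)
    _check_sorted(sites)
    n_input = len(sites)
    if n_input == 0:
        empty = sites.iloc[0:0]
        return (empty, FilterStats(0, 0, 0, 0, 0)) if return_stats else empty

    is_snp = sites["ref"].isin(_SNP_ALLELES) & sites["alt"].isin(_SNP_ALLELES)
    n_non_snp = int((~is_snp).sum())
    sites = sites[is_snp]

    depth_ok = (
        (sites["necrotic_ref"] + sites["necrotic_alt"] >= min_depth)
        & (sites["healthy_ref"] + sites["healthy_alt"] >= min_depth)
    )
    n_low_depth = int((~depth_ok).sum())
    sites = sites[depth_ok]

    keep = np.ones(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    last_chrom, last_pos = None, None
    for i in range(len(sites)):
        if chroms[i] != last_chrom or pos[i] - last_pos >= min_spacing_bp:
            last_chrom, last_pos = chroms[i], pos[i]
        else:
            keep[i] = False
    n_spacing = int((~keep).sum())
    out = sites[keep].reset_index(drop=True)
    stats = FilterStats(n_input, n_non_snp, n_low_depth, n_spacing, len(out))
    return (out, stats) if return_stats else out


def allele_frequencies(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-pool alternate-allele frequencies and ΔSNP (necrotic − healthy).

    Positive delta = excess of the non-reference (*P. exserta*) allele in
    the necrotic pool.
    """
    nec_depth = (sites["necrotic_ref"] + sites["necrotic_alt"]).to_numpy(float)
    hea_depth = (sites["healthy_ref"] + sites["healthy_alt"]).to_numpy(float)
    if np.any(nec_depth == 0) or np.any(hea_depth == 0):
        raise ValueError("zero total depth at a site; run filter_sites first")
    track = sites[["chrom", "pos"]].copy()
    track["af_necrotic"] = sites["necrotic_alt"].to_numpy(float) / nec_depth
    track["af_healthy"] = sites["healthy_alt"].to_numpy(float) / hea_depth
    track["delta"] = track["af_necrotic"] - track["af_healthy"]
    return track


def genome_thresholds(track: pd.DataFrame) -> QuantileThresholds:
    """Empirical 0.01/0.05/0.95/0.99 quantiles of ΔSNP, pooled genome-wide.

    Uses the linear-interpolation definition of the empirical quantile.
    """
    delta = track["delta"].to_numpy(float)
    if delta.size < 2:
        raise ValueError("need at least 2 sites for genome-wide thresholds")
    q = np.quantile(delta, [0.01, 0.05, 0.95, 0.99], method="linear")
    return QuantileThresholds(*q)


def _window_bounds(n: int, window_snps: int) -> list[tuple[int, int]]:
    """Blocks of ``window_snps`` SNPs; trailing block kept if >= half a
    window, merged into the previous block otherwise (or kept standalone
    when it is the only block, so every SNP belongs to exactly one window)."""
    if n == 0:
        return []
    bounds = [(s, min(s + window_snps, n)) for s in range(0, n, window_snps)]
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < window_snps / 2:
        s, _ = bounds.pop()
        bounds[-1] = (bounds[-1][0], n)
    return bounds


def window_proportions(
    track: pd.DataFrame,
    thresholds: QuantileThresholds,
    window_snps: int = 100,
) -> pd.DataFrame:
    """Outlier proportions in stepping (non-overlapping) SNP windows.

    Windows are consecutive blocks of ``window_snps`` SNPs per chromosome,
    never spanning a chromosome boundary.  A SNP is an outlier for a
    threshold pair iff its delta lies *strictly* outside the pair.  Returns
    one row per window with counts and proportions for both pairs
    (0.05/0.95 and 0.01/0.99).
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    _check_sorted(track)
    lo5, up5 = thresholds.pair("05_95")
    lo1, up1 = thresholds.pair("01_99")
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        delta = grp["delta"].to_numpy(float)
        pos = grp["pos"].to_numpy()
        out5 = (delta < lo5) | (delta > up5)
        out1 = (delta < lo1) | (delta > up1)
        for s, e in _window_bounds(delta.size, window_snps):
            n = e - s
            k5 = int(out5[s:e].sum())
            k1 = int(out1[s:e].sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e - 1]),
                    "n_snps": n,
                    "n_out_05_95": k5,
                    "prop_05_95": k5 / n,
                    "n_out_01_99": k1,
                    "prop_01_99": k1 / n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "n_snps",
            "n_out_05_95", "prop_05_95", "n_out_01_99", "prop_01_99",
        ],
    )


def call_regions(
    windows: pd.DataFrame,
    min_proportion: float = 0.5,
    threshold_pair: str = "05_95",
) -> pd.DataFrame:
    """Merge maximal runs of adjacent high-proportion windows into regions.

    Adjacency is within a chromosome only.  Returns one row per region:
    chrom, start_bp, end_bp, n_windows, n_snps, peak_proportion; sorted by
    peak proportion (then SNP count) descending.
    """
    col = f"prop_{threshold_pair}"
    if col not in windows.columns:
        raise ValueError(f"unknown threshold pair {threshold_pair!r}")
    regions = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        hot = (grp[col] >= min_proportion).to_numpy()
        i = 0
        while i < len(grp):
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and hot[j + 1]:
                j += 1
            block = grp.iloc[i : j + 1]
            regions.append(
                {
                    "chrom": chrom,
                    "start_bp": int(block["start_bp"].iloc[0]),
                    "end_bp": int(block["end_bp"].iloc[-1]),
                    "n_windows": len(block),
                    "n_snps": int(block["n_snps"].sum()),
                    "peak_proportion": float(block[col].max()),
                }
            )
            i = j + 1
    out = pd.DataFrame(
        regions,
        columns=["chrom", "start_bp", "end_bp", "n_windows", "n_snps", "peak_proportion"],
    )
    return out.sort_values(
        ["peak_proportion", "n_snps"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
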
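"""Independent brute-force oracles and tiny map builders used by the tests.

Everything here is deliberately naive (per-record loops, closed forms)
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from necromap.simdata import CausalLocus, Chromosome, GenomeMap


def tiny_map(marker_cm, length_cm=None, length_bp=None, name="Chr1", causal=()):
    """Single-chromosome genome map from explicit marker cM positions."""
    marker_cm = list(marker_cm)
    length_cm = max(marker_cm, default=0.0) if length_cm is None else length_cm
    length_bp = length_bp or max(1_000_000, 1000 * (len(marker_cm) + 1))
    pos_bp = np.arange(1, len(marker_cm) + 1) * (length_bp // (len(marker_cm) + 1))
    chrom = Chromosome(name, length_bp, length_cm, pos_bp, np.array(marker_cm, dtype=float))
    loci = {n: CausalLocus(n, name, cm) for n, cm in causal}
    return GenomeMap((chrom,), loci)


def two_locus_map(hne2_cm=25.0, hne7_cm=25.0, markers_per_chrom=5):
    """Two small chromosomes carrying HNe2 and HNe7 for F2 simulations."""
    chroms = []
    for name, total_cm in (("Chr2", 50.0), ("Chr7", 50.0)):
        pos_bp = np.arange(1, markers_per_chrom + 1) * 100_000
        pos_cm = np.linspace(0, total_cm, markers_per_chrom + 2)[1:-1]
        chroms.append(Chromosome(name, (markers_per_chrom + 1) * 100_000, total_cm, pos_bp, pos_cm))
    loci = {
        "HNe2": CausalLocus("HNe2", "Chr2", hne2_cm),
        "HNe7": CausalLocus("HNe7", "Chr7", hne7_cm),
    }
    return GenomeMap(tuple(chroms), loci)


# ---------------------------------------------------------------------------
# Brute-force re-implementation of the mapping statistic


def bf_filter(records, min_depth=100, min_spacing=100):
    """records: list of dicts with the site-table keys."""
    kept = []
    last = {}
    for rec in records:
        if len(rec["ref"]) != 1 or len(rec["alt"]) != 1:
            continue
        if rec["ref"] not in "ACGT" or rec["alt"] not in "ACGT":
            continue
        if rec["necrotic_ref"] + rec["necrotic_alt"] < min_depth:
            continue
        if rec["healthy_ref"] + rec["healthy_alt"] < min_depth:
            continue
        c = rec["chrom"]
        if c in last and rec["pos"] - last[c] < min_spacing:
            continue
        last[c] = rec["pos"]
        kept.append(rec)
    return kept


def bf_delta(rec):
    af_n = rec["necrotic_alt"] / (rec["necrotic_ref"] + rec["necrotic_alt"])
    af_h = rec["healthy_alt"] / (rec["healthy_ref"] + rec["healthy_alt"])
    return af_n - af_h


def bf_quantile(values, q):
    """Linear-interpolation empirical quantile, written out longhand."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def bf_window_blocks(n, window):
    blocks = []
    start = 0
    while start < n:
        blocks.append((start, min(start + window, n)))
        start += window
    if len(blocks) > 1 and blocks[-1][1] - blocks[-1][0] < window / 2:
        s, e = blocks.pop()
        blocks[-1] = (blocks[-1][0], e)
    return blocks


def bf_window_proportions(records, lower, upper, window=100):
    """Per-SNP outlier flags then block averaging; one entry per window."""
    by_chrom = {}
    for rec in records:
        by_chrom.setdefault(rec["chrom"], []).append(rec)
    out = []
    for chrom, recs in by_chrom.items():
        flags = [1 if (bf_delta(r) < lower or bf_delta(r) > upper) else 0 for r in recs]
        for s, e in bf_window_blocks(len(recs), window):
            out.append(
                {
                    "chrom": chrom,
                    "n_snps": e - s,
                    "n_out": sum(flags[s:e]),
                    "prop": sum(flags[s:e]) / (e - s),
                }
            )
    return out


def enumerate_score_distribution(model):
    """Exact F2 score distribution by summing the 3x3 genotype table."""
    weights = {"AA": 0.25, "AE": 0.5, "EE": 0.25}
    dist = {s: 0.0 for s in range(5)}
    for g2, w2 in weights.items():
        for g7, w7 in weights.items():
            for score, p in model.distribution(g2, g7).items():
                dist[score] += w2 * w7 * p
    return dist
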
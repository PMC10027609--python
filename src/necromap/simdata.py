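"""Synthetic data generators for a two-locus hybrid-necrosis mapping study.

This module emulates the statistical structure of an interspecific
*Petunia axillaris* x *P. exserta* F2 experiment: a 7-chromosome genome map,
interference-free (Haldane) meiosis, a two-locus epistatic necrosis model
with the incompatibility loci *HNe2* (chromosome 2) and *HNe7*
(chromosome 7), bulked-pool allele-depth tables for BSR-seq, and synthetic
leaf photographs with a known yellow-area fraction.

Allele coding: genotypes count **A** (*P. axillaris*, reference) alleles,
so 2 = homozygous axillaris (AA), 1 = heterozygous (AE), 0 = homozygous
exserta (EE).  The alternate allele in pooled read counts is the *P.
exserta* allele, matching variant calls made against the *P. axillaris*
reference genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

__all__ = [
    "Chromosome",
    "CausalLocus",
    "GenomeMap",
    "EpistasisModel",
    "F2Cohort",
    "PoolSpec",
    "SyntheticLeafImage",
    "InsufficientPoolError",
    "default_genome_map",
    "haldane_r",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_f2",
    "simulate_pool_counts",
    "generate_leaf_image",
]

GENOTYPE_LABELS = {2: "AA", 1: "AE", 0: "EE"}
SCORES = (0, 1, 2, 3, 4)


class InsufficientPoolError(ValueError):
    """Raised when a cohort cannot supply the requested pool size."""


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance ``d_cm`` (Haldane).

    r = (1 - exp(-2 d / 100)) / 2; no crossover interference.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# Genome map


@dataclass(frozen=True)
class CausalLocus:
    name: str
    chromosome: str
    position_cm: float


@dataclass(frozen=True)
class Chromosome:
    """One chromosome with ordered marker positions (bp and cM).

    ``map_anchors`` is an optional piecewise-linear bp<->cM relation as
    (bp, cM) anchor pairs; when omitted, the map is linear end to end.
    Anchors allow regions of suppressed recombination (many Mb compressed
    into few cM), as around both incompatibility loci in the study system.
    """

    name: str
    length_bp: int
    length_cm: float
    marker_pos_bp: np.ndarray
    marker_pos_cm: np.ndarray
    map_anchors: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        bp = np.asarray(self.marker_pos_bp, dtype=np.int64)
        cm = np.asarray(self.marker_pos_cm, dtype=float)
        object.__setattr__(self, "marker_pos_bp", bp)
        object.__setattr__(self, "marker_pos_cm", cm)
        if bp.shape != cm.shape:
            raise ValueError(f"{self.name}: bp/cM marker arrays differ in length")
        if bp.size and (np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0)):
            raise ValueError(
                f"{self.name}: marker positions must be strictly increasing in bp "
                "and non-decreasing in cM"
            )
        if cm.size and (cm[0] < 0 or cm[-1] > self.length_cm):
            raise ValueError(f"{self.name}: genetic positions outside [0, {self.length_cm}] cM")
        if self.map_anchors is not None:
            anchors = tuple((int(b), float(c)) for b, c in self.map_anchors)
            ab = np.array([a[0] for a in anchors])
            ac = np.array([a[1] for a in anchors])
            if np.any(np.diff(ab) <= 0) or np.any(np.diff(ac) <= 0):
                raise ValueError(f"{self.name}: map anchors must be strictly increasing")
            object.__setattr__(self, "map_anchors", anchors)

    @property
    def n_markers(self) -> int:
        return int(self.marker_pos_bp.size)

    def _anchor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.map_anchors is None:
            return (
                np.array([0, self.length_bp], dtype=float),
                np.array([0.0, self.length_cm]),
            )
        anchors = np.asarray(self.map_anchors, dtype=float)
        return anchors[:, 0], anchors[:, 1]

    def bp_to_cm(self, bp) -> np.ndarray | float:
        ab, ac = self._anchor_arrays()
        return np.interp(bp, ab, ac)

    def cm_to_bp(self, cm: float) -> int:
        """Invert the (monotone piecewise-linear) cM->bp map."""
        if self.length_cm == 0:
            return self.length_bp // 2
        ab, ac = self._anchor_arrays()
        return int(round(float(np.interp(cm, ac, ab))))


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome layout, marker grid and the two causal incompatibility loci."""

    chromosomes: tuple[Chromosome, ...]
    causal_loci: Mapping[str, CausalLocus]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "causal_loci", dict(self.causal_loci))
        names = {c.name for c in self.chromosomes}
        for locus in self.causal_loci.values():
            if locus.chromosome not in names:
                raise ValueError(f"causal locus {locus.name} on unknown chromosome {locus.chromosome}")
            chrom = self.chromosome(locus.chromosome)
            if not 0 <= locus.position_cm <= chrom.length_cm:
                raise ValueError(f"causal locus {locus.name} outside its chromosome map")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def locus_bp(self, name: str) -> int:
        locus = self.causal_loci[name]
        return self.chromosome(locus.chromosome).cm_to_bp(locus.position_cm)

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    def marker_index(self) -> pd.DataFrame:
        """One row per marker: chrom, id, pos_bp, pos_cm."""
        frames = []
        for c in self.chromosomes:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "marker_id": [f"{c.name}_m{i:05d}" for i in range(c.n_markers)],
                        "pos_bp": c.marker_pos_bp,
                        "pos_cm": c.marker_pos_cm,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


#: physical (Mb) and genetic (cM) chromosome sizes of the default map --
#: a ~1.2-Gb solanaceous-scale genome with a ~565 cM linkage map.
_DEFAULT_LENGTHS_MB = (190, 180, 165, 155, 145, 135, 125)
_DEFAULT_LENGTHS_CM = (100.0, 90.0, 85.0, 80.0, 75.0, 70.0, 65.0)

#: recombination-suppressed blocks around the incompatibility loci: both
#: sit in large low-recombination regions (the chromosome-2 supergene and
#: a comparable block on chromosome 7), compressing tens of Mb into ~3 cM.
_DEFAULT_MAP_ANCHORS = {
    "Chr2": ((0, 0.0), (70_000_000, 44.0), (110_000_000, 47.0), (180_000_000, 90.0)),
    "Chr7": ((0, 0.0), (40_000_000, 34.0), (80_000_000, 37.0), (125_000_000, 65.0)),
}


def default_genome_map(
    markers_per_chromosome: int = 2000,
    hne2_cm: float = 45.5,
    hne7_cm: float = 35.5,
) -> GenomeMap:
    """Seven-chromosome map with evenly spaced markers and HNe2/HNe7.

    Markers are uniform in bp; the bp<->cM relation is linear except on
    Chr2 and Chr7, where a recombination-suppressed block surrounds the
    causal locus (see ``_DEFAULT_MAP_ANCHORS``).  *HNe2* sits on Chr2 and
    *HNe7* on Chr7, inside their low-recombination blocks.
    """
    chromosomes = []
    for i, (mb, cm) in enumerate(zip(_DEFAULT_LENGTHS_MB, _DEFAULT_LENGTHS_CM), start=1):
        name = f"Chr{i}"
        length_bp = mb * 1_000_000
        anchors = _DEFAULT_MAP_ANCHORS.get(name)
        pos_bp = np.linspace(0, length_bp, markers_per_chromosome + 2, dtype=np.int64)[1:-1]
        if anchors is None:
            pos_cm = pos_bp / length_bp * cm
        else:
            ab = np.array([a[0] for a in anchors], dtype=float)
            ac = np.array([a[1] for a in anchors], dtype=float)
            pos_cm = np.interp(pos_bp, ab, ac)
        chromosomes.append(Chromosome(name, length_bp, cm, pos_bp, pos_cm, anchors))
    loci = {
        "HNe2": CausalLocus("HNe2", "Chr2", hne2_cm),
        "HNe7": CausalLocus("HNe7", "Chr7", hne7_cm),
    }
    return GenomeMap(tuple(chromosomes), loci)


# ---------------------------------------------------------------------------
# Epistasis model


@dataclass(frozen=True)
class EpistasisModel:
    """Necrosis-score distributions for each (HNe2, HNe7) genotype pair.

    ``score_table`` maps (genotype at HNe2, genotype at HNe7) -- labels in
    {"AA", "AE", "EE"} -- to a distribution over scores 0..4.  The default
    model triggers symptoms only when HNe2 carries at least one axillaris
    (A) allele *and* HNe7 is homozygous exserta (EE); the heterozygous-HNe2
    class is semi-dominant, i.e. strictly milder in expectation.
    """

    score_table: Mapping[tuple[str, str], Mapping[int, float]]

    def __post_init__(self) -> None:
        table = {}
        for g2 in ("AA", "AE", "EE"):
            for g7 in ("AA", "AE", "EE"):
                dist = dict(self.score_table.get((g2, g7), {0: 1.0}))
                if any(s not in SCORES for s in dist):
                    raise ValueError(f"invalid score in distribution for ({g2},{g7})")
                total = sum(dist.values())
                if not np.isclose(total, 1.0):
                    raise ValueError(f"distribution for ({g2},{g7}) sums to {total}, not 1")
                table[(g2, g7)] = dist
        object.__setattr__(self, "score_table", table)

    def distribution(self, g2: str, g7: str) -> dict[int, float]:
        return dict(self.score_table[(g2, g7)])

    def expected_score(self, g2: str, g7: str) -> float:
        return sum(s * p for s, p in self.score_table[(g2, g7)].items())

    def sample_scores(self, g2: np.ndarray, g7: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one score per individual from the class distributions."""
        scores = np.zeros(g2.shape, dtype=np.int8)
        for (l2, l7), dist in self.score_table.items():
            sel = (g2 == {"EE": 0, "AE": 1, "AA": 2}[l2]) & (g7 == {"EE": 0, "AE": 1, "AA": 2}[l7])
            k = int(sel.sum())
            if k == 0:
                continue
            vals = np.array(sorted(dist), dtype=np.int8)
            probs = np.array([dist[v] for v in sorted(dist)])
            scores[sel] = rng.choice(vals, size=k, p=probs / probs.sum())
        return scores

    @classmethod
    def default(cls) -> "EpistasisModel":
        """Dominant A at HNe2 x recessive E at HNe7; semi-dominant HNe2.

        Heterozygous-HNe2 plants are mostly scored 1-3 (milder, expected
        score 2.45) with a 10% chance of the severe class, reflecting
        variable expressivity of the semi-dominant genotype.
        """
        return cls(
            {
                ("AA", "EE"): {4: 1.0},
                ("AE", "EE"): {1: 0.15, 2: 0.35, 3: 0.40, 4: 0.10},
            }
        )

    @classmethod
    def l7_dominant(cls) -> "EpistasisModel":
        """Alternative model: one exserta allele at HNe7 suffices."""
        het = {1: 0.15, 2: 0.35, 3: 0.40, 4: 0.10}
        return cls(
            {
                ("AA", "EE"): {4: 1.0},
                ("AA", "AE"): {4: 1.0},
                ("AE", "EE"): dict(het),
                ("AE", "AE"): dict(het),
            }
        )

    @classmethod
    def single_locus_dominant(cls) -> "EpistasisModel":
        """Score 4 whenever HNe2 carries >=1 A allele, regardless of HNe7."""
        return cls({("AA", g7): {4: 1.0} for g7 in ("AA", "AE", "EE")}
                   | {("AE", g7): {4: 1.0} for g7 in ("AA", "AE", "EE")})

    @classmethod
    def null(cls) -> "EpistasisModel":
        return cls({})


# ---------------------------------------------------------------------------
# Meiosis


def _chromosome_positions(gmap: GenomeMap) -> list[tuple[Chromosome, np.ndarray, dict[str, int]]]:
    """Per chromosome: combined sorted cM positions (markers + causal loci)
    and the column index of each causal locus within that array."""
    out = []
    for chrom in gmap.chromosomes:
        cm = chrom.marker_pos_cm
        causal = {n: l.position_cm for n, l in gmap.causal_loci.items() if l.chromosome == chrom.name}
        if causal:
            combined = np.concatenate([cm, np.fromiter(causal.values(), dtype=float)])
            order = np.argsort(combined, kind="stable")
            combined = combined[order]
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            idx = {name: int(inv[cm.size + j]) for j, name in enumerate(causal)}
        else:
            combined, idx = cm, {}
        out.append((chrom, combined, idx))
    return out


def simulate_gametes(gmap: GenomeMap, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate ``n`` F1 gametes; returns per-chromosome (n, n_positions) arrays.

    Positions are the sorted union of markers and causal loci (see
    :func:`_chromosome_positions`).  Entry 1 means the A (*P. axillaris*)
    allele was transmitted.  Crossovers follow a Poisson process on the
    genetic map (Haldane: disjoint intervals recombine independently with
    r = (1 - e^(-2d/100))/2), so two positions d cM apart recombine with
    exactly that probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = {}
    for chrom, cm, _ in _chromosome_positions(gmap):
        if cm.size == 0:
            out[chrom.name] = np.zeros((n, 0), dtype=np.int8)
            continue
        r = haldane_r(np.diff(cm))
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        switches = (rng.random((n, r.size)) < r).astype(np.int8)
        state = np.concatenate([start, switches], axis=1).cumsum(axis=1) % 2
        out[chrom.name] = state.astype(np.int8)  # 1 = A allele
    return out


def simulate_gamete(gmap: GenomeMap, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One gamete: per-chromosome haplotype vectors (1 = A allele)."""
    return {k: v[0] for k, v in simulate_gametes(gmap, 1, rng).items()}


# ---------------------------------------------------------------------------
# F2 cohort


@dataclass
class F2Cohort:
    """Simulated F2 individuals: marker genotypes, causal genotypes, scores.

    ``genotypes`` is (n_individuals, n_markers) with entries 0/1/2 counting
    A alleles, columns ordered as ``marker_index`` rows.
    """

    genotypes: np.ndarray
    g_hne2: np.ndarray
    g_hne7: np.ndarray
    scores: np.ndarray
    marker_index: pd.DataFrame
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotypes must be in {0,1,2}")
        if not np.isin(self.scores, SCORES).all():
            raise ValueError("scores must be in 0..4")

    @property
    def n(self) -> int:
        return int(self.genotypes.shape[0])

    def individuals_with_scores(self, scores: Iterable[int]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.scores, list(scores)))

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per individual, genotype columns per marker."""
        df = pd.DataFrame(
            self.genotypes, columns=self.marker_index["marker_id"].to_numpy()
        )
        df.insert(0, "individual", [f"F2_{i:04d}" for i in range(self.n)])
        df.insert(1, "g_HNe2", [GENOTYPE_LABELS[g] for g in self.g_hne2])
        df.insert(2, "g_HNe7", [GENOTYPE_LABELS[g] for g in self.g_hne7])
        df.insert(3, "score", self.scores)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_f2(
    gmap: GenomeMap,
    model: EpistasisModel,
    n: int = 384,
    rng: np.random.Generator | int | None = None,
) -> F2Cohort:
    """Simulate an F2 cohort of ``n`` plants and score their necrosis.

    Each individual is the union of two independent F1 gametes; the
    necrosis score (0 healthy .. 4 severe) is drawn from the epistasis
    model at the individual's (HNe2, HNe7) genotype.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    per_chrom = _chromosome_positions(gmap)
    gam1 = simulate_gametes(gmap, n, rng)
    gam2 = simulate_gametes(gmap, n, rng)

    marker_blocks, g2 = [], None
    g7 = None
    for chrom, cm, causal_idx in per_chrom:
        geno = gam1[chrom.name] + gam2[chrom.name]
        for name, col in causal_idx.items():
            if name == "HNe2":
                g2 = geno[:, col].copy()
            elif name == "HNe7":
                g7 = geno[:, col].copy()
        marker_cols = np.setdiff1d(np.arange(cm.size), list(causal_idx.values()))
        marker_blocks.append(geno[:, marker_cols])
    if g2 is None or g7 is None:
        raise ValueError("genome map must define causal loci HNe2 and HNe7")
    genotypes = np.concatenate(marker_blocks, axis=1)
    scores = model.sample_scores(g2, g7, rng)
    return F2Cohort(genotypes, g2, g7, scores, gmap.marker_index(), rng_seed=seed)


# ---------------------------------------------------------------------------
# Pooled read counts


@dataclass(frozen=True)
class PoolSpec:
    """Bulk composition and sequencing model for the two pools."""

    necrotic_scores: frozenset = frozenset({4})
    healthy_scores: frozenset = frozenset({0})
    necrotic_size: int = 19
    healthy_size: int = 89
    mean_depth: float = 150.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.necrotic_size < 1 or self.healthy_size < 1:
            raise ValueError("pool sizes must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")


_BASES = np.array(list("ACGT"))


def simulate_pool_counts(
    cohort: F2Cohort,
    gmap: GenomeMap,
    spec: PoolSpec = PoolSpec(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-site allele depths for the necrotic and healthy bulks.

    For each pool the true alternate (exserta) allele frequency at a marker
    is p = 1 - (sum of A-allele counts)/(2 * pool size) over the pooled
    individuals; observed depth ~ Poisson(mean_depth) and alternate count
    ~ Binomial(depth, p(1-e) + (1-p)e) with symmetric miscall rate e.

    Returns a site table with columns chrom, pos, ref, alt,
    necrotic_ref, necrotic_alt, healthy_ref, healthy_alt.
    """
    rng = np.random.default_rng(rng)
    pools = {}
    for pool, scores, size in (
        ("necrotic", spec.necrotic_scores, spec.necrotic_size),
        ("healthy", spec.healthy_scores, spec.healthy_size),
    ):
        candidates = cohort.individuals_with_scores(scores)
        if candidates.size < size:
            raise InsufficientPoolError(
                f"{pool} pool needs {size} individuals with scores {sorted(scores)}, "
                f"cohort has only {candidates.size}"
            )
        pools[pool] = rng.choice(candidates, size=size, replace=False)

    n_sites = cohort.genotypes.shape[1]
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    table = cohort.marker_index[["chrom", "pos_bp"]].rename(columns={"pos_bp": "pos"}).copy()
    table["ref"] = _BASES[ref_idx]
    table["alt"] = _BASES[alt_idx]
    e = spec.error_rate
    for pool, idx in pools.items():
        g = cohort.genotypes[idx]
        p_alt = 1.0 - g.sum(axis=0) / (2.0 * len(idx))
        p_obs = p_alt * (1 - e) + (1 - p_alt) * e
        depth = rng.poisson(spec.mean_depth, size=n_sites)
        alt = rng.binomial(depth, p_obs)
        table[f"{pool}_ref"] = depth - alt
        table[f"{pool}_alt"] = alt
    return table


# ---------------------------------------------------------------------------
# Leaf images


@dataclass
class SyntheticLeafImage:
    """RGB leaf photograph with exact ground-truth pixel counts."""

    pixels: np.ndarray  # uint8 (H, W, 3)
    leaf_pixel_count: int
    yellow_pixel_count: int

    @property
    def yellow_fraction(self) -> float:
        return self.yellow_pixel_count / self.leaf_pixel_count

    def save(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels).save(path)


def generate_leaf_image(
    yellow_fraction: float,
    shape: tuple[int, int] = (240, 320),
    rng: np.random.Generator | int | None = None,
    yellow_hue: float = 50.0,
    green_hue: float = 110.0,
    hue_jitter: float = 8.0,
    background_level: int = 12,
) -> SyntheticLeafImage:
    """Elliptical leaf on a dark background with a contiguous yellow sector.

    Exactly round(yellow_fraction * leaf_pixels) leaf pixels (a contiguous
    left-to-right patch, emulating necrosis spreading from the leaf base)
    get hues in the yellow band; the rest are green.  Hues are jittered by
    +-``hue_jitter`` degrees but clipped to stay inside the conventional
    yellow [35, 65) and green [65, 165) bands.
    """
    if not 0.0 <= yellow_fraction <= 1.0:
        raise ValueError("yellow_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    mask = ((yy - cy) / (0.40 * h)) ** 2 + ((xx - cx) / (0.42 * w)) ** 2 <= 1.0
    leaf_n = int(mask.sum())
    if leaf_n == 0:
        raise ValueError("image too small for a leaf")
    n_yellow = int(round(yellow_fraction * leaf_n))

    # order leaf pixels left-to-right so the yellow patch is contiguous
    ys, xs = np.nonzero(mask)
    order = np.lexsort((ys, xs))
    ys, xs = ys[order], xs[order]

    # hue clip margins (3 deg inside the nominal bands) keep every pixel's
    # band membership stable under 8-bit RGB quantization
    hue = np.empty(leaf_n)
    hue[:n_yellow] = np.clip(yellow_hue + rng.uniform(-hue_jitter, hue_jitter, n_yellow), 38.0, 62.0)
    hue[n_yellow:] = np.clip(
        green_hue + rng.uniform(-hue_jitter, hue_jitter, leaf_n - n_yellow), 68.0, 162.0
    )
    sat = rng.uniform(0.60, 0.90, leaf_n)
    val = rng.uniform(0.50, 0.80, leaf_n)
    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    rgb_leaf = (hsv2rgb(hsv[None, :, :])[0] * 255).round().astype(np.uint8)

    img = rng.integers(0, background_level + 1, size=(h, w, 3)).astype(np.uint8)
    img[ys, xs] = rgb_leaf
    return SyntheticLeafImage(img, leaf_n, n_yellow)
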
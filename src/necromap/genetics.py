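"""Classical-genetics calculations: allele frequencies in wild accessions,
expected F2 segregation under two-locus epistasis, goodness of fit, map
distances, and fine-mapping interval exclusion from recombinant lines."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .simdata import EpistasisModel

__all__ = [
    "GenotypeCounts",
    "AlleleFrequency",
    "RecombinantLine",
    "IntervalResult",
    "InconsistentLinesError",
    "allele_frequency",
    "expected_f2_fractions",
    "segregation_gof",
    "map_distance",
    "fine_map_interval",
]

#: F2 genotype weights at one locus: hom / het / hom = 1:2:1
_F2_WEIGHTS = {"AA": 0.25, "AE": 0.5, "EE": 0.25}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies at a biallelic marker across accessions."""

    n_hom_allele1: int
    n_het: int
    n_hom_allele2: int

    def __post_init__(self) -> None:
        if min(self.n_hom_allele1, self.n_het, self.n_hom_allele2) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_allele1 + self.n_het + self.n_hom_allele2


@dataclass(frozen=True)
class AlleleFrequency:
    """Frequency of allele 1, both as a raw fraction and as the
    integer-rounded percentage used for reporting."""

    fraction: float

    @property
    def percent(self) -> int:
        return int(round(100 * self.fraction))


def allele_frequency(counts: GenotypeCounts) -> AlleleFrequency:
    """Allele-1 frequency: (2·hom1 + het) / (2·total)."""
    if counts.total == 0:
        raise ValueError("no accessions: total count is zero")
    frac = (2 * counts.n_hom_allele1 + counts.n_het) / (2 * counts.total)
    return AlleleFrequency(frac)


def expected_f2_fractions(model: EpistasisModel) -> dict[int, float]:
    """Exact necrosis-score distribution in an idealized F2.

    Enumerates the 3x3 (HNe2, HNe7) genotype table with independent 1:2:1
    weights at each locus (the loci are on different chromosomes) and sums
    the model's score distributions.
    """
    out = {s: 0.0 for s in range(5)}
    for g2, w2 in _F2_WEIGHTS.items():
        for g7, w7 in _F2_WEIGHTS.items():
            for score, p in model.distribution(g2, g7).items():
                out[score] += w2 * w7 * p
    return out


def segregation_gof(
    observed: Sequence[int], expected_fractions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against expected fractions.

    Returns (statistic, df, p_value) with df = classes - 1.
    """
    obs = np.asarray(observed, dtype=float)
    frac = np.asarray(expected_fractions, dtype=float)
    if obs.shape != frac.shape:
        raise ValueError("observed and expected class lists differ in length")
    if not np.isclose(frac.sum(), 1.0):
        raise ValueError("expected fractions must sum to 1")
    if np.any((frac == 0) & (obs > 0)):
        raise ValueError("non-zero observation in a zero-probability class")
    keep = frac > 0
    exp = frac[keep] * obs.sum()
    stat = float(((obs[keep] - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def map_distance(
    recombinant_gametes: int, total_gametes: int, method: str = "direct"
) -> float:
    """Map distance in cM from a recombinant-gamete count.

    ``direct`` returns 100·r (adequate for tight linkage, r < 0.1);
    ``haldane`` returns −50·ln(1 − 2r), undefined for r >= 0.5.
    """
    if total_gametes <= 0:
        raise ValueError("total gametes must be positive")
    if not 0 <= recombinant_gametes <= total_gametes:
        raise ValueError("recombinant count outside [0, total]")
    r = recombinant_gametes / total_gametes
    if method == "direct":
        return 100.0 * r
    if method == "haldane":
        if r >= 0.5:
            raise ValueError("Haldane distance undefined for r >= 0.5")
        return -50.0 * float(np.log(1.0 - 2.0 * r))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Fine mapping from recombinant lines


class InconsistentLinesError(ValueError):
    """No marker position explains every line's phenotype."""


@dataclass(frozen=True)
class RecombinantLine:
    """A recombinant line's genotypes over the mapped region and the
    phenotype of its homozygous progeny.

    Genotypes per marker: ``A`` (hom *P. axillaris*), ``E`` (hom
    *P. exserta*), ``H`` (heterozygous).  Phenotype: ``necrotic`` or
    ``healthy``.
    """

    line_id: str
    genotypes: tuple[str, ...]
    phenotype: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        if any(g not in {"A", "E", "H"} for g in self.genotypes):
            raise ValueError(f"{self.line_id}: genotypes must be A/E/H")
        if self.phenotype not in {"necrotic", "healthy"}:
            raise ValueError(f"{self.line_id}: phenotype must be necrotic/healthy")

    def allowed_markers(self, heterozygous_affected: bool = True) -> np.ndarray:
        """Boolean mask of markers where the causal locus may reside.

        The necrosis-causing allele is the axillaris (A) one, so a necrotic
        line excludes hom-E markers; a healthy line excludes hom-A markers
        and, when heterozygotes are symptom-capable (semi-dominance,
        default), heterozygous markers as well.
        """
        g = np.array(self.genotypes)
        if self.phenotype == "necrotic":
            return g != "E"
        excluded = (g == "A") | (heterozygous_affected & (g == "H"))
        return ~excluded


@dataclass(frozen=True)
class IntervalResult:
    chromosome: str
    lower_marker: str
    upper_marker: str
    lower_bp: int
    upper_bp: int

    @property
    def span_bp(self) -> int:
        return self.upper_bp - self.lower_bp


def fine_map_interval(
    lines: Iterable[RecombinantLine],
    marker_ids: Sequence[str],
    marker_pos_bp: Sequence[int],
    chromosome: str = "Chr2",
    heterozygous_affected: bool = True,
) -> IntervalResult:
    """Intersect per-line exclusion masks to localize the causal locus.

    Markers must be ordered along the region.  Raises
    :class:`InconsistentLinesError` (naming a conflicting pair) if no
    marker survives every line's exclusions.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("need at least one recombinant line")
    n = len(marker_ids)
    if len(marker_pos_bp) != n:
        raise ValueError("marker ids and positions differ in length")
    masks = []
    for line in lines:
        if len(line.genotypes) != n:
            raise ValueError(f"{line.line_id}: genotype vector does not match markers")
        masks.append(line.allowed_markers(heterozygous_affected))
    allowed = np.logical_and.reduce(masks)
    if not allowed.any():
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                if not (masks[i] & masks[j]).any():
                    raise InconsistentLinesError(
                        f"lines {lines[i].line_id} and {lines[j].line_id} exclude "
                        "complementary regions; no position explains both phenotypes"
                    )
        raise InconsistentLinesError("the combined exclusions leave no candidate marker")
    idx = np.flatnonzero(allowed)
    if np.any(np.diff(idx) != 1):
        warnings.warn(
            "surviving candidate markers are not contiguous; reporting their full span",
            stacklevel=2,
        )
    lo, hi = int(idx[0]), int(idx[-1])
    return IntervalResult(
        chromosome,
        marker_ids[lo],
        marker_ids[hi],
        int(marker_pos_bp[lo]),
        int(marker_pos_bp[hi]),
    )
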
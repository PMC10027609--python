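"""In-silico CAPS genotyping at the ChiA1 nonsense-mutation site.

FokI recognizes GGATG and cleaves downstream of the site (9 nt on the
top strand, 13 nt on the bottom).  The G→T nonsense mutation in the
*P. exserta* allele destroys the recognition site (GGATG → GTATG), so a
digested amplicon diagnoses the *P. axillaris* allele and an uncut one
the *P. exserta* allele; heterozygotes show both patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "Amplicon",
    "DigestResult",
    "GenotypeCall",
    "FOKI_MOTIF",
    "find_recognition_sites",
    "digest",
    "classify_genotype",
    "synthetic_diagnostic_alleles",
]

FOKI_MOTIF = "GGATG"
#: FokI cleaves 9 nt (top strand) / 13 nt (bottom strand) 3' of GGATG
DEFAULT_CUT_OFFSET_TOP = 9
DEFAULT_CUT_OFFSET_BOTTOM = 13

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class Amplicon:
    """A strandless PCR product; alphabet A/C/G/T/N (N never matches)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Amplicon":
        return Amplicon(self.id, str(Seq(self.sequence).reverse_complement()))


@dataclass(frozen=True)
class DigestResult:
    """Cut positions (top-strand coordinates = left-fragment lengths) and
    the resulting fragment lengths, which partition the amplicon."""

    amplicon_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.fragment_lengths) != self.amplicon_length:
            raise ValueError("fragments do not partition the amplicon")

    @property
    def is_cut(self) -> bool:
        return len(self.cut_positions) > 0


def find_recognition_sites(
    amplicon: Amplicon, motif: str = FOKI_MOTIF
) -> list[tuple[int, str]]:
    """All motif occurrences on either strand, overlapping ones included.

    Positions are 0-based forward-strand coordinates of the occurrence's
    first base: the motif itself for '+' hits, its reverse complement
    (CATCC for FokI) for '-' hits.
    """
    motif = motif.upper()
    seq = amplicon.sequence
    rc = str(Seq(motif).reverse_complement())
    sites = []
    for pattern, strand in ((motif, "+"), (rc, "-")):
        start = 0
        while True:
            pos = seq.find(pattern, start)
            if pos == -1:
                break
            if "N" not in pattern:
                sites.append((pos, strand))
            start = pos + 1
    return sorted(sites)


def digest(
    amplicon: Amplicon,
    sites: Iterable[tuple[int, str]],
    cut_offset_top: int = DEFAULT_CUT_OFFSET_TOP,
    cut_offset_bottom: int = DEFAULT_CUT_OFFSET_BOTTOM,
) -> DigestResult:
    """Predict restriction fragments from recognition sites.

    For a forward site starting at p the top strand is cut
    ``cut_offset_top`` nt past the motif end (position p + len(motif) +
    offset); reverse-strand sites are mirrored (cut at p −
    ``cut_offset_bottom``).  Cuts falling outside the sequence are dropped
    with a warning.  Fragment lengths always sum to the amplicon length.
    """
    n = len(amplicon)
    motif_len = len(FOKI_MOTIF)
    cuts = set()
    for pos, strand in sites:
        cut = pos + motif_len + cut_offset_top if strand == "+" else pos - cut_offset_bottom
        if 0 < cut < n:
            cuts.add(cut)
        else:
            warnings.warn(
                f"{amplicon.id}: cut at {cut} outside sequence bounds; dropped",
                stacklevel=2,
            )
    ordered = tuple(sorted(cuts))
    edges = (0,) + ordered + (n,)
    fragments = tuple(b - a for a, b in zip(edges, edges[1:]))
    return DigestResult(n, ordered, fragments)


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid call from the two allele digests of one amplicon."""

    genotype: str  # "Ax/Ax", "Ex/Ex" or "Ax/Ex"
    ambiguous: bool = False


def classify_genotype(allele1: DigestResult, allele2: DigestResult) -> GenotypeCall:
    """Call Ax/Ax, Ex/Ex or Ax/Ex from presence of the diagnostic cut.

    The classification keys on whether each allele is cut at all, not on
    the full fragment pattern.  If both alleles are cut but at different
    positions the call is flagged ambiguous for manual review.
    """
    c1, c2 = allele1.is_cut, allele2.is_cut
    if c1 and c2:
        return GenotypeCall("Ax/Ax", ambiguous=allele1.cut_positions != allele2.cut_positions)
    if not c1 and not c2:
        return GenotypeCall("Ex/Ex")
    return GenotypeCall("Ax/Ex")


def genotype_amplicon_pair(
    allele1: Amplicon,
    allele2: Amplicon,
    cut_offset_top: int = DEFAULT_CUT_OFFSET_TOP,
    cut_offset_bottom: int = DEFAULT_CUT_OFFSET_BOTTOM,
) -> GenotypeCall:
    """Convenience wrapper: find sites, digest both alleles, classify."""
    d1 = digest(allele1, find_recognition_sites(allele1), cut_offset_top, cut_offset_bottom)
    d2 = digest(allele2, find_recognition_sites(allele2), cut_offset_top, cut_offset_bottom)
    return classify_genotype(d1, d2)


def synthetic_diagnostic_alleles(
    length: int = 400,
    site_position: int = 150,
    rng: np.random.Generator | int | None = None,
) -> tuple[Amplicon, Amplicon]:
    """Synthetic Ax/Ex amplicon pair differing only at the G→T site.

    The Ax allele carries a single GGATG at ``site_position``; the Ex
    allele has the second base mutated to T (GTATG), destroying the site.
    The random flanks are regenerated until no spurious FokI site exists
    in either allele, so the diagnostic site is the only cut.
    """
    rng = np.random.default_rng(rng)
    if not 0 <= site_position <= length - len(FOKI_MOTIF):
        raise ValueError("site_position does not fit in the amplicon")
    bases = np.array(list("ACGT"))
    while True:
        seq = rng.choice(bases, size=length)
        seq[site_position : site_position + 5] = list(FOKI_MOTIF)
        ax = "".join(seq)
        seq[site_position + 1] = "T"
        ex = "".join(seq)
        ax_amp = Amplicon("Ax", ax)
        ex_amp = Amplicon("Ex", ex)
        ax_sites = find_recognition_sites(ax_amp)
        if ax_sites == [(site_position, "+")] and find_recognition_sites(ex_amp) == []:
            return ax_amp, ex_amp
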
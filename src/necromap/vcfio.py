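"""VCF 4.2 input/output for pooled allele-depth tables.

The pool table (see :mod:`necromap.simdata` / :mod:`necromap.bsa`) is
written as a minimal two-sample VCF with per-sample AD (ref,alt depths)
and DP; reading goes through cyvcf2 and accepts any VCF carrying AD for
the two named pool samples.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .bsa import SITE_COLUMNS

__all__ = ["write_pool_vcf", "read_pool_vcf"]


def write_pool_vcf(
    table: pd.DataFrame,
    path,
    contig_lengths: Mapping[str, int] | None = None,
    samples: Sequence[str] = ("necrotic", "healthy"),
) -> None:
    """Write a pool site table as VCF 4.2 (two samples, AD and DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=necromap {__version__}\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in pd.unique(table["chrom"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for row in table.itertuples(index=False):
            cells = []
            for sample in samples:
                ref_d = getattr(row, f"{sample}_ref")
                alt_d = getattr(row, f"{sample}_alt")
                cells.append(f"{ref_d},{alt_d}:{ref_d + alt_d}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tAD:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_pool_vcf(
    path,
    necrotic_sample: str = "necrotic",
    healthy_sample: str = "healthy",
) -> pd.DataFrame:
    """Read per-pool allele depths (AD) from a VCF into a site table.

    Multi-allelic records keep the first ALT allele's depth; records
    without AD are rejected.
    """
    vcf = VCF(str(path))
    try:
        idx = {}
        for name in (necrotic_sample, healthy_sample):
            if name not in vcf.samples:
                raise ValueError(f"sample {name!r} not in VCF (has {vcf.samples})")
            idx[name] = vcf.samples.index(name)
        rows = []
        for variant in vcf:
            ad = variant.format("AD")
            if ad is None:
                raise ValueError(f"record {variant.CHROM}:{variant.POS} lacks AD")
            ad = np.asarray(ad)
            rows.append(
                {
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "ref": variant.REF,
                    "alt": variant.ALT[0] if variant.ALT else "",
                    "necrotic_ref": int(ad[idx[necrotic_sample], 0]),
                    "necrotic_alt": int(ad[idx[necrotic_sample], 1]),
                    "healthy_ref": int(ad[idx[healthy_sample], 0]),
                    "healthy_alt": int(ad[idx[healthy_sample], 1]),
                }
            )
    finally:
        vcf.close()
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
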
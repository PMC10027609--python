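# necromap

Bulked-segregant mapping of a two-locus hybrid incompatibility.

Hybrid necrosis is a post-zygotic isolation barrier: hybrids between two
healthy parental species develop autoimmune leaf death. In the
*Petunia axillaris* x *P. exserta* system this is caused by deleterious
epistasis between a chromosome-2 locus (*HNe2*, the chitinase gene
*ChiA1*) and a chromosome-7 locus (*HNe7*): plants with at least one
*P. axillaris* allele at *HNe2* and a homozygous *P. exserta* genotype
at *HNe7* become necrotic. `necromap` is a toolkit for the computational
side of mapping such an incompatibility:

- **simdata** — seeded generators for F2 cohorts (Haldane meiosis over a
  7-chromosome genome with recombination-suppressed blocks around the
  causal loci), bulked-pool allele-depth tables (written as VCF), and
  synthetic leaf photographs with known ground truth;
- **bsa** — the BSR-seq ΔSNP statistic: per-pool alternate-allele
  frequencies, δ = af(necrotic) − af(healthy), genome-wide quantile
  thresholds (0.01/0.05/0.95/0.99), outlier proportions in 100-SNP
  stepping windows, candidate-region calling;
- **genetics** — allele frequencies from genotype tallies, exact F2
  segregation under two-locus epistasis, chi-square goodness of fit,
  map distances (direct and Haldane), fine-mapping interval exclusion
  from recombinant lines;
- **leafscore** — leaf yellow-area ratio by hue/saturation/brightness
  thresholding with colour-card calibration;
- **caps** — in-silico FokI CAPS genotyping of the *ChiA1* G→T nonsense
  site;
- **cli** — the `necromap` command binding the stages into seeded,
  reproducible runs with JSON metadata sidecars.

It is aimed at plant geneticists who want to prototype or sanity-check a
bulked-segregant design (how reliably would pools of 19 and 89 plants
localize two epistatic loci?) and at anyone re-implementing the
individual calculations.

## The statistic

For each retained SNP (biallelic, allele depth ≥ 100 in each pool,
≥ 100 bp apart), the ΔSNP value is

    δ = alt_necrotic/(ref+alt)_necrotic − alt_healthy/(ref+alt)_healthy

Against the *P. axillaris* reference, markers linked to *HNe2* go
strongly negative in the necrotic pool and markers linked to *HNe7*
strongly positive. Empirical genome-wide quantiles of δ define outlier
thresholds; the fraction of threshold-exceeding SNPs in non-overlapping
100-SNP windows is the mapping signal, and runs of windows with
proportion ≥ 0.5 become candidate regions.

## Worked example

```
$ necromap pipeline --seed 1 --out run/
chrom  start_bp    end_bp  n_windows  n_snps  peak_proportion
 Chr2  72053973 125937031          6     600             1.00
 Chr7  43790604  87456271          7     700             0.89
```

A seeded end-to-end run — 384 simulated F2 plants, pools of 19 necrotic
and 89 healthy, mean depth 150 — calls exactly two candidate regions.
The Chr2 region (peak proportion 1.00: every SNP in its best window
exceeds the genome-wide thresholds) contains the true *HNe2* position
(90.0 Mb), and the Chr7 region contains the true *HNe7* position
(60.0 Mb); the remaining five chromosomes show no window above 0.5.
`run/windows.tsv` holds the per-window track, `run/regions.tsv` the
calls, and `run/pipeline.meta.json` the seed, parameters and thresholds
needed to regenerate them.

The smaller calculations are one-liners:

```
$ necromap mapdist --recombinants 12 --total 738
{"method": "direct", "r": 0.016260162601626018, "cM": 1.6260162601626018}
```

— twelve recombinant gametes among 738 place *ChiA1* 1.63 cM from the
pollination-syndrome gene *MYB-FL*, and

```
$ necromap freq --counts wild_accessions.csv
```

turns genotype tallies (58 homozygous, 4 heterozygous, 13 opposite
homozygous among 75 wild *P. exserta* accessions) into the 80%
*ChiA1*-Ex allele frequency.

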
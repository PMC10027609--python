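# Methods

`necromap` models and maps a two-locus hybrid incompatibility of the kind
found between *Petunia axillaris* and *P. exserta*: plants carrying at
least one *P. axillaris* allele at a chromosome-2 locus (*HNe2*, the
chitinase gene *ChiA1*) together with a homozygous *P. exserta* genotype
at a chromosome-7 locus (*HNe7*) develop autoimmune leaf necrosis. The
package simulates the mapping experiment end to end, implements the
bulked-segregant statistic that localizes the loci, and provides the
supporting genetics, image-scoring and CAPS-genotyping calculations.

## The genetic model

Genotypes count A (*P. axillaris*) alleles, so `AA` = 2, `AE` = 1,
`EE` = 0. The epistasis model maps each (HNe2, HNe7) genotype pair to a
distribution over necrosis scores 0 (healthy) to 4 (severe). The default
table:

| HNe2 \ HNe7 | AA      | AE      | EE                              |
|-------------|---------|---------|---------------------------------|
| AA          | healthy | healthy | score 4 always                  |
| AE          | healthy | healthy | {1: .15, 2: .35, 3: .40, 4: .10}|
| EE          | healthy | healthy | healthy                         |

Symptoms therefore require ≥1 A allele at HNe2 *and* EE at HNe7; in an
idealized F2 (independent 1:2:1 segregation at both loci) the
symptomatic fraction is exactly 3/4 x 1/4 = 3/16 ≈ 0.19, matching the
roughly one-quarter symptomatic plants seen in real F2s within sampling
error. HNe2 is semi-dominant: heterozygotes are affected but milder
(expected score 2.45 vs 4). The 10% chance of a severe heterozygote
reflects variable expressivity; it also matters statistically — with
fully mild heterozygotes, a 384-plant F2 produces fewer than 19
score-4 plants (the necrotic-pool size) in ~12% of cohorts, while
making half of heterozygotes severe dilutes the necrotic pool's allele
frequency signal at HNe2 from δ ≈ −0.52 to ≈ −0.37 and degrades
mapping. An alternative `l7_dominant` model (one E allele at HNe7
suffices; 9/16 symptomatic) and a single-locus dominant model (3/4) are
provided for comparison.

Dominance at HNe7 cannot be resolved from introgression lines that are
all EE there; the recessive default is the choice closest to the
observed ~one-quarter symptomatic fraction, and the model is fully
configurable.

## The simulated genome

Seven chromosomes totalling ~1.1 Gb and ~565 cM (190→125 Mb,
100→65 cM), a solanaceous-scale genome. Markers (default 2,000 per
chromosome) are evenly spaced in bp. Meiosis is interference-free
(Haldane): crossovers form a Poisson process on the genetic map, so
disjoint intervals recombine independently with
r = (1 − e^(−2d/100))/2 for a distance of d cM. An F2 individual is the
sum of two independent F1 gametes.

The bp↔cM relation is piecewise linear. On Chr2 and Chr7 a 40-Mb block
spanning only 3 cM surrounds the causal locus (HNe2 at 90 Mb / 45.5 cM;
HNe7 at 60 Mb / 35.5 cM), emulating the strong recombination
suppression documented around both loci in the real system (the
chromosome-2 "supergene" that holds the pollination-syndrome genes, and
a large low-recombination region around HNe7). This matters for
mapping: the suppressed block concentrates near-maximal allele-frequency
differences over a contiguous run of markers. Each block holds ~3% of
all simulated SNPs, deliberately below the 5% of sites that one tail of
the genome-wide quantile threshold can flag — if the block exceeded
that budget, the empirical threshold would necessarily fall *inside*
the block's noise band and the signal would fragment. Other chromosomes
use a uniform map; real pericentromeric suppression elsewhere is not
modelled.

## Pooled sequencing model

The necrotic pool draws 19 plants with score 4 and the healthy pool 89
plants with score 0 (a seeded random subset when more qualify; an
explicit error when fewer exist). At each marker the pool's true
alternate-allele (E-allele) frequency is p = 1 − Σg/(2n). Sequencing is
modelled as depth ~ Poisson(150) per site per pool and alternate count
~ Binomial(depth, p(1−e) + (1−p)e) with a symmetric miscall rate
e = 0.001 — the simplest model compatible with a depth-≥100 filtering
regime. Counts are written as a two-sample VCF 4.2 (AD, DP).

What the generator does *not* emulate: expression-level variation in
RNA-seq coverage (depth is homogeneous across genes), allele-specific
expression, mapping bias toward the reference allele, linked paralogs,
and genotyping error in the cohort itself. Passing tests therefore show
the statistic behaves correctly under clean pooled-count sampling, not
that it is robust to RNA-seq artefacts.

## The ΔSNP window statistic

1. **Filter**: keep biallelic SNPs with summed allele depth ≥ 100 in
   *each* pool, then enforce ≥ 100 bp between kept sites greedily in
   coordinate order.
2. **ΔSNP**: per-pool alternate-allele frequency from AD; δ =
   af(necrotic) − af(healthy). With the *P. axillaris* reference,
   positive δ means excess *P. exserta* alleles in the necrotic pool, so
   the expected signature is strongly negative δ at HNe2 and strongly
   positive δ at HNe7.
3. **Thresholds**: empirical genome-wide quantiles of δ at 0.01/0.05
   (lower) and 0.95/0.99 (upper), linear-interpolation definition
   (alternative definitions differ by O(1/n); the choice is recorded in
   run metadata).
4. **Windows**: non-overlapping blocks of 100 consecutive SNPs per
   chromosome ("stepping", not sliding). A trailing block with at least
   half a window of SNPs stands alone; smaller remainders merge into
   the previous window (or stand alone if they are the chromosome's
   only block), so every SNP belongs to exactly one window and the
   SNP-weighted mean of window proportions equals the global outlier
   fraction identically. A SNP is an outlier iff δ is *strictly*
   outside a threshold pair; both pairs are reported per window.
5. **Regions**: maximal runs of adjacent windows with outlier
   proportion ≥ 0.5, merged per chromosome and ranked by peak
   proportion (SNP count breaks ties).

Numerical notes: all-equal δ values yield zero outliers (strict
inequality); the strict-outlier fraction can exceed 0.10 by at most
2/n from interpolation granularity; windows never span chromosome
boundaries, and results are invariant to processing chromosomes
separately (thresholds are computed genome-wide first).

Under the default design the pipeline recovers both loci — top two
regions on Chr2/Chr7 containing the true positions, no hot window
elsewhere — in ~95% of seeded replicates (133/140 over seven disjoint
20-replicate batches). The residual failures are inherent to the
design: ~2% of cohorts yield fewer than 19 score-4 plants, and in ~3%
a random allele-frequency excursion elsewhere on chromosome 2 (driven
by the 19-plant pool's sampling noise, shared across linked markers)
outranks the causal block.

## Genetics calculations

- Allele frequency from genotype tallies: (2·hom + het)/(2·total),
  reported both raw and as the integer-rounded percent used in print.
- Expected F2 score distribution by exact enumeration of the 3x3
  genotype table with (1,2,1)/4 weights per locus (loci unlinked).
- Goodness of fit: Pearson Σ(O−E)²/E with df = classes − 1.
- Map distance: direct (100·r, adequate below r ≈ 0.1, the default) or
  Haldane (−50·ln(1−2r), undefined at r ≥ 0.5). Twelve recombinant
  gametes among 738 (an F2 of 369 plants) give 1.626 ≈ 1.63 cM, the
  ChiA1–MYB-FL linkage.
- Fine mapping by interval exclusion: a necrotic line cannot carry the
  causal A allele where it is homozygous E; a healthy line excludes
  homozygous-A markers and, because heterozygotes are symptomatic under
  semi-dominance (the default; a flag restores the strict reading),
  heterozygous markers as well. The interval is the span of markers
  surviving every line's exclusions; an empty intersection raises an
  error naming a conflicting pair of lines. If the surviving set is
  non-contiguous (possible with inconsistent genotyping) the full span
  is returned with a warning.

## Leaf yellow-area score

Images are converted to hue/saturation/brightness (hexcone model;
achromatic pixels get hue 0, saturation 0). The leaf is the largest
connected component of pixels with brightness ≥ 0.15 (dark-background
photography), hole-filled. Within the leaf, pixels with saturation
≥ 0.25 and brightness ≥ 0.15 are classified by half-open hue bands —
yellow [35°, 65°), green [65°, 165°) — and the severity score is
yellow/leaf pixels. The original analysis's exact cutoffs live in
unpublished macro settings; these defaults are conventional, fully
configurable, and recorded with every output. Cross-session comparisons
are guarded by a colour-card check: a session passes calibration when
the yellow patch's measured area varies by ≤ 5% across photos.

The synthetic leaf generator paints an elliptical leaf with a
contiguous yellow sector of exactly the requested pixel fraction, with
per-pixel hue jitter clipped 3° inside the nominal bands so 8-bit
quantization cannot flip a pixel's band. Recovery error on such images
is essentially zero; real leaves (specular highlights, shadows, hue
gradients at lesion edges) will be harder, so the synthetic MAE bounds
only segmentation/classification correctness, not field accuracy.

## CAPS genotyping

FokI recognizes GGATG and cuts downstream of it: 9 nt on the top
strand and 13 on the bottom (the common shorthand "GGATG(N7)" refers to
the same enzyme; offsets are configurable and only the presence of the
cut matters for genotyping). Site search reports every overlapping
occurrence on both strands (reverse-complement CATCC on the forward
coordinates); N never matches. Fragment lengths always partition the
amplicon; out-of-bounds cuts are dropped with a warning. The G→T
nonsense mutation in *ChiA1*-Ex destroys the site, so the diploid call
is Ax/Ax (both alleles cut), Ex/Ex (neither) or Ax/Ex (one); two cut
alleles with discordant cut positions are flagged for manual review.

## Problem sizes and reproducibility

Defaults mirror the study design: 384 F2 plants, pools of 19/89, mean
depth 150, 14,000 markers, 100-SNP windows; replicate batches use 20
seeds. The synthetic-leaf benchmark uses 200 images of 240x320 px. All
randomness flows through `numpy.random.Generator`; pipeline stages
derive independent streams from the global seed by stable hashing, so
adding a stage never perturbs earlier stages' draws, and fixed seeds
give bit-identical cohorts, count tables and images.

## Known limitations

- Crossover interference is not modelled (Haldane), and the
  recombination landscape outside the two suppressed blocks is uniform.
- The pool model ignores RNA-seq-specific coverage structure (see
  above); depth filtering uses the sum of allele depths, not the raw DP.
- Heterozygote severity probabilities are a modelling choice
  constrained only qualitatively ("milder") by observation.
- Fine mapping assumes full penetrance and error-free marker genotypes.
- No automatic colour-card detection or white-balance correction.
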
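# Methods

## The question

When two inbred mouse strains differ in the expression of a gene, the
difference can be *cis* regulated — caused by DNA polymorphism in the
gene's own regulatory region — or *trans* regulated — caused by
polymorphism elsewhere acting through transcription factors or
metabolites.  `cistrans` implements two complementary estimates:

1. **Cis, from haplotype maps.** If the upstream regulatory haplotype
   differs between the strains for a fraction *b* of all genes, but for a
   larger fraction *o* of the differentially expressed (DE) genes, the
   excess attributes part of the differential expression to the local
   haplotype.
2. **Trans, from congenic lines.** A congenic line carries a small donor
   interval on the host background; in a congenic-versus-control
   comparison every DE gene whose TSS lies outside the interval must be
   trans regulated by it, so the outside fraction estimates the
   trans-regulated share directly.

## Models and procedures

### Haplotype assignment

Within each haplotype block, a strain's alleles are compared with the
reference strain's over the SNPs in the block; missing (`N`) sites are
pairwise-deleted.  From the mismatch proportion *p* the Jukes-Cantor
distance is

    d = -(3/4) ln(1 - (4/3) p),

defined for p < 3/4.  Strains with d below a threshold (default 0.2
substitutions/site) carry the reference haplotype allele.  Degenerate
cases are handled explicitly: a block with no SNPs is "same" (identity by
state — block maps define blocks by observed SNPs, so absence of SNPs is
absence of evidence of divergence); a block where every site is missing is
flagged and excluded; a saturated block (p ≥ 3/4) is "different" with a
warning, since extreme divergence cannot be identity.

A gene's haplotype is anchored to the window upstream of its TSS (default
1 kb, strand-aware: `[tss-w, tss)` on `+`, the mirror-image window on
`-`).  If that window overlaps any block carrying a non-reference allele
the gene is "different" — one divergent regulatory block suffices for a
cis hypothesis.  When the window overlaps no assessable block the gene has
no haplotype data and is excluded from denominators (logged).  The
any-overlap rule is a package decision: block maps do not dictate how a
window spanning several blocks should vote.

### Differential expression: the pplr surrogate

Replicate-level confidence in a log2 ratio is expressed as the
probability of a positive log-ratio (PPLR): under a normal model with
common unknown variance and flat reference prior, the posterior of the
mean difference is a scaled Student-t, so

    PPLR = T_df( (mean_a - mean_b) / se_pooled ),   df = n_a + n_b - 2.

For ranking, `pplr = min(PPLR, 1-PPLR)` in (0, 0.5], behaving like a
one-sided p-value (uniform on (0, 0.5] under the null — verified
empirically in the tests).  This is deliberately a *replicate-level*
statistic: probe-level measurement-error models need probe intensities,
which are outside this package's inputs.  The DE rule is
`|log2 ratio| > 0.5` **and** `pplr < threshold`, both strict, with a
strict (0.005) and a loose (0.05) threshold stratum.

### Percentile scan

Genes are ranked by pplr and split into 100 equal groups (ties broken by
gene id; remainders spread one per group from the lowest-pplr group).
For each group and each SNP threshold s = 1..10 a 2×2 table compares
{≥ s upstream SNPs} vs {0 SNPs} inside vs outside the group, excluding
genes with 1..s-1 SNPs, tested by Pearson χ² (no Yates by default) and
Bonferroni-corrected over the full 100 × 10 family at α = 0.05.

Two validity guards mark a table untestable (never significant): an empty
margin, and a minimum expected cell below 5 (Cochran's rule).  The second
matters: at high s the expected counts fall below 1 and the χ² tail
approximation is meaningless at Bonferroni levels (5×10⁻⁵); without the
guard the null scan shows spurious hits.  With the guard the family-wise
error of the null scan is at the nominal ~5% (measured ~2% over 60 runs).

The SNP-dose relative-risk curve reports, for each n, the relative risk
of being DE (pplr below a cutoff, default the first-three-percentile
boundary 0.0046) for genes with ≥ n upstream SNPs against genes with
none, with the Katz log-normal 95% CI, plus the Pearson r between n and
RR.  Two ambiguities are exposed as flags with these defaults: the
comparator is "0 SNPs" (the scan's explicit contrast) and the outcome
does not additionally require the fold-change cut.

### Attribution

With N_h DE genes having haplotype data, N_hd of them on different
haplotypes, and G_d of E genes on different haplotypes genome-wide, the
attributable cis fraction is the epidemiological attributable fraction

    AF = (o - b) / (1 - b),   o = N_hd/N_h,   b = G_d/E,

the share of DE genes whose differential expression the haplotype
difference accounts for, assuming same-haplotype genes are never cis
regulated through the assessed window (hence an underestimate when
regulatory variants sit outside it).  o = 55% over b = 30% gives
AF ≈ 36%.  The simpler conditional rate N_hd/G_d is also reported
(`conditional_de_rate`) for transparency; it answers "what fraction of
different-haplotype genes are DE", not the attribution question, and the
two agree only degenerately.  Each estimate ships with the
{DE, non-DE} × {different, same} χ² for the excess.

Breadth classes: per single tissue, "any" (DE in ≥1 tissue, the headline
class), and exactly-k-of-T classes where the class value for intermediate
k is the mean over tissue combinations (an at-least-k mode is a flag).
The breadth-enrichment contrast crosses haplotype class with being DE in
all tissues among genes DE in ≥1, by two-sided Fisher test.

### Congenic estimates

Genes are classified inside/outside the introgressed interval by TSS
(half-open interval; a gene straddling the boundary follows its TSS), so
membership is independent of DE calling.  `trans_fraction` = outside/all
among strict DE calls.  The stratum contrast (strict vs loose-only DE
versus membership, two-sided Fisher) tests the signature that interval cis
effects produce tight, low-pplr differences.  Background dependence
intersects the congenic DE genes outside the interval with parental DE
genes in the same tissue; expected overlap under independence and
hypergeometric depletion/enrichment tails are reported.  Residual
non-target donor segments are ignored.

### 2×2 statistics

The two-sided Fisher exact test is implemented directly: hypergeometric
probabilities over the support via cached log-factorials, summing all
tables with probability ≤ observed × (1+1e-7) (the minimum-likelihood
rule; the relative tie tolerance absorbs floating-point noise).  The
direct implementation is ~30× faster than a generic library call, which
the bulk enumeration check exploits; tests verify it against both
scipy and an exact integer-arithmetic enumeration.  χ² and the relative
risk use standard scipy machinery; zero cells in the RR are flagged, not
continuity-corrected.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not microarray chemistry.  Defaults (all config-exposed):

| parameter | default | why |
|---|---|---|
| n_genes / n_tissues / n_replicates | 20000 / 3 / 5 | study scale: three tissues, five pooled replicates per strain |
| frac_diff_haplotype | 0.30 | genome-wide different-haplotype rate between the strains |
| frac_cis_de / frac_trans_de | 0.05 / 0.10 | ~2:1 trans:cis among planted effects |
| cis lfc, noise | N(±1.0, 0.2), sd 0.15 | cis: reproducible, tissue-constant |
| trans lfc, noise, tissue prob | N(±0.8, 0.3) per tissue, sd 0.35, 0.4 | trans: intermittent, noisier, redrawn per tissue |
| null noise | sd 0.25 | between the cis and trans noise levels |
| upstream SNP rate | Poisson(3.0 / 0.05) | diff vs same haplotype; counts correlated with haplotype |
| block backbone | 50 sites, divergence 0.40 / 0.02 | places diff/same blocks clearly either side of the 0.2 JC threshold |
| genome | 5 chromosomes, mean 5 kb spacing (min 3 kb) | keeps per-gene ±1.4 kb blocks disjoint; ~20 Mb chromosomes |
| congenic | chr1 interval ~1000 genes, frac_interval_cis 0.005, 13 targets at lfc 1.0 | ~5 interval cis calls + 13 coordinated targets ⇒ planted trans fraction ~0.7 |

Cis genes are drawn only from the different-haplotype stratum; trans
genes are drawn stratified so their haplotype composition matches the
genome-wide rate (trans regulation is blind to the local haplotype).
Effect signs are balanced; a directional excess is not baked in.  With
background buffering (default), congenic trans targets are drawn from
parental null genes, so congenic-specific trans regulation does not
replicate in the parental comparison.

Each gene owns one haplotype block and backbone divergence is placed at
fixed offsets clear of the upstream window, so upstream SNP counts follow
their Poisson rates exactly.  Features of real data deliberately not
emulated: shared multi-gene blocks, linkage between neighbouring genes,
probe-level intensity artefacts, normalisation effects, library-size or
batch structure, and correlated expression within pathways (congenic
trans targets are coordinated in effect size but statistically
independent otherwise).  A passing recovery test therefore shows the
estimators are consistent under the model's assumptions, not that real
arrays meet those assumptions.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; files keep their native
  1-based (SNP tables, TSS TSVs) or 0-based (BED) conventions.
- JC threshold comparison is strict (d < 0.2 ⇒ same).
- DE thresholds are strict inequalities on both the fold change and pplr.
- Zero pooled variance: PPLR is 0.5 with zero difference, saturates to
  0/1 otherwise.
- Fisher with a zero margin returns p = 1 (one possible table); χ² with a
  zero margin raises (scalar form) or yields NaN (vectorised form).
- Partition ties break by gene id; the remainder goes to the lowest
  groups, so group sizes differ by at most one.
- The undefined RR points (zero cells) are omitted from the dose-response
  correlation.

## Problem sizes used by tests and the acceptance script

Recovery and calibration suites run ten (attribution/trans recovery) and
twenty (null scan) simulations of 20,000 genes — the full study scale —
which completes in a couple of minutes on one CPU thanks to vectorised
generation and assignment.  The exact-enumeration Fisher check covers all
~635,000 tables with total count ≤ 60.

## Known limitations

- The pplr surrogate ignores probe-level measurement error; with few
  replicates it is less sensitive than probe-level models, so absolute DE
  counts are not comparable with probe-level analyses.
- Attribution assumes no cis regulation without an upstream-window
  haplotype difference; distal cis variants deflate the estimate.
- The trans fraction treats every DE call outside the interval as trans:
  false-positive DE calls inflate it slightly (visible as a small upward
  bias in the recovery suite), and interval genes can also be trans
  regulated, deflating it.
- The percentile scan's χ² validity guard (expected ≥ 5) means very
  sparse SNP-count strata are reported untestable rather than tested
  badly.
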
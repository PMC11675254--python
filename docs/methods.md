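# Methods

## Model and procedure

The package tests whether trio-GWAS association signal concentrates in a
biological pathway and whether that concentration survives an independent
replication sample. The unit of analysis is the affected-offspring trio
(child with a diagnosis plus both genotyped parents). Association is
measured by the Transmission Disequilibrium Test: conditioning on parental
genotypes, a heterozygous parent transmits either allele with probability
1/2 under the null regardless of population structure, so the TDT is
immune to stratification by construction; the statistic is
(T−U)²/(T+U) ~ χ²₁, where T and U count transmitted and untransmitted
copies of the minor allele over all heterozygous parents at a SNP.

The pathway step is deliberately simple: genes carrying at least one SNP
with p below the listing threshold form the query list, and each gene set
is scored by the upper-tail hypergeometric probability of its overlap with
the query given the array-bound gene universe. The selected (index)
pathway then contributes *every* genotyped SNP in its genes — not only the
sub-threshold ones — to two confirmatory statistics:

- **prevalence**: the fraction of pathway SNPs significant at a nominal
  level in the replication sample, whose expectation under no enrichment
  is the level itself (independent SNPs, uniform p-values); reported with
  the relative excess 100·(prev − level)/level;
- **exceedance**: the fraction of random SNP sets — matched to the
  pathway's size and functional-class composition and drawn from the
  non-pathway SNPs of the same sample — with at least as many significant
  SNPs as the pathway. This is a permutation p-value analogue that
  inherits the realized p-value distribution of the sample, so per-SNP
  miscalibration (e.g. χ² discreteness at modest trio counts) cancels.

The decision rule is one-sided: only an excess of significant SNPs is
evidence, so the two-sided 0.05/0.01 levels are halved to 0.025/0.005
thresholds on the exceedance fractions, both of which must be cleared
(H1); the pathway "replicates" iff both samples accept H1.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.05 | founder minor-allele-frequency floor |
| `geno_min` | 0.95 | per-SNP call-rate floor (all individuals) |
| `hwe_p_min` | 1e-5 | founder HWE exact-test floor |
| `vif_window/step/threshold` | 50 / 5 / 2 | LD pruning (VIF = 1/(1−R²)) |
| `p_threshold` | 0.001 | SNP p-value for gene listing |
| `alpha` | 0.05 | BH-adjusted enrichment cut for the index pathway |
| `alpha_05`, `alpha_01` | 0.025, 0.005 | one-sided exceedance thresholds |
| `n_perm` | 10⁶ (pipeline default 2000) | permutation draws |
| `tau` | 0.6 (generator) | risk-allele transmission probability at causal SNPs |

## Numerical choices

- **HWE exact test**: conditional on allele counts, heterozygote-count
  probabilities are computed in log space (gammaln) and summed over
  outcomes no more probable than the observed one (with a 1+1e-12 guard
  against ties lost to rounding). Monomorphic samples return p = 1.
- **Minor allele**: determined per sample from founder frequencies; a
  0.5/0.5 tie goes to the genotype-coded allele. Because direction
  concordance compares minor-allele ORs, a SNP whose frequency straddles
  0.5 across samples can flip polarity and be dropped as discordant; this
  mirrors how per-sample A1 coding behaves in standard tooling.
- **Mendelian errors**: a trio inconsistent at a SNP is masked to missing
  at that SNP (all three members) rather than excluded study-wide; the
  TDT additionally skips inconsistent trios, so it is safe without QC.
- **VIF pruning**: correlations over founders with pairwise-complete
  deletion; windows slide over the surviving SNPs of each chromosome;
  within a window the largest-VIF SNP is removed first (ties: lowest
  index), removal is permanent. VIFs come from the diagonal of the
  inverted correlation matrix, with a per-SNP pseudo-inverse fallback when
  pairwise deletion makes the matrix singular (perfect collinearity ⇒
  infinite VIF).
- **Exceedance sampling**: within a functional class, the number of
  significant SNPs in a uniform without-replacement draw is multivariate
  hypergeometric over the categories (p<0.01, 0.01≤p<0.05, rest), and
  classes are independent, so the per-draw (count₀₅, count₀₁) pair is
  sampled jointly class-by-class and summed. This is distributionally
  identical to materialising each SNP set and counting — verified against
  an exhaustive C(6,2) enumeration — and makes 10⁶ permutations a few
  vectorised draws. `draw_matched_set` still returns explicit SNP sets,
  with a chi-square goodness-of-fit test of draw uniformity.
- **Exceedance uses ≥** (a draw tying the observed count counts against
  the pathway), the conservative reading; with observed count 0 the
  fraction is 1 and the verdict H0.
- **Degenerate inputs**: empty genelist1, no set below alpha, and an empty
  replication selection are explicit, clean outcomes (the pipeline exits
  with status 2 for "no index pathway" rather than erroring).

## The synthetic generator

`simulate_study` emulates what the analysis assumes: founders drawn
binomial(2, MAF) — i.e. exact HWE — at MAFs uniform on [0.05, 0.5];
children built by explicit parental transmissions, with heterozygous
parents transmitting the risk allele with probability τ at causal SNPs
and 1/2 elsewhere; genotypes masked missing at a 2% default rate; SNPs
split contiguously into genes (10 SNPs/gene at defaults) and genes into
sets; functional classes (missense 10%, splice 5%, unannotated 85%)
assigned independently of causality so class-matching is exercised
without confounding. `simulate_pair` reuses the MAFs, classes and causal
assignments on a random subset of the panel with fresh families,
mimicking a replication array that covers only part of the discovery
panel. Defaults (500 trios, 1000 SNPs, τ = 0.6 on half of one 100-SNP
set) give per-SNP noncentrality ≈ (2τ−1)²·(T+U), comfortably detectable —
a deliberate "clear signal" regime for demonstrations; power studies vary
τ explicitly.

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent, except for an engineered-collinearity path used to test
pruning), population stratification, genotyping batch effects, sex
chromosomes, de novo variation, or a liability-threshold disease model.
Passing tests therefore show the machinery is correct and calibrated for
exchangeable SNPs; they do not show robustness to LD-induced correlation
between pathway SNPs, which in real data argues for pruning before the
permutation step (the default pipeline order does exactly that).

## Problem sizes

The repeated-run experiments use desk-scale sizes chosen to keep Monte
Carlo error meaningfully small: null calibration uses 1000 studies of 200
trios × 2000 SNPs with a designated 100-SNP pathway and 2000 permutations
(3 binomial standard errors ≈ ±1.5 points around the nominal 2.5%);
power/monotonicity uses 200 replicates per τ at 200 trios × 1000 SNPs;
the end-to-end replication rate uses 50 seeds at 500 trios per sample.
The observed type-I rate sits slightly below nominal because the
exceedance count is discrete — the attainable tail probability just under
0.025 is accepted, anything at it is not.

## Known limitations

- Gene sets are flat lists; no GO-hierarchy propagation or evidence-code
  filtering.
- No X-chromosome TDT, parent-of-origin effects, sib-TDT or haplotype
  TDT; sex is carried through IO but unused by statistics.
- No sample-level QC (per-individual missingness, heterozygosity) and no
  imputation; proxy-SNP lookup for panel gaps is out of scope.
- Binary plink formats and VCF are not read; text PED/MAP only. The
  PED writer canonicalises heterozygote allele order, so byte-identical
  round-trips hold for writer-produced files.
- Multiplex families are handled per affected offspring (each child with
  two genotyped parents forms a trio), which double-counts parental
  transmissions shared by siblings; with few multiplex families the
  effect on the TDT is negligible.
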
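# Methods

This note documents the models, defaults and numerical choices behind
`paleotwas`, and what the synthetic-data generator does and does not
emulate.

## Synthetic cohorts

Allele-frequency trajectories follow a discrete Wright–Fisher model with
genic (multiplicative) selection: from frequency p, the post-selection
frequency is p' = p(1+s)/(p(1+s)+(1−p)) and the next generation draws
Binomial(2Ne, p')/2Ne. Frequencies 0 and 1 are absorbing. Defaults:
Ne = 10⁴, generation time 28 years, 161 generations (a ~4,500-year
transect). SNPs are mutually independent — there is no linkage
disequilibrium, haplotype structure or mutation; each locus carries one
biallelic SNP with initial frequency drawn U(0.1, 0.9).

Dated cohorts are sampled at scheduled time points (default 154
individuals at each of 4,500/3,000/1,500/500 years BP plus 91 at present,
707 total, mirroring a 616-ancient + 91-modern design). A diploid
genotype at date d is Binomial(2, p) at the matching generation.
Imputation noise is modelled as linear shrinkage of the dosage toward the
population mean: dose = q·genotype + (1−q)·2p, with per-SNP quality
q ~ U(0.6, 1.0) recorded as the SNP's R². This choice reproduces the
qualitative behaviour of genotype imputation on ancient samples — reduced
per-sample variance pulling frequencies toward the reference — with a
magnitude tied directly to the reported R². The joint distribution of
imputation quality across SNPs is a modelling choice (uniform), not an
empirical fit. Dates are exact point values; no radiocarbon-like dating
error is simulated.

Gene models are sparse linear cis-eQTL weight vectors: model size
k ~ Poisson(12) clipped at ≥ 1 (median ~12 SNPs), members are a contiguous
block of SNPs (cis clustering), weights ~ N(0, 0.3) expression-SD per
effect-allele copy. For a planted selected gene with intended direction
d = ±1, each member SNP receives a true selection coefficient
s = 0.02·sign(weight)·d, so frequency shifts push predicted expression the
intended way. Classic selection scores are N(shift·s, 1) with shift = 100
per unit s — standard normal at neutral SNPs, mean-shifted where selection
acted — with optional uniform masking to mimic incomplete score coverage.

Because SNPs are independent, passing tests demonstrate calibration and
power under drift and sampling noise, but say nothing about LD-induced
correlation between genes sharing a locus, haplotype-based confounding, or
real imputation error structure.

## Transcriptome-wide scan

Per gene, OLS of predicted expression on forward time t = −(years BP)
with an intercept; positive slopes mean expression rising toward the
present (the sign convention is configurable via `time_convention`). The
Wald statistic (β/se)² is referred to χ²₁. Genomic control divides all
χ² by λ = median(χ²)/0.45494, clamped below at 1 (no deflation). Note a
*neutral but drifting* cohort genuinely produces λ > 1: drift creates real
temporal trends in every gene, and absorbing that inflation is precisely
the purpose of genomic control. Calibration is therefore assessed against
date randomization (one shared permutation per replicate, preserving
inter-gene correlation) or i.i.d. expression noise, where λ = 1 is the
correct answer. λ is computed after the quality filter. Significance is
Benjamini–Hochberg at q = 0.05 (statsmodels implementation), reporting
the implied p threshold (the largest p called significant). No ancestry
covariates are used. Degenerate inputs: constant expression → β = 0,
p = 1; constant dates → error; numerically exact fits are floored at
p = 10⁻³⁰⁰ to keep p ∈ (0, 1].

Gene-level imputation quality is R²_gene = Σ|βᵢ|Rᵢ²/Σ|βᵢ| over variants
resolvable in the dataset. The quality filter removes genes strictly below
the (⌊f·n⌋+1)-th smallest quality (f = 0.20), retaining ties at the
threshold, so ⌈0.8n⌉ genes survive when qualities are distinct. Missing
dosages are filled with twice the cohort-wide allele frequency (the
standard TWAS convention); predictions are not re-standardized per gene,
so slopes stay in model units. Allele orientation is by exact allele
match (effect = alt → dose; effect = ref → 2−dose); strand-ambiguous
A/T–C/G sites are resolved by allele match only and flagged; unresolvable
variants contribute nothing and reduce the gene's reported weight
coverage.

## Genome-wide scan

Site filters: overall MAF ≥ 0.1 (boundary retained), missingness ≤ 90%,
and MAF > 0 among ancient samples. Allele counts are binned per century
(configurable); hard calls by rounding dosages, or dosage expectations
with `dosage_counts`. The per-SNP estimator maximizes the binomial
likelihood of the binned counts under a deterministic logistic trajectory
logit p(g) = a + s·g (g in generations), via a damped Newton solver
vectorised across SNPs, started at s = 0; it is a deliberately simple,
pluggable stand-in for richer time-varying selection estimators, and
externally computed ŝ tables can be substituted (`external_estimates`).
The `blocks` mode makes s piecewise-constant over B equal time spans with
an L2 smoothness penalty λₛ·Σ(Δs)² (default analog 10⁴·⁵) and collapses to
the scalar fit as λₛ → ∞. Monomorphic series are flagged unconverged and
excluded from windows. The estimator is antisymmetric under allele
relabeling.

Windows contain 20 consecutive usable SNPs advancing by 10, per
chromosome (never crossing boundaries); a final partial window (≥ 10
SNPs) is emitted, flagged, only when it covers SNPs beyond the last full
window, so 40 SNPs yield exactly 3 windows. The window statistic is the
mean |ŝ| (RMS of the block vector in blocks mode). A gamma distribution is
fitted to *all* window statistics by maximum likelihood with location 0
(method-of-moments fallback; zeros replaced by half the smallest positive
value); the fit is mildly sensitive to including the top windows, which
makes the resulting p-values conservative in the presence of strong
signals. Significant windows (default: BH-implied threshold at q = 0.05)
merge when gaps are < 5 Mb; merged intervals grow by 0.1 Mb each side
(floored at position 1) and are annotated with counts of all, modeled and
scan-significant genes by interval intersection. BED output converts the
internal 1-based inclusive intervals to 0-based half-open.

## Gene-level classic statistics

z = Σᵢ βᵢ sᵢ / √(Σᵢ βᵢ²), with both sums over *scored* SNPs. Restricting
the denominator to scored SNPs preserves the standard-normal null under
arbitrary masking (verified to variance 1 ± 0.03 at 40% masking); the
alternative all-SNP denominator, which deflates z toward 0 under masking,
is available via `denominator="all"`. Scores are polarized to the model's
effect allele before weighting (negated when the scored allele is the
other allele; scores matching neither allele are treated as unscored with
a warning). Genes with under half their model SNPs scored are removed
(exactly half is retained). Two-sided normal p-values, genomic control on
z². Concordance with the time-series scan reports sign agreement among
scan-significant genes and the Spearman correlation of β vs z over shared
genes.

## Observed-expression comparison

Per-gene Spearman ρ (average ranks) between predicted and observed
population medians over ≥ 3 shared populations; constant vectors are
skipped with a warning. T = Σ ρ is tested one-sided (the hypothesis is
positive agreement) against a null that permutes which observed gene row
pairs with which predicted gene row — population columns are untouched, so
each matrix's between-population mean and covariance are preserved exactly
— with the add-one correction p = (1 + #{T₀ ≥ T})/(1 + n_perm). Permuting
populations instead would destroy the between-population structure the
test conditions on; that alternative is deliberately not the default.

## Problem sizes and verification

The test suite and the acceptance script use desk-scale problems chosen to
make Monte-Carlo error small relative to the tolerances: 10⁴ genes × 707
samples for null calibration (λ within 0.05 of 1, KS uniformity at 1%),
10⁴ genes for the z-variance checks (±0.03), 40 replicate trajectories per
s for estimator recovery (bias < 20% of s), 50 replicate 700-SNP cohorts
for detection power (≥ 80% with correct sign; null call rate ≤ q plus
binomial noise), and a 2,000-SNP / 150-gene genome for the end-to-end run.
Brute-force oracles (explicit dot products, hand step-up FDR, interval
intersection) back the exact-agreement tests on hundreds of random small
instances.

## Known limitations

- No LD: gene models on overlapping SNP blocks are correlated, but there
  is no background haplotype structure, so genomic-control behaviour on
  real data (λ ≈ 1.8 reported for deep real cohorts) is only qualitatively
  reproduced.
- The logistic-trajectory estimator ignores drift variance in the
  likelihood; at small counts it is noisier than full time-series
  estimators, and the smoothing penalty in blocks mode is an analog, not a
  calibrated reimplementation, of published spline-based methods.
- SQLite PredictDB files are not read directly; export the same schema to
  TSV first.
- Coordinates are taken from the input assembly unchanged; no liftover.
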
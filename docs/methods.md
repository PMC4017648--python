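# Methods

This note documents the statistical models implemented in `twinvar`, the
design decisions behind them, what the synthetic-cohort generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## The twin mixed model

Expression of individual *i* is modelled as

    y_i = mu + a·S_iv + Σ_{k<K} (b_k·S_ik + c_k·S_iv·S_ik) + b_K·S_iK
          [+ c_K·S_iv·S_iK] + beta_i + gamma_i + eps_i

with `S_iv` the alt-allele dosage of the v-eQTL, `S_ik` dosages of partner
SNPs, `beta_i ~ N(0, σ²_FAM)` equal for the two members of any twin pair,
`gamma_i ~ N(0, σ²_MZ)` equal within MZ pairs only, and `eps_i ~ N(0, σ²)`
independent. The marginal covariance is block diagonal over families: every
diagonal entry is σ²_FAM + σ²_MZ + σ², the within-pair covariance is σ²_FAM
(DZ) or σ²_FAM + σ²_MZ (MZ). All fits are maximum likelihood, not REML,
because nested fixed-effect models are compared by likelihood-ratio tests.

**Fitting.** Both the fixed effects (by GLS) and the residual variance are
profiled out analytically, leaving a two-dimensional optimisation over the
variance ratios τ_FAM = σ²_FAM/σ² and τ_MZ = σ²_MZ/σ² on the log scale
(L-BFGS-B, bounds `[exp(-27.6), exp(15)]`, i.e. an effective zero of 1e-12).
Because every MZ block shares one 2×2 covariance and every DZ block another,
all weighted cross-products in the profiled likelihood are linear
combinations of a handful of precomputed p×p matrices, making one likelihood
evaluation O(p²) independent of sample size. Three fixed starting points
(τ = 0.5, 0.05, 2.0 for both ratios) guard against local maxima. Components
whose sharing structure is absent from the cohort (no pairs; no MZ pairs)
are pinned to zero so the model stays identified — this also makes the
polygenic residual stage reduce exactly to mean-centring for unrelated
cohorts. The engine reproduces a dense multivariate-normal ML oracle to
better than 1e-4 in log-likelihood on random small cohorts (tested).

**LRT.** c_K = 0 is tested with the chi-square(1) upper tail of
2·(ll_full − ll_null), negative statistics clamped to zero. No
boundary-mixture correction is needed since c_K is unconstrained. Measured
type-I error at cohort scale (n ≈ 700) is within 0.05 ± 0.008 over 5000 null
simulations.

**Forward stepwise scan.** At step K every remaining cis candidate is tested
conditional on all previously selected pairs (their c_k free); the minimum-p
candidate is added while p < α. The default α = 1.98e-8 is the genome-wide
Bonferroni threshold for a full cis scan; when the caller supplies the scan
size the tool recomputes 0.05/#tests instead (the dominance-screening
simulations use 0.05-scale/#tests ≈ 1e-4 for their 10-variant windows).
Ties in p are broken by genomic position for determinism; candidates
collinear with the current design are skipped, not fatal.

**Dominance conditioning.** Selected interactions are refitted with
a_het·P(het) + a_hom·P(alt-hom) replacing the additive v-eQTL term (earlier
selected pairs keep additive coding, as the model sequence is written) and
c_K is retested at the same threshold. With hard genotype calls the het/hom
columns saturate the three genotype classes, so any apparent interaction
that is really a non-additive single-locus effect tagged by an LD partner
loses its significance. Degenerate genotype probabilities (no heterozygote
information) leave a hit retained but flagged untestable.

**Signed interaction variance share.** The reported effect size is

    share = Var_i(ĉ_K · (S_iv − mean)(S_iK − mean)) /
            [Var_i(fixed-effect predictor) + σ̂²_FAM + σ̂²_MZ + σ̂²]

with the sign of ĉ_K (positive: joint alternate alleles raise expression
beyond the additive prediction). The numerator uses mean-centred dosages: it
measures the variance the interaction explains *beyond* anything an additive
recoding of the two SNPs could absorb, which is the "additional variance
explained" scale on which such effects are conventionally reported, and the
scale on which the simulator plants and records its truth values. The
denominator is the marginal-R² construction (fixed-predictor variance plus
all variance components) computed on the analysis sample.

## v-eQTL scan

Mean (eQTL) effects of each variant are removed by regressing the polygenic
residuals on [1, P(het), P(alt-hom)]; the squared residuals are each
individual's distance from its genotype-class mean (exactly so for hard
calls). The tie-corrected Spearman correlation between distance and dosage,
with a two-sided t approximation on n−2 df, is the variance statistic.
Working on genotype probabilities rather than hard calls lets dosage
uncertainty enter both stages coherently.

**Permutation FDR.** One set of five permutations of the individuals is
drawn per run and reused for every gene and variant, so the permuted null
preserves LD structure among SNPs within a window. Permuting the distance
residuals (not the raw phenotype) is valid because relatedness was already
removed. Per gene the peak (minimum-p) statistic is recorded for the
observed data and each permutation, and

    FDR(t) = [#{permuted peaks ≤ t} / n_perm] / #{observed peaks ≤ t},

evaluated at each observed peak, made monotone nondecreasing in t, capped at
one. By default the permutation count is floored at 1 (so the smallest
reportable FDR is (1/n_perm)/#observed): with only five permutations a count
of zero is sampling noise, and an unguarded estimate declares FDR = 0 for
the most extreme observed peak in ~1/(n_perm+1) of pure-null datasets. The
raw proportion is available with `zero_protect=False`.

**Permutation policy.** Permutations shuffle individuals ignoring family
structure. The polygenic-residual stage uses conditional (BLUP-subtracted)
residuals; note these over-correct the within-pair correlation toward
negative values when the family component dominates — acceptable here
because the scan's null calibration is established by the same permuted
residuals, and measured null runs produce zero discoveries in ≥ 90% of
replicates.

## Preprocessing

Order: square-root transform → latent-factor removal → quantile
normalisation → polygenic residuals. The square root stabilises the Poisson
sampling variance of read-count-derived abundances (delta method:
Var(√X) ≈ 1/4), breaking the mean-variance link that would otherwise let
ordinary eQTL masquerade as variance effects; log(1+x) is provided for
robustness checks. Latent factors are removed by residualising each gene on
the top sample-space principal components — a deliberate substitution of PCA
for variational-Bayes factor models: the broad-variance confounders PCA
captures are the ones that matter here, and the factor count stays a
configuration knob (50 for the discovery-scale default, 20 for
replication-style cohorts). An optional protected-covariate matrix is
projected out of the factors first so its signal survives. Quantile
normalisation maps each gene to Φ⁻¹((rank − 0.5)/n) with average ranks for
ties; sorted output equals the fixed normal-score vector for that n.
Each stage tags its output and refuses out-of-order input.

## Replication and haplotype screening

The replication cohort is unrelated, so models are OLS with indicator
covariates for study population (levels with < 3 samples are merged into the
largest level with a warning). Each discovery interaction is retested
individually (y ~ mu + a·S_v + b·S_K + c·S_v·S_K + populations) with a
two-sided t test on c — interactions are assessed one at a time because LD
and dominance screening already happened at discovery.

A haplotype effect — a rare causal eQTL carried on the joint background of
the two SNPs (high D′, low R² with each) — can mimic an interaction. The
screen: a forward stepwise additive eQTL scan (p < 1e-5 to enter,
population-adjusted) lists all cis eQTL including rare variants; the
interaction is then retested conditional on each eQTL in turn; the *largest*
conditional p over eQTL must still pass the same Storey q < 0.05 rule
applied across all tested interactions, else the record is removed.
Conditioning on a collinear eQTL is skipped (conservative). The screen is
monotone: adding eQTL to the conditioning list can only weaken evidence.

**Storey q-values.** π0 is estimated by the smoother method on a λ grid of
step 0.05 restricted to [min p, max p] — the restriction prevents overly
lenient correction when the p-value set does not reach 1 — with a cubic
polynomial fit evaluated at the largest admissible λ and clipped to (0, 1].
Fewer than 20 p-values (or fewer than 4 usable grid points) falls back to
π0 = 1, i.e. Benjamini-Hochberg. π1 = 1 − π0 estimates the replicating
fraction. Sign concordance compares the signs of the signed variance shares
across cohorts, with an exact binomial test against 0.5.

## GxE through MZ discordance

Both members of an MZ pair carry identical genotypes at every locus, so any
purely genetic mechanism — additive, dominant, epistatic, haplotype-driven —
contributes identically to both twins and cancels exactly in the within-pair
difference d = y₁ − y₂. Genotype-dependent environmental sensitivity does
not cancel: if the genotype scales the response to an exposure that differs
between twins, Var(d) grows with genotype. The default d-eQTL statistic
models d ~ N(0, exp(α + β·g)) and tests β = 0 by a chi-square(1) LRT.

The max-on-min construction (regressing the larger expression value of each
pair on the smaller plus genotype and their product) is also provided
(`test='joint'`/`'interaction'`). It is kept for comparability but not as
the default: because the fitted slope on the minimum is attenuated below 1,
a pure *mean* effect of the variant leaks into the genotype coefficient —
measured at ~65% rejection at α = 0.05 for a mean-only variant — so the
joint reading cannot serve as the epistasis/GxE discriminator. The
difference-variance LRT is calibrated under any purely genetic architecture
(measured ~5% null rejection under both additive-only and epistasis-only
simulations) with ~80% power at 134 MZ pairs for a GxE share of 0.3.

The GxE fraction among v-eQTL is Storey's π1 over the d-eQTL p-values of the
discovered peak variants. The pipeline restricts the d-eQTL stage to the
FDR-significant v-eQTL set: peak variants are selected in-sample as the most
variance-associated SNP of their window, so testing *every* peak would
inherit a winner's-curse inflation; restricting to discoveries matches the
two-step design (and even so, effect sizes at selected peaks remain
optimistically biased in-sample — replication is the guard).

## cis × trans variance components

Assuming no recombination across the 2 Mbp cis window, a DZ pair shares 0,
0.5 or 1 of the cis region IBD; trans sharing defaults to the genome-wide
expectation 0.5 unless per-family values are supplied (the simulator
supplies exact values). With Π_cis, Π_trans the pairwise IBD matrices (unit
diagonal, MZ entries 1) and Π_cis-trans their Hadamard product,

    Ω = Π_cis σ²_cis + Π_trans σ²_trans + Π_cis-trans σ²_cis-trans + I σ²_e

is fitted by ML over nonnegative components (log-scale, three fixed starts,
intercept profiled; block-diagonal pair algebra, no dense matrices) and the
epistatic fraction is σ²_cis-trans / (σ²_cis + σ²_trans + σ²_cis-trans +
σ²_e). The common-environment alternative replaces the Hadamard term with
C σ²_c, C the within-pair indicator for both zygosities. The two models have
equal dimension and are non-nested, so only Δloglik is reported, no p-value.

Sampling behaviour worth knowing: at 300 DZ + 150 MZ pairs the ML components
of a pure-noise trait sit on the zero boundary only about half the time
each; individual genetic shares exceed 0.05 in a nontrivial fraction of null
replicates (the cis×trans share alone stays below 0.05 in ~90% of runs, but
all three jointly only in ~70%). This is a property of boundary ML at this
design size, verified against a dense-likelihood oracle, not an optimizer
artifact; interpret small single-gene shares accordingly.

## The synthetic cohort generator

Simulation is haplotype-level: each genome carries two 0/1 haplotypes per
region, genotype = haplotype sum, so IBD sharing, D′ and R² are exact
constructs. Defaults mirror a discovery cohort of 134 MZ pairs + 192 DZ
pairs + 113 singletons (765 samples) and a replication cohort of 462
unrelated samples across five populations whose labels shift means only.

- **LD**: allele-copy process — variant j copies variant j−1's allele with
  probability `ld_rho` (default 0.8), else draws fresh at its own frequency;
  adjacent-variant genotype correlation ≈ ld_rho, decaying geometrically.
- **IBD**: DZ cis and trans sharing drawn from {0, 0.5, 1} with
  probabilities (0.25, 0.5, 0.25), the autosomal expectation; sharing
  applies to the whole region (no within-window recombination, matching the
  analysis assumption).
- **Effects**: additive terms calibrated to target variance fractions of a
  unit-variance phenotype (default 0.2 for a planted eQTL); interactions
  planted on mean-centred dosage products with the coefficient solved by
  root-finding so the realized beyond-additive share matches its signed
  target (default ±0.05); family/MZ components 0.1/0.1 where planted.
- **GxE**: an additive genotype-by-exposure term η·g_i·E_i with E_i ~ N(0,1)
  independent per individual (hence within MZ pairs),
  η = √(share/mean(g²)). Conditional on genotype the variance is
  σ² + η²g². A multiplicative log-normal residual-scale mechanism was
  implemented first and rejected: its scale factor is symmetric around 1 in
  log, so group medians do not move and rank-based variance tests are almost
  blind to it. The additive form is the standard interaction model, is
  analytically calibrated, and produces the genotype-dependent spread the
  scan is designed to detect. The "detectable" GxE share used by the
  discordance-stage simulations is 0.3 on a common variant (MAF 0.3–0.5),
  fixed by an a-priori power analysis (~80% power at 134 MZ pairs); the
  v-eQTL-stage planted share is 0.25, at which the squared-residual Spearman
  attains peak p < 1e-4 in > 90% of cohorts.
- **Haplotype confounders**: a rare variant (default MAF 0.03) whose minor
  allele is placed only on haplotypes carrying the alternate allele of both
  designated tag SNPs — realized D′ = 1 with each tag, R² < 0.1 — and only
  the rare variant receives an expression effect.
- **Truth records**: per gene, planted coefficients plus realized variance
  fractions, both marginal (Var(term)/Var(y)) and incremental (telescoping
  attribution including covariances; sums to 1 exactly).

What the generator does **not** emulate: read-level count noise (phenotypes
are Gaussian on the analysis scale), population LD differences and admixture
(population labels shift means only), imputation-quality gradients (the info
field is constant 1; dosage blur is a single symmetric-noise knob),
recombination inside the cis window, and X-chromosome/parent-of-origin
effects. Passing tests therefore certify the statistical machinery under the
model's own assumptions, not robustness to real-data artifacts such as
count overdispersion or stratified LD.

## Problem sizes

Test-suite and acceptance-script simulations use: 20 random small cohorts
(n ≤ 30) for oracle equivalence; 5000 (suite) / 2000 (script) null LRT
simulations at n = 702; 20 (suite) / 10 (script) global-null v-eQTL runs of
200 genes × 50 variants plus 3 runs with 10% planted effects; 50 / 30
interaction-recovery replicates at n = 800 with 40-SNP windows; 40 / 30
haplotype-screening replicates at n = 462; 12 dominance replicates; 20-fold
π1 mixtures at 508 tests; 30 GxE and 30–40 epistasis discordance replicates
at 134 MZ pairs; 25 variance-component recovery replicates and 15–20 null
runs at 300 DZ + 150 MZ pairs. These sizes were chosen so each property is
measured with useful Monte-Carlo precision while the whole suite stays
desk-scale.

## Known limitations

- The permutation FDR is gene-level; no variant-level FDR is offered.
- The LMM engine covers twin-block covariance only — no general kinship.
- PCA latent-factor removal can absorb genuine broad genetic signal if a
  trans hub dominates many genes; the factor count is a knob, not an
  inference.
- Storey's π1 is biased downward when alternatives have modest power; the
  restricted-λ grid mitigates but does not remove this.
- ML variance components at a few hundred pairs have boundary-inflated
  sampling noise (see above); per-gene shares should be read as noisy
  estimates, not point facts.
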
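# Methods

`traitgraph` builds signed causal graphs from genes through co-expression
programs to a quantitative trait by integrating two genome-scale
measurements: gene-level loss-of-function (LoF) burden effect sizes, and
gene-regulatory effects from single-cell CRISPR perturbation (Perturb-seq
style) screens. This note records the models, the numerical choices, what
the synthetic generator does and does not emulate, and the known
limitations.

## Burden effect shrinkage

A LoF burden test yields, per gene x, an effect estimate γ̂ₓ with standard
error SEₓ. Because LoF carriers are rare — rarest for constrained genes —
γ̂ is noisy exactly where effects are most interesting. We shrink with a
signed empirical-Bayes prior:

    sign(γ)  ~ Bernoulli(p)          (+ with probability p)
    |γ|      ~ Gamma(α, θ)           (shape α, scale θ)
    γ̂ | γ    ~ Normal(γ, SE²)

The prior (p, α, θ) is fitted per gene bin (e.g. shet deciles; a single
shared bin works for small panels) by maximizing the marginal likelihood
Σₓ log ∫ f(γ) N(γ̂ₓ; γ, SEₓ²) dγ with L-BFGS-B in (logit p, log α, log θ)
from three fixed starts. The integral inside the fit uses 256-node
Gauss–Legendre quadrature in the prior-CDF coordinate u = F(|γ|), which
places nodes at prior magnitude quantiles. Fits that terminate on the box
boundary from every start carry `converged=False`; a flat profile
likelihood in p (e.g. all γ̂ ≈ 0) sets `p_identifiable=False`.

Per-gene posterior summaries (mean and P(γ > 0)) use a fixed composite
grid per sign branch: 2000 log-spaced magnitudes spanning the prior
quantiles [1e-9, 1 − 1e-9] (log spacing absorbs the integrable
singularity at 0 when α < 1) unioned with 500 linear points on
γ̂ ± 8·SE where the likelihood concentrates, integrated with composite
Simpson's rule after factoring out the peak log-density. The span was
chosen so that truncated prior mass (≈1e-9) sits far below the 1e-6
relative-accuracy target; against an adaptive-quadrature oracle the
worst relative error over wide random parameter draws is below 1e-6.
SE = 0 short-circuits to (γ̂, 1[γ̂ > 0]).

This per-bin prior deliberately simplifies gradient-boosted
feature-conditional priors: the empirical-Bayes structure (signed prior,
Normal likelihood, posterior mean as point estimate) is preserved while
the machine-learned prior-parameter regression is replaced by binning on
a user-chosen gene feature. Per-gene tree-learned priors, and estimation
of shet itself, are out of scope.

## Perturbation effects

Cells carry exactly one perturbation label (a gene, or non-targeting).
After removing cells expressing < 500 genes and then genes expressed in
< 500 cells (in that order; thresholds scale down for synthetic panels),
expression is log-normalized: ln(1 + count·scale / cell_total),
scale = 1e4.

The effect of knocking down gene x on a response r (a gene's
log-normalized expression, or a program's usage) is the `is_perturbed`
coefficient of per-response OLS over the cells {perturbation = x} ∪
{non-targeting}:

    response ~ 1 + is_perturbed + batch + n_genes_expressed + pct_mito

with batch one-hot encoded (first level dropped). p-values are exact
two-sided t-tests; Benjamini–Hochberg FDR is applied within a declared
family — across responses per perturbation (gene-level scans) or across
perturbations per response (program regulator identification). Constant
responses return β = 0, p = 1; collinear covariates are dropped (keeping
`is_perturbed`); under-powered targets (< 10 perturbed cells) are
recorded and skipped rather than raising. Self-knockdown rows
(response = perturbed gene) are flagged for downstream exclusion.
Moderated-variance DE is available behind
``moderate_variance=`` as a simplified empirical-Bayes squeeze of the
residual variances toward their across-response mean (fixed prior
degrees of freedom, default 10) and is off by default: point estimates
are identical either way and moderation matters mainly at very low cell
counts. Log-fold-changes are natural-log.

Cell-cycle phases: S and G2M scores are means over marker genes of
expression z-scored across cells; the larger score wins when positive,
else G1. The expression-matched control-bin refinement of the cited
scoring scheme is omitted — on synthetic data all genes share one depth
regime, where matching changes little. Phase fractions per perturbation
carry leave-one-cell-out jackknife SEs,
SE = sqrt((n−1)/n · Σᵢ(fᵢ − f̄)²), computed in closed form.

## Consensus NMF programs

Programs come from consensus non-negative matrix factorization of the
cells × genes matrix (genes scaled to unit variance without centering,
preserving non-negativity). Each of `n_runs` NMF restarts (coordinate
descent) contributes k L2-normalized spectra; components whose mean
Euclidean distance to their ⌊n_runs/3⌋ nearest neighbors exceeds
`density_threshold` (default 0.5) are discarded as outliers; survivors
are k-means clustered (10 restarts, fixed internal seed) into k groups;
each cluster's elementwise median, renormalized, is a consensus
spectrum; usages are refit per cell by non-negative least squares.
Stability is the mean silhouette of the surviving components and the
error is the Frobenius reconstruction error; `select_k` tabulates both
over candidate k and leaves the choice to the caller, and `choose_k`
implements the error-versus-stability rule: among candidates whose
stability is within a small tolerance of the best (under-factorized
solutions can be perfectly reproducible, so stability alone near-ties),
take the lowest reconstruction error; over-factorized k values stay
excluded by their genuinely depressed stability. Program indices
are ordered by decreasing cluster size with spectrum-hash tie-breaks, so
numbering is reproducible under run reordering.

Initialization is a genuine trade-off. Random non-negative init (the
default) gives independent restarts, which is what makes the stability
diagnostic informative — under-factorized k values become visibly
unstable on noisy data. NNDSVD-based init is near-deterministic: every
restart reaches the same strong optimum, which collapses the ensemble
(stability ≈ 1 at every k) but yields sharp consensus spectra from very
few runs. The end-to-end pipeline therefore runs NNDSVD-ar with a small
run budget, while stability-based k selection uses random restarts; both
are exposed via `init=`.

## Program–trait association

Two statistics, deliberately kept separate because programs can be
trait-relevant through their genes, their regulators, either, or both:

**Program burden effect.** Loadings are non-negative, so the mean γ of a
program's top-loading genes (default 100 for scans, 200 inside graph
construction; scaled to panel size on synthetic data) is a signed,
interpretable program-level effect. Constraint confounds it — shet
correlates with |γ| — so the null draws `n_perm` random gene sets
matching the observed set's composition across 10 shet quantile bins
*exactly* (ties to the lower bin). The two-sided permutation p is
2·min(#{null ≥ obs}+1, #{null ≤ obs}+1)/(n_perm+1), capped at 1, never
0, on the (n_perm+1) lattice, and carries the sign of the observed mean.
An exact-tie tolerance (1e-9 relative) keeps degenerate inputs (constant
γ) at p = 1 rather than splitting float ties.

**Regulator-burden correlation.** OLS of γ on [βₓ→P, shet] with
intercept across perturbed genes; the β coefficient, its SE, and
−log10(two-sided p) signed by the coefficient. For gene-level responses
the focal gene is excluded from its own regressor vector. A positive
coefficient reads: up-regulating the program promotes the trait.

Two-sided QQ construction ranks positive- and negative-signed statistics
separately against uniform order statistics scaled by the total test
count. Top-hit enrichment is a two-sided Fisher exact test of a hit set
against the top-n of a ranking over a declared background, with Haldane
0.5 correction and Woolf 95% CI when a cell is empty.

## Causal direction between programs

For programs p1, p2: take each program's significant regulators
(FDR < 0.05, per-response family; overlapping regulators stay in both
sets), compute Spearman ρ₁ of their effects on (p1, p2) over p1's
regulators and ρ₂ over p2's, Fisher-transform (z = arctanh ρ,
variance 1/(N−3); |ρ| is clamped to 1 − 1e-12), and compare four
Gaussian models by AIC: M1 (p1→p2: Z₂=0), M2 (p2→p1: Z₁=0), M3 (both 0,
k=0), M4 (shared Z*, the precision-weighted mean, k=1). The relative
likelihood r = exp((AIC_causal − AIC_noncausal)/2) with
AIC_causal = min(M1, M2) and AIC_noncausal = min(M3, M4); r < 0.01 is
called causal in the winning direction. Fewer than 4 regulators on
either side makes the pair untestable (the 1/(N−3) variance
degenerates). Raw betas enter the Spearman step — rank correlation is
scale-invariant, so standardization would change nothing.

A power note: with N = 50 regulators per side, discriminating a true
one-way transmission from the shared-correlation model M4 at r < 0.01
requires |z₁ − z₂| > 0.63; reliable (≥90%) recovery therefore needs a
transmitted correlation around ρ ≈ 0.75 or stronger, and the planted
direction-recovery study uses ρ ≈ 0.76 (Fisher z ≈ 1).

## TF binding scores and program annotation

A TF's regulatory potential on a gene is S(i,j; d) = Σₖ P(i,k)·
exp(−x(i,j,k)/d): peak strengths P (−log10 q) decay-weighted by
peak-to-TSS distance x, with d = 5 kb or 50 kb. The peak reference point
is the narrowPeak summit offset when present and non-negative, else the
integer-floor midpoint; distances are same-chromosome only; coordinates
are 0-based half-open BED throughout; strand is ignored. TFs are
classified activator/inhibitor by one-sided Mann–Whitney of their scores
over down-/up-regulated knockdown DEGs against the background minus the
TF's DEGs (the DEGs under test are excluded from the background — the
conservative choice), BH-corrected across TFs per test, keeping per TF
whichever decay gives the stronger DEG correspondence; a TF may carry
both flags. Programs are annotated by one-sided Mann–Whitney enrichment
of each classified TF's scores over the program's top-loading genes,
BH-corrected across TF × program, optionally joined with the TF's direct
knockdown effect on program usage.

## Graph construction (five steps)

1. **Regulator programs.** Exhaustive best-subset regression of γ on
   program effects {βₓ→p} with shet always included: for each subset
   size s the best R² subset is found by full enumeration (a model
   budget, default 2×10⁶, guards combinatorial blowup; collinear
   subsets are skipped and recorded). The final size is the smallest s
   whose marginal R² gain drops below 10% of the total gain — an
   explicit, configurable form of "where the variance explained
   flattens"; the winning subset's OLS coefficients are the path
   weights w_p. All genes enter the regression, not only significant
   regulators, matching the genome-wide regression formulation.
2. **Content programs.** Programs ranked by the shet-matched permutation
   p of their program burden effect; the retained count defaults to the
   number of Bonferroni-significant programs; each carries the sign of
   its top-gene mean γ.
3. **Gene signs.** Significant regulators (FDR < 0.05 on ≥ 1 selected
   program) get sign(Σ_p w_p·βₓ→p) over their significant selected
   programs — multi-path regulators keep all paths; exact cancellations
   below 1e-12 stay unassigned. Top-loading genes of selected content
   programs inherit the program's content sign, which takes precedence
   for dual-role genes (program membership is assumed to carry the
   larger effect); the same program-wins rule covers three-way
   conflicts.
4. **Validation.** Leave-one-gene-out: selection is rerun without the
   gene (subset sizes fixed to the full-data fit; content ranked by the
   fast Mann–Whitney path, since the ranking is deterministic and a
   permutation null per fold would add nothing but cost) and the
   held-out gene's sign is predicted; Fisher's exact test compares
   correct predictions among high-|γ| genes (> 0.1) vs minimal-|γ|
   genes (< 0.01). The label-permutation test reruns selection + sign
   assignment on permuted γ (fixed subset counts, Mann–Whitney content
   ranking — fast but potentially conservative) and reports
   (1 + #{perm Fisher p ≤ observed})/(n_perm + 1). An 80/20
   cross-validation utility reports out-of-sample R² for the chosen
   multi-program set vs single programs and baselines.
5. **Serialization.** The graph keeps high-|γ| genes whose predicted
   sign matches observed γ, with per-path effects, program weights,
   content signs and the validation summary; JSON round-trips
   byte-identically, and a flat edge table / networkx export serve
   downstream tooling.

## Synthetic data generator

The generator is the testbed's ground truth, not a cosmetic fixture. It
plants: disjoint regulator and member sets per program; non-negative
member loadings (U(1,2)) over a faint background; signed regulator
effects βₓ→P (±scale·U(0.75,1.25)); a trait
γₓ = Σ_p w_p·βₓ→P + content_p·1[member] + ε, ε ~ N(0, trait_noise_sd²),
so regulator-path and content weights can disagree in sign (the
discordant-program phenomenon); shet ~ Beta(1.2, 3) coupled to |γ| by a
Gaussian copula (the noise model linking burden SE to constraint is not
prescribed anywhere; a deterministic monotone map SE = lo + (hi−lo)·shet
is this package's modeling choice, with cohort noise γ̂ = γ + N(0, SE²)
and cohort seeds sharing γ); batched cells with one perturbation each,
usage = baseline + βₓ→P + batch offset + noise truncated at 0, rates
usage·loadingᵀ plus a housekeeping baseline (mito-like genes scaled to a
target expression share), per-cell depth scaling and Poisson counts
(gamma-mixed Poisson behind an `overdispersion` knob, default off —
the downstream regressions operate on log-normalized values, for which
Poisson is the simplest generator satisfying the assumptions); and TF
peaks within a window of target-member TSSs plus uniform background
peaks on a linear genome, written as narrowPeak/BED.

Defaults (300 genes, 3 programs, 20 cells/perturbation, 500
non-targeting cells, 2 batches, depth 2000, mito fraction 8%) are a
desk-scale analogue of a genome-wide CRISPRi screen in one cell line
(~9,500 perturbations, median ~166 cells each, ~11,500 UMIs/cell); the
planted three-program study adds content weights (0.4, −0.4, 0.4) and
regulator-path weights (0.6, 0.6, −0.6) so that one program's genes and
regulators pull the trait in opposite directions.

Not emulated: guide-level (multi-sgRNA) structure, doublets, ambient
RNA, LD or variant-level genetics, chromosome structure, cell-type
mixtures, and realistically heavy-tailed expression (negative binomial
is available only via the overdispersion knob). Passing tests therefore
demonstrate internal consistency and recoverability under the stated
generative model — not robustness to these real-data complications.

## Problem sizes

The test-suite and acceptance runs use: 100 random draws for the
quadrature oracle; 5,000 genes for prior recovery; 3,000 genes × 2
cohorts for shrinkage/replication; 500 null programs at n_perm = 2,000
(and 500 null regressions) for calibration; 200 × 90 cells × genes at
rank 5 for factorization recovery; 200 replicates at N = 50 for causal
direction; and the 300-gene three-program study with 1,000 label
permutations end-to-end. These sizes were chosen so each property is
tested with comfortable statistical margin on a single CPU.

## Known limitations

- Per-bin priors cannot express smooth feature effects; with few genes
  per bin the α, θ estimates are noisy.
- OLS effect estimation assumes homoskedastic Gaussian residuals on
  log-normalized counts; at very low counts a moderated or count-based
  model would be better calibrated.
- The causal-asymmetry test assumes regulator ascertainment is the only
  source of asymmetry; shared latent regulators of both programs can
  mimic transmission (the M4 model absorbs only the symmetric part).
- Best-subset selection is exhaustive and exact but exponential in K;
  beyond ~20 candidate programs a heuristic search would be needed.
- The permutation test's fast content ranking (Mann–Whitney instead of
  the constraint-matched permutation) makes its p-value conservative
  when constraint strongly confounds content selection.
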
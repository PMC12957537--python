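# Methods

## Scope and design

`protmr` implements a proteome-wide two-sample MR screen of circulating
proteins on a glycemic outcome as a chain of pure, testable stages over
summary statistics. The two-sample design rests on the three instrumental
variable assumptions (relevance, independence from confounders, exclusion
restriction); the pipeline's sensitivity ladder, Steiger filter and
colocalization stage are the operational checks on the second and third.
Because the original nine proteomic GWAS and the glycemic outcome GWAS are
external resources, the package ships a synthetic-data generator whose
output is structurally identical to the real inputs, plus two small
bundled reference tables of prioritized proteins and druggability
annotations used for count-level checks.

## Instrument selection

Per study: keep variants with p ≤ the study's significance threshold
(default 5e-8, boundary inclusive); drop the MHC region
(chr6:26,000,000–34,000,000, both bounds inclusive — the region's complex
LD makes instruments there unreliable); greedy LD clumping per protein
(sort by ascending p, ties broken lexicographically on variant id for
determinism; accept the best record; prune records within 500 kb at
r² > 0.01 with an accepted record; repeat); then remove any variant
instrumenting five or more proteins in the study's pooled candidate set
(configurable to run before clumping instead). A pQTL is cis when it lies
on the gene's chromosome within [start − 500 kb, end + 500 kb] measured
from the gene body, trans otherwise, and unknown (excluded from cis-only
analyses) without an annotation. Missing LD pairs are treated as r² = 0
with a logged warning: conservative for the instrument count, and the
warning surfaces LD-panel coverage gaps.

## Harmonization

Exposure and outcome records are merged on variant id; swapped alleles
flip the outcome beta and EAF; palindromic variants (A/T, C/G) are dropped
when either trait's EAF lies in [0.42, 0.58] or is missing, otherwise
treated like any match; irreconcilable allele pairs are dropped. No proxy
search is attempted for variants absent from the outcome. The palindromic
window bounds are a common convention, configurable.

## Estimators and the ladder

The Wald ratio uses the first-order delta SE (se_out/|β̂ₓ|) by default;
the second-order form adding the exposure term is available but not
default, matching prevailing practice. IVW weights per-variant ratios by
inverse squared first-order SEs, reports Cochran's Q on k−1 df, and scales
the SE by max(1, √(Q/(k−1))) — multiplicative random effects that never
deflate below the fixed-effect SE. MR-Egger orients pairs to β̂ₓ ≥ 0 and
fits WLS with weights 1/se_out²; its covariance is rescaled by
max(1, RSS_w/(k−2)) under the same never-deflate rule (statsmodels
provides the fit, the rescaling is applied on the unscaled covariance).
The weighted median interpolates the cumulative weight function of the
ordered ratios at ½ and takes its SE from a seeded parametric bootstrap
(default 1,000 resamples).

The ladder is a pure function of two p-values at α = 0.05 (configurable):
no flag → IVW (or Wald ratio for one instrument); heterogeneity (Q) →
weighted median; directional pleiotropy (Egger intercept) → Egger, taking
precedence when both fire, because a nonzero intercept invalidates IVW and
potentially the median's majority-valid assumption. Bonferroni correction
uses strict p < 0.05/n with n = proteins tested per dataset (taken from
config, or the observed protein count).

## Steiger directionality

On standardized traits a variant explains r² = 2f(1−f)β² of a trait's
variance; the per-trait totals over the (clumped, hence approximately
independent) instruments are converted to correlations and compared with a
two-sample Fisher z-test using the two studies' sample sizes. Where EAF is
missing the per-variant fallback is r² = F/(F + n − 2) with F = (β/se)².
Categories follow the standard rule: "true" for the forward direction at
p < 0.05, "false" for the reverse at p < 0.05, "uncertain" otherwise;
equal variance explained with equal n gives z = 0 and p = 1 exactly. The
summed-r² form slightly overstates totals when instruments are correlated;
after clumping at r² ≤ 0.01 the error is negligible.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor computed from
beta and SE (the SE-based form; an allele-frequency-based variant is not
implemented). Hypothesis sums S0…S4 combine per-SNP ABFs with priors
p1 = p2 = 1e-4, p12 = 1e-5 and prior effect SD 0.15 per quantitative
trait — the published defaults of the ABF colocalization framework, all
configurable — entirely in log space (log-sum-exp; H3's
(ΣA1)(ΣA2) − Σ(A1A2) term via log1p, so a single-SNP region yields
PPH3 = 0 exactly). The "1-Mb range" around an index pQTL is read as a
1-Mb total span (±500 kb); the ±1-Mb reading is available by doubling
`window_bp`. Strong colocalization is strictly PPH4 > 0.8. The model
assumes at most one causal variant per trait per locus; with several, PPH4
reflects only the dominant shared signal.

## Synthetic data generator

Summary statistics are generated directly — no individual-level genotypes
— because every stage consumes only summary data and the summary-level
sampling model is exact for standardized traits: se = 1/√(2nf(1−f)),
marginal effects are LD-propagated causal effects under an AR(1)
correlation (r² = ρ^{2|i−j|}, emitted exactly in the LD table), estimates
add independent normal noise with the analytic SE, and p-values are exact
normal tails. Defaults: MAF uniform on (0.1, 0.5), per-allele causal
effects of 0.15–0.25 SD (exposure F ≫ 10 at n = 10,000, the
strong-instrument regime the two-sample design presumes), ρ = 0.7 within
10-SNP loci, n = 10,000 exposure / 100,000 outcome.

Violation mechanisms: directional pleiotropy adds direct SNP→outcome
effects with nonzero mean *defined relative to the exposure-raising
allele* (random allele orientation would cancel the bias);
`pleiotropy_frac` limits the share of invalid loci; balanced pleiotropy is
mean zero; reverse causation makes the variant act on the outcome with the
protein responding at `reverse_effect` times that effect. Colocalization
regions place zero / one-trait / distinct / shared causal variants in one
AR(1) region (ρ = 0.6, 50 SNPs, n = 50,000, causal β = 0.15); H3's two
variants sit at the region ends where r² ≤ 0.01. A single global seed
feeds SeedSequence spawn-key substreams, so each replicate is individually
reproducible and runs are bitwise deterministic.

The multi-protein study generator (20 proteins, 3 causal at θ = 0.2, ten
loci per protein with the first hosting the coding gene, effects
U(0.1, 0.4)) feeds the end-to-end pipeline checks. Ten loci with a wide
effect-size spread are deliberate: when a spurious heterogeneity or
pleiotropy flag promotes the weighted median or Egger, those fallbacks
remain well identified (Egger needs spread in instrument strength), so a
true effect is not lost to a chance flag.

What the generator does not emulate: assay noise of real proteomic
platforms, cohort structure, allele-frequency spectra, correlated
(in-sample LD) noise across SNPs of one trait, sample overlap between
exposure and outcome, or missing/incorrect allele metadata beyond what the
harmonizer's unit tests construct. Passing simulations therefore validate
the statistical machinery, not robustness to real-data artefacts.

## Calibration scenarios (frozen)

`protmr.calibration` fixes the scenarios behind the tests, analysis
drivers and acceptance script: recovery (10 valid instruments, θ = 0.2),
null (θ = 0, type-I error of the IVW test), directional pleiotropy (50
instruments, pleiotropy mean 0.02, n_exposure = 50,000 and effects
U(0.1, 0.5) so instrument-strength heterogeneity dominates exposure
estimation error — Egger's NOME assumption — isolating the pleiotropy
mechanism), and contamination (4 of 10 instruments with large balanced
pleiotropy, SD 0.12). In the contaminated scenario the weighted median's
mean is compared to truth while IVW is shown unreliable per replicate
(|estimate − θ| > 3 fixed-effect SEs); a one-sided contamination at 40% of
the weight would shift the weighted median itself by an amount of order
the ratio SE — the median-shift effect — which is why the robustness claim
is operationalized under sign-symmetric invalidity and the mean-bias
contrast under the directional scenario.

## Numerical choices and degenerate inputs

Coordinates 1-based inclusive throughout; all boundary comparisons
inclusive and unit-tested. Clumping ties break lexicographically.
β̂ₓ = 0 raises on the Wald ratio; all-equal exposure betas raise a
degenerate-design error in Egger; fewer instruments than an estimator
needs raises a typed signal the ladder handles. Posteriors sum to 1 within
1e-9 by construction; Steiger caps summed r² just below 1 before the
z-transform. Reported floats are written at 15 significant digits so
write-then-read round-trips are identity.

## Known limitations

Single-causal-variant colocalization (no SuSiE-style extension, no
conditional analysis); no MR-PRESSO, mode-based or multivariable
estimators; no leave-one-out analyses; no proxy search for outcome-missing
variants; no liftover or VCF/PLINK parsing; eQTL direction checks trust
the input table's orientation to the pQTL effect allele and its
significance flags; enrichment/PPI analyses are out of scope. Steiger's
Fisher-z approximation treats the instrument sets as independent within
trait; the Bonferroni denominator is a configuration choice, not inferred.
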
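# Methods

## The factorial interaction model

Each gene's log2 CPM expression is modeled by ordinary least squares on the
saturated 2×2 design matrix `(1, u, o, u·o)` with exposure indicators
`u` (UVSSR) and `o` (ozone). The four coefficients are the control mean
`mu`, the simple main effects `a` and `b` (each stressor's log2 fold change
at the reference level of the other), and the interaction `c`. Derived
effects: co-exposure effect `a + b + c` and marginal main effects `a + c/2`
and `b + c/2`, the balanced-design average of one factor's effect over the
other's levels. Standard errors of derived effects follow by
linear-combination propagation through `(X'X)^-1`; p-values are two-sided t
on `n − 4` residual degrees of freedom (df = 8 at 3 replicates/arm).

Because the model is saturated in the four arms, fitted arm means equal
empirical arm means on balanced designs, and the interaction t-test is
algebraically the classical two-way ANOVA interaction F-test (t² = F); both
identities are exercised in the test suite against independent oracles.

The estimator is deliberately the plain per-gene OLS rather than a
moderated (shrunken-variance) variant, so every reported number is exactly
reproducible from the stated formulae. A pooled-variance moderation weight
(`moderation_weight` ∈ [0, 1], default 0, shrinking each gene's residual
variance toward the genome-wide mean) is provided for users who want
limma-style stabilization at n = 3.

Assumptions: approximately Gaussian log2 CPM residuals within arms, shared
within-gene variance across arms, independent samples. At typical bulk
depths (mean counts in the hundreds) log2 CPM of NB counts is close enough
to Gaussian that the gate is well calibrated (measured type-I error 0.049 at
the nominal 0.05 on a 10,000-gene null simulation).

## Classification and synergy

Interaction-gated genes (`p_c < alpha`, default 0.05) are classified from
the signs of `(a, b, a+b+c)`: same-signed `a`, `b` → cooperative, split into
concordant/discordant by whether `a+b+c` shares their sign; opposite-signed
`a`, `b` → competitive, split into UVSSR-/ozone-dominant by whether
`a+b+c` follows `a` or `b`. The eight sign patterns map bijectively onto the
eight components. An exactly zero input is returned as `unclassifiable`
rather than tie-broken silently — with continuous estimates this occurs only
in degenerate fixtures, and silent assignment would corrupt the fraction
summaries. Classification consumes the factorial-fit fold changes (not the
DE-stage contrasts) so gating and labeling come from a single model; on
balanced designs with the same normalization the two coincide.

The synergy score compares the co-exposure response with the additive
expectation on the log2-FC scale: `raw_ratio = |a+b+c| / |a+b|`, reported by
default as `score = log2(raw_ratio)` so that positive score ⇔ super-additive
magnitude. A literal `abs_ratio` variant (score = raw_ratio, synergy ⇔
ratio > 1) is exposed because the ratio itself is sometimes quoted; the two
agree on the selection boundary (log2 score > 0 ⇔ ratio > 1). Degenerate
inputs are flagged with infinite sentinels: `a + b = 0` → +inf (the additive
expectation vanishes), `a+b+c = 0` → −inf. Synergy genes require a strictly
positive score **and** a significant expression change: p < 0.05 and linear
|FC| > 1.2 (|log2 effect| > log2 1.2 ≈ 0.263) of the main effect. "Main
effect" defaults to either marginal main effect passing (`either_main`); a
`co_effect` rule applying the same thresholds to the co-exposure effect is
provided because either reading is defensible.

## Supporting stages

* **Normalization** — plain CPM with pseudocount 1.0, log base 2, library =
  column sum; low-expression filter CPM ≥ 1 in ≥ 3 samples (one arm's
  worth). No TMM or other composition correction: CPM keeps the artifact
  self-contained and the factorial coefficients interpretable as log2 fold
  changes. The cost of that choice is quantified below.
* **Differential expression** — per-gene two-sided Welch t on log2 CPM,
  DEG ⇔ p < 0.05 and linear |FC| > 2, no multiple-testing correction (the
  DEG rule is a raw cut-off by design). Welch at n = 3 per group is
  intrinsically conservative: even on exactly normal data the
  Welch–Satterthwaite approximation at df ≈ 2–4 yields empirical type-I
  ≈ 0.034–0.038 at nominal 0.05 and measurably non-uniform null p-values.
  The suite asserts Welch is never anti-conservative rather than exactly
  calibrated.
* **Enrichment** — hypergeometric upper tail (equivalent to one-sided Fisher
  exact, verified exhaustively on small tables), BH q-values across the
  tested sets, universe = genes surviving the expression filter.
* **Phenotype** — one-way ANOVA F across the four arms plus Tukey HSD on the
  pooled within-group variance (Tukey–Kramer when unbalanced), significance
  at adjusted p < 0.05. All-constant input is handled degenerately (p = 0 if
  any means differ, else 1) so noiseless fixtures remain usable.

## The synthetic cohort

The simulator emulates the study conditions the analysis assumes: four arms
(control, UVSSR, ozone, co-exposure) × 3 RNA-seq replicates (5 replicates
for the Gaussian phenotype), negative-binomial counts with mean–dispersion
parameterization `var = mu + phi·mu²` and shared `phi`, log2-normal baseline
abundances, and a planted mixture of the eight components plus null genes.

Defaults, chosen once as conventional bulk RNA-seq values: library size 1e7,
`phi = 0.1` (calibration) or as set per run, `baseline_log_mean = 4`,
`baseline_log_sd = 2`, 20% planted genes split evenly over the eight
components, `effect_size_log2 = 2` (|a| = |b| = 2) and
`interaction_size_log2 = 2` — the planted interaction magnitude at which the
factorial gate has ≥ 80% power at `phi = 0.05`, n = 3/arm. Component labels
are assigned by exact proportions (floor + largest remainder) so fixture
counts are deterministic and assertable; placement among genes is
seed-shuffled. For concordant components the interaction reinforces the
shared direction (`c = ±interaction_size`); for discordant and dominant
components the co-exposure sign is set by
`c = −sign(a+b)·|a+b| ± interaction_size`, which realizes the component's
sign pattern exactly — the classifier applied to the true effects recovers
every assignment (a tested generator contract). Identical config + seed ⇒
bit-identical output; the pipeline derives per-stage seeds from the run seed
by hashing `"<seed>:<stage>"`.

What the simulator does **not** emulate: read-level data, sequencing error,
batch effects, gene–gene correlation, per-gene dispersion, or realistic
effect-size spectra (all planted effects share one magnitude). Passing
recovery tests therefore demonstrates the correctness of the estimators and
rules under the stated generative model, not performance on real tissue
data.

## Known limitation: CPM composition bias

Planted concordant genes reach co-exposure fold changes of 2^(2a+c) = 64×;
at 20% planted genes this inflates co-exposure library totals ≈ 2× over
control. Plain CPM renormalizes that away uniformly, shifting every *null*
gene's apparent interaction by ≈ −0.7 log2 in the mixture cohort and raising
the null false-positive rate at the gate from the nominal 5% to ≈ 36%
(pure-null cohorts, with no composition shift, stay calibrated at ≈ 5%).
Planted-gene recovery is essentially unaffected (sensitivity ≈ 0.9,
component accuracy ≈ 1.0) because the planted effects dwarf the shift. This
is the standard argument for composition-robust scaling (TMM, median-ratio)
on strongly asymmetric datasets; it is deliberately out of scope here, and
recovery metrics are reported against ground truth so the effect is visible
rather than hidden.

## Problem sizes

Calibration runs use 10,000 genes × 12 samples, recovery runs 2,000 × 12,
unit fixtures 1–1,000 genes; a full pipeline run at these sizes completes in
seconds on one core.
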
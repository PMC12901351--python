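# Methods

## Data model

The unit of evidence is a *study*: several algorithms ("arms") evaluated on
the same participants, each reporting proportions of correctly classified
subjects — accuracy, and optionally sensitivity and specificity — plus
participant counts per clinical group (HC, MCI, AD). Proportions are stored
in [0, 1]; the input scale (percent or fraction) is declared in the loader,
never inferred from magnitudes, because a fraction of 0.9 and a percentage
of 0.9 are both legal.

**Denominators.** Source studies report group sizes, not per-metric
denominators, yet the logit variance needs an *n*. Three policies are
implemented and must be chosen explicitly:

| policy | denominator | rationale |
|---|---|---|
| `task_total` (default) | sum of the groups the diagnostic task compares (HC+AD for AD-vs-HC; all groups for studies that also classify MCI conversion) | accuracy is evaluated on every classified subject of the task |
| `all_total` | all enrolled participants | upper bound; matches studies that classify all groups |
| `metric_group` | cases (AD) for sensitivity, task non-cases for specificity, task total for accuracy | the strict definition of the conditional metrics |

The headline estimates move only slightly across policies (the information
ordering of studies barely changes), which is why the default is a
convention rather than a sensitivity point.

## Effect construction

θ̂ = logit(p) with delta-method variance 1/(n·p·(1−p)) — the standard
variance of a logit-transformed binomial proportion, equivalent to
1/x + 1/(n−x) for the implied counts. At p ∈ {0, 1} the default continuity
correction replaces the implied cells x, n−x by x+0.5, n−x+0.5 and
recomputes both the proportion and the variance (1/x′ + 1/(n′−x′)) from the
corrected cells; it triggers only at the boundary (exactly one cell of the
packaged table, a reported 100% specificity). Disabling the correction
raises rather than propagating infinities.

Within-study arm differences are log odds ratios of correct classification.
Contrasts are stored in lexicographic orientation (treat\_a < treat\_b);
all downstream estimates are orientation-invariant (tested).

**Multi-arm adjustment.** The k(k−1)/2 contrasts of a k-arm study are not
independent. With arm variances v\_a, assigning edge (a, b) the adjusted
variance v\_a·v\_b·Σ\_c 1/v\_c makes the weighted graph Laplacian of the
"independent" edges equal the information matrix of the joint arm-level
least-squares problem *exactly* (for two arms it reduces to v\_a + v\_b).
Tests verify a three-arm study fitted as a network reproduces the direct
arm-level GLS fit to machine precision. Arms evaluated on the same subjects
are in truth positively correlated; like the standard contrast-based
formulation, the model treats the binomial variances as independent — a
`pairing_rho` refinement was considered and deliberately left out because
no study reports the joint classification table needed to identify it.

## Network engine

Fixed (common-effect) stage: weighted least squares of the contrast vector
on the edge-incidence design matrix over non-reference treatments, weights
1/variance, normal equations solved by Moore–Penrose pseudo-inverse (clean
under the rank structure of incidence matrices; reference invariance is
tested to 1e-12). Cochran's Q is the weighted residual sum of squares with
df = Σ(k\_s − 1) − (T − 1): a k-arm study contributes k − 1 independent
contrasts, not k(k−1)/2, which is what makes the two-treatment case
collapse onto the textbook pairwise analysis.

**τ² (DerSimonian–Laird, generalised).** τ² = max(0, (Q − df)/tr(PΔ)),
where P = W − WX(XᵀWX)⁺XᵀW is the residual projection under the fixed
weights and Δ the random-effects structure per unit τ²: study random
effects are modelled as iid arm-level effects with variance τ²/2, so
contrasts of one study correlate ±1/2 when sharing an arm. On two-treatment
data tr(PΔ) reduces exactly to the textbook Σw − Σw²/Σw (tested to 1e-10
against an independently coded pairwise routine). One τ² is shared by the
whole network; the random-effects stage refits with arm variances inflated
by τ²/2, re-deriving the multi-arm adjustment at the inflated values.

Q decomposes by *design* (the set of treatments a study compared):
Q\_within sums each multi-study design's own residual Q (df (m−1)(k−1)),
Q\_between is the remainder. Network I² = max(0, (Q − df)/Q) × 100, with the
conventional four interpretation bands (≤30 unimportant, 30–50 moderate,
50–75 large, >75 important).

**Disconnected networks.** Fitting a disconnected graph is refused with the
component list (estimates across components are meaningless). A
`component=` argument restricts the model to the connected component
containing a named treatment; the packaged evidence needs this (the FFR–NN
study is isolated in the accuracy network, and the CNN/DenseNet/ResNet
cluster is separate from the SVM hub in the sensitivity and specificity
networks).

League tables exponentiate all re-expressed contrasts with Wald 95%
intervals (multiplier 1.96; no Hartung–Knapp, matching the plain-Wald
convention of contrast-based NMA). The contribution matrix reports, per
network comparison, the absolute hat-matrix weights of each direct
comparison, row-normalised to 1.

## Diagnostics

**Node-splitting.** Direct estimate: inverse-variance pooling of the
comparison's own contrasts at the shared network τ². Indirect: the network
refitted with exactly those contrasts removed (other contrasts of a
multi-arm study are kept). Z = (direct − indirect)/√(se\_d² + se\_i²). Only
comparisons with both direct evidence and a surviving indirect path are
splittable; bridges (e.g. every SVM spoke of the packaged accuracy network)
return a flagged "no indirect evidence" result instead of a p-value. On
consistent data the inverse-variance recombination of the two halves
reproduces the full-network estimate (identity tested to 1e-6; it holds to
machine precision).

**Funnel and Egger.** The comparison-adjusted funnel centres every contrast
on its comparison's *fixed-effect* pooled estimate — random-effects
centring would absorb part of the asymmetry being tested. Egger's test is
OLS of effect/se on 1/se with a t test (n − 2 df) on the intercept,
algebraically identical to the 1/se²-weighted regression of effect on se
(tested to 1e-10). *Known limitation:* with several comparisons sharing one
funnel, the centring consumes degrees of freedom the n − 2 t test ignores,
and between-study heterogeneity overdisperses the standardised deviates;
both push the type-I error above nominal (measured ≈ 8–11% at the 5% level
in the calibration experiment below). The directional power property — a
planted effect ∝ se is detected — is unaffected. Interpret small funnel
p-values on heterogeneous networks cautiously.

**P-scores.** P(a) = mean over b ≠ a of Φ(d̂\_ab/se\_ab) from the
random-effects fit, orientation "higher odds of correct classification is
better": the closed-form frequentist analogue of SUCRA. Mean over
treatments is exactly 0.5.

**Descriptive summaries.** Per-algorithm unweighted arithmetic means of the
reported percentages with descending ranks (average ranks on ties, flagged;
display rounding one decimal, half-up; internal values unrounded).
Unweighted means are the deliberate convention for this table — it
describes reported values, not a pooled estimate.

## Synthetic networks

A `SyntheticNetworkSpec` fixes treatments, true basic effects (logit scale,
vs reference), a baseline logit, τ², designs (treatment subset × number of
studies × per-arm denominator) and a seed. Per study: iid arm-level random
effects u ~ N(0, τ²/2) (giving every contrast variance τ² and shared-arm
covariance τ²/2 — exactly the structure the estimator assumes), true arm
proportions expit(baseline + effect + u), binomial counts, reported
proportion x/n. Per-study RNG streams are derived from the root seed by
counter, so extending a spec never perturbs earlier studies. An optional
per-design `inconsistency_shift` plants a logit offset for power studies of
node-splitting.

The generator emulates binomially sampled correct-classification
proportions with additive normal heterogeneity. It does **not** emulate
paired arms on common subjects, selective reporting/publication bias,
covariate-driven heterogeneity, or rounded percentages — so passing
calibration shows the estimator chain is correct *under its own model*, not
that real evidence satisfies that model.

The standard calibration experiment (a consistent 4-treatment network,
τ² = 0.05, 30 two-arm studies, 200 subjects/arm, 1000 replicates — sizes
chosen to keep Monte-Carlo error near ±0.7 percentage points on a rate)
yields 95% CI coverage ≈ 94%, node-splitting rejection ≈ 5%, mean τ̂²
within 1% of truth, and the Egger inflation discussed above.

## Numerical conventions

- Pseudo-inverse tolerance: numpy defaults; design matrices are small
  (≤ tens of treatments).
- τ² truncated at 0; df ≤ 0 or tr(PΔ) ≤ 0 yields τ² = 0 with a
  `tau2_defined=False` flag rather than an error.
- Q = 0 gives I² = 0, not NaN.
- Rounding of implied counts is never needed by the variance formula (it
  uses n·p directly); display rounding is half-up to one decimal.
- Proportions written back to CSV use exact decimal scaling so printed
  percentages round-trip byte-identically.
- All analysis outputs are deterministic; randomness exists only in the
  simulation entry points and is fully seed-derived.
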
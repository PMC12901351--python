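# propnma

Frequentist **network meta-analysis of diagnostic-performance proportions** —
built for evidence syntheses that compare many classification algorithms
(for example machine-learning and deep-learning models that detect
Alzheimer's disease from MRI) when each primary study reports only
proportions: accuracy, sensitivity, specificity, together with participant
counts.

Studies rarely compare all algorithms head to head. `propnma` connects them
through shared comparators: every reported proportion *p* is carried to the
log-odds scale, logit(*p*) = log[*p*/(1 − *p*)], within-study differences
become **log odds ratios of correct classification**, and all treatments are
synthesised jointly on the comparison graph.

## The model

For arm *k* of study *i* with proportion *p\_ik* and denominator *n\_ik*,

- θ̂*\_ik* = logit(*p\_ik*), with delta-method variance
  *v\_ik* = 1/(*n\_ik* · *p\_ik* · (1 − *p\_ik*))
  (a 0.5 continuity correction on both implied cells handles *p* ∈ {0, 1});
- each pair of arms yields a contrast *d* = θ̂*\_a* − θ̂*\_b* (log OR). A
  *k*-arm study's *k*(*k*−1)/2 contrasts get adjusted variances
  *v\_a·v\_b·Σ\_c 1/v\_c*, so jointly they carry exactly the information of
  its *k* arms;
- contrasts are combined by weighted least squares on the edge-incidence
  design matrix (Moore–Penrose solve), giving every treatment's pooled log
  OR versus a reference plus the full covariance;
- between-study variance τ² is the DerSimonian–Laird method of moments
  generalised to networks, τ² = max(0, (Q − df)/tr(PΔ)); the random-effects
  model refits with arm variances inflated by τ²/2;
- heterogeneity/inconsistency is reported as Cochran's Q (decomposed within
  and between designs) and the network I² = max(0, (Q − df)/Q) × 100;
- inconsistency per comparison via **node-splitting** (direct vs indirect,
  Z test), small-study effects via comparison-adjusted funnels and
  **Egger regression**, ranking via closed-form **P-scores**, plus league
  tables and contribution matrices.

A fully specified synthetic-network generator (binomial sampling around
logit-scale effects with normal between-study heterogeneity) supports
calibration experiments for every inferential stage.

## Worked example

The packaged evidence table `table1` holds 10 MRI Alzheimer's-classification
studies (21 arms, 11 algorithms, percentages as printed in the source
studies).

```python
import propnma as P

studies = P.load_fixture("table1")
model = P.NetworkMetaAnalysis.from_studies(
    studies, "accuracy", reference="SVM", component="SVM"
)
res = model.fit("random")
print(res.summary())
```

```
Network meta-analysis of logit-transformed proportions
  model: random effects   reference: SVM
  studies: 9   treatments: 9   contrasts: 11
  tau^2 (DL) = 0.2086   tau^2 used = 0.2086
  Q = 6.080 (df 2)  [within designs 0.701 (df 1), between designs 5.379 (df 1)]
  network I^2 = 67.1%  (large heterogeneity)
```

The accuracy network is disconnected — one study compares FFR with NN and
nothing links that pair to the rest — so `component="SVM"` restricts the fit
to the component containing the reference (9 of the 10 studies). The fit
says: heterogeneity between studies is large (I² = 67%), and the treatment
effects (log ORs vs SVM) favour the deep architectures. A single comparison
back-transforms to an odds ratio:

```python
print(res.odds_ratio("ResNet", "CNN"))
# {'OR': 1.9705, 'ci_low': 0.7794, 'ci_high': 4.9818, 'p_value': 0.1518, ...}
```

ResNet's odds of classifying a subject correctly are about twice CNN's, but
the interval is wide — the comparison rests on one three-arm study plus an
indirect path through DenseNet. Ranking and descriptives:

```python
res.p_scores().head(3)          # DenseNet 0.935, ResNet 0.880, CNN 0.658
P.metric_summary_table(studies) # per-algorithm mean sensitivity/specificity + ranks
```

The same pipeline runs from the shell and writes a complete report bundle
(contrast/league/funnel CSVs, fit and node-split and Egger JSON, network
geometry, figures):

```sh
propnma analyze --fixture table1 --metric accuracy --out report/
propnma summarize
```

Evidence CSVs follow the documented one-row-per-arm schema (`study_id, task,
modality, source, validation, n_hc, n_mci, n_ad, algorithm, accuracy,
sensitivity, specificity`; `NR` marks unreported metrics; the proportion
scale — percent or fraction — is always declared, never guessed). Because
the source studies never state which participants enter each metric's
denominator, three explicit policies are provided (`task_total`, default;
`all_total`; `metric_group`), switchable with `--denominator`.

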
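"""Synthetic diagnostic-accuracy networks with known truth.

The generator is the exact inverse of the fitted model: every study draws
iid arm-level random effects ``u ~ N(0, tau2/2)`` (so any contrast has
between-study variance ``tau2`` and contrasts sharing an arm covary by
``tau2/2``, matching the multi-arm adjustment), forms each arm's true
proportion ``expit(baseline + effect + u)``, and samples the number of
correctly classified subjects binomially.  Output is a list of ordinary
:class:`~propnma.data.StudyRecord` objects, indistinguishable from ingested
evidence, so every inferential stage can be calibration-tested without any
external data.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .data import (
    ArmRecord,
    DataSource,
    DiagnosticTask,
    Metric,
    MetricObservation,
    MriModality,
    StudyRecord,
    resolve_denominator,
)
from .diagnostics import egger_test, funnel_data, node_split, splittable_comparisons
from .model import NetworkMetaAnalysis

__all__ = [
    "DesignSpec",
    "SyntheticNetworkSpec",
    "simulate_network",
    "recovery_experiment",
    "mirror_geometry",
    "default_calibration_spec",
]


class DesignSpec(BaseModel):
    """One design: a treatment subset compared by ``n_studies`` studies,
    each evaluating every arm on ``n_per_arm`` subjects."""

    model_config = {"frozen": True}

    treatments: tuple[str, ...] = Field(min_length=2)
    n_studies: int = Field(ge=1)
    n_per_arm: int = Field(ge=10)
    #: additive logit shift applied to every non-first arm of this design's
    #: studies — a planted inconsistency for power experiments (0 = consistent)
    inconsistency_shift: float = 0.0


class SyntheticNetworkSpec(BaseModel):
    """Generative truth for a synthetic evidence network."""

    model_config = {"frozen": True}

    treatments: tuple[str, ...] = Field(min_length=2)
    reference: str
    true_basic_effects: dict[str, float]  # logit effect vs reference; reference = 0
    baseline_logit: float = 1.0
    tau2_true: float = Field(ge=0.0)
    designs: tuple[DesignSpec, ...] = Field(min_length=1)
    seed: int = 0
    allow_disconnected: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticNetworkSpec":
        if self.reference not in self.treatments:
            raise ValueError("reference must be among treatments")
        unknown = set(self.true_basic_effects) - set(self.treatments)
        if unknown:
            raise ValueError(f"effects given for unknown treatments {sorted(unknown)}")
        covered = {t for d in self.designs for t in d.treatments}
        missing = set(self.treatments) - covered
        if missing:
            raise ValueError(f"treatments in no design: {sorted(missing)}")
        if not self.allow_disconnected:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(self.treatments)
            for d in self.designs:
                ts = list(d.treatments)
                g.add_edges_from(zip(ts, ts[1:]))
            if nx.number_connected_components(g) > 1:
                raise ValueError("design graph is disconnected")
        return self

    def effect(self, treatment: str) -> float:
        if treatment == self.reference:
            return 0.0
        return self.true_basic_effects.get(treatment, 0.0)

    def true_contrast(self, a: str, b: str) -> float:
        return self.effect(a) - self.effect(b)


def simulate_network(spec: SyntheticNetworkSpec) -> list[StudyRecord]:
    """Draw one synthetic evidence base from the spec (reproducible: the
    RNG stream of study *i* depends only on ``spec.seed`` and ``i``)."""
    studies: list[StudyRecord] = []
    counter = 0
    for design in spec.designs:
        for _ in range(design.n_studies):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(counter,))
            )
            n = design.n_per_arm
            u = rng.normal(0.0, math.sqrt(spec.tau2_true / 2.0), len(design.treatments))
            arms = []
            for j, t in enumerate(design.treatments):
                shift = design.inconsistency_shift if j > 0 else 0.0
                p_true = float(expit(spec.baseline_logit + spec.effect(t) + shift + u[j]))
                x = int(rng.binomial(n, p_true))
                arms.append(
                    ArmRecord(
                        algorithm=t,
                        accuracy=MetricObservation(p=x / n, n=n, metric=Metric.accuracy),
                    )
                )
            studies.append(
                StudyRecord(
                    study_id=f"sim{counter:04d}",
                    diagnostic_task=DiagnosticTask.AD_vs_HC,
                    mri_modality=MriModality.T1,
                    data_source=DataSource.ADNI,
                    validation_strategy="NR",
                    n_hc=n // 2,
                    n_mci=0,
                    n_ad=n - n // 2,
                    arms=tuple(arms),
                )
            )
            counter += 1
    return studies


def mirror_geometry(
    studies: Sequence[StudyRecord],
    metric: Metric | str = Metric.accuracy,
    *,
    reference: str = "SVM",
    true_basic_effects: Optional[dict[str, float]] = None,
    tau2_true: float = 0.0,
    seed: int = 0,
) -> SyntheticNetworkSpec:
    """Spec whose designs and denominators copy an existing evidence base."""
    metric = Metric(metric)
    designs = []
    treatments: set[str] = set()
    for s in studies:
        arms = s.arms_with(metric)
        if len(arms) < 2:
            continue
        labels = tuple(sorted(a.algorithm for a in arms))
        treatments.update(labels)
        designs.append(
            DesignSpec(
                treatments=labels,
                n_studies=1,
                n_per_arm=resolve_denominator(s, metric, "task_total"),
            )
        )
    return SyntheticNetworkSpec(
        treatments=tuple(sorted(treatments)),
        reference=reference if reference in treatments else sorted(treatments)[0],
        true_basic_effects=true_basic_effects or {},
        tau2_true=tau2_true,
        designs=tuple(designs),
        seed=seed,
        allow_disconnected=True,
    )


def default_calibration_spec(
    tau2_true: float = 0.05,
    n_studies: int = 30,
    n_per_arm: int = 200,
    seed: int = 0,
) -> SyntheticNetworkSpec:
    """Consistent four-treatment network used by the calibration experiments:
    a triangle-plus-spoke geometry with moderate true effects."""
    per = [
        ("A", "B"), ("A", "C"), ("B", "C"), ("A", "D"), ("B", "D"), ("C", "D"),
    ]
    base = n_studies // len(per)
    extra = n_studies - base * len(per)
    designs = []
    for i, pair in enumerate(per):
        k = base + (1 if i < extra else 0)
        if k > 0:
            designs.append(DesignSpec(treatments=pair, n_studies=k, n_per_arm=n_per_arm))
    return SyntheticNetworkSpec(
        treatments=("A", "B", "C", "D"),
        reference="A",
        true_basic_effects={"B": 0.3, "C": 0.6, "D": 0.9},
        baseline_logit=0.8,
        tau2_true=tau2_true,
        designs=tuple(designs),
        seed=seed,
    )


def recovery_experiment(
    spec: SyntheticNetworkSpec,
    replicates: int,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    do_nodesplit: bool = True,
    do_egger: bool = True,
    metric: Metric | str = Metric.accuracy,
) -> dict:
    """Run the full pipeline on ``replicates`` fresh draws and report
    calibration: per-contrast 95% CI coverage, the tau-hat^2 distribution,
    node-splitting rejection rate, and Egger type-I rate, each with its
    binomial Monte-Carlo standard error."""
    if replicates < 100:
        raise ValueError("rate estimates need >= 100 replicates")
    non_ref = [t for t in spec.treatments if t != spec.reference]
    covered = {t: 0 for t in non_ref}
    tau2_hats = []
    ns_tests = 0
    ns_rejects = 0
    egger_tests = 0
    egger_rejects = 0
    split_pair: Optional[tuple[str, str]] = None
    for rep in range(replicates):
        rep_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)).generate_state(1)[0] % (2**31))
        studies = simulate_network(spec.model_copy(update={"seed": rep_seed}))
        model = NetworkMetaAnalysis.from_studies(
            studies, metric, reference=spec.reference, component=spec.reference
        )
        res = model.fit("random")
        tau2_hats.append(res.tau2_dl)
        for t in non_ref:
            est, se = res.contrast(t, spec.reference)
            lo, hi = est - 1.96 * se, est + 1.96 * se
            truth = spec.true_contrast(t, spec.reference)
            covered[t] += int(lo <= truth <= hi)
        if do_nodesplit:
            if split_pair is None:
                pairs = splittable_comparisons(model)
                split_pair = pairs[0] if pairs else None
            if split_pair is not None:
                ns = node_split(model, split_pair, tau2=res.tau2)
                if ns.splittable:
                    ns_tests += 1
                    ns_rejects += int(ns.p < alpha)
        if do_egger:
            points = funnel_data(model)
            if len(points) >= 3:
                egger_tests += 1
                egger_rejects += int(egger_test(points).p < alpha)
    tau2_hats_arr = np.array(tau2_hats)

    def rate(k: int, n: int) -> dict:
        if n == 0:
            return {"rate": float("nan"), "mc_se": float("nan"), "n": 0}
        r = k / n
        return {"rate": r, "mc_se": math.sqrt(r * (1 - r) / n), "n": n}

    return {
        "replicates": replicates,
        "coverage": {
            t: rate(covered[t], replicates) for t in non_ref
        },
        "tau2": {
            "true": spec.tau2_true,
            "mean": float(tau2_hats_arr.mean()),
            "median": float(np.median(tau2_hats_arr)),
            "zero_fraction": float((tau2_hats_arr == 0).mean()),
        },
        "node_split": rate(ns_rejects, ns_tests),
        "egger": rate(egger_rejects, egger_tests),
        "alpha": alpha,
    }
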
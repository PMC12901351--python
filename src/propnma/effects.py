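"""Logit transforms and within-study pairwise contrasts (log odds ratios).

A reported proportion ``p`` with denominator ``n`` is carried to the log-odds
scale, ``theta = log(p / (1 - p))``, with the delta-method binomial variance
``1 / (n p (1 - p))`` (equivalently ``1/x + 1/(n - x)`` for the implied
counts).  Differences of two arms' thetas within a study are log odds ratios
of correct classification and are the effect measure of the whole analysis.

Multi-arm studies contribute all pairwise contrasts, but those contrasts are
not independent: the standard error of each contrast is inflated so that the
``k (k - 1) / 2`` contrasts of a ``k``-arm study jointly carry exactly the
information of its ``k`` arms.  For arm-level variances ``v_a`` the adjusted
contrast variance is ``v_a * v_b * sum_c 1/v_c`` (which reduces to
``v_a + v_b`` for two arms); the weighted graph Laplacian built from these
independent edge weights then equals the information matrix of the joint
arm-level least-squares problem exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .data import (
    DenominatorPolicy,
    Metric,
    MetricObservation,
    StudyRecord,
    resolve_denominator,
)

__all__ = [
    "TransformedEffect",
    "PairwiseContrast",
    "NonFiniteLogitError",
    "logit_with_se",
    "build_contrasts",
    "contrasts_from_studies",
    "contrasts_to_frame",
]


class NonFiniteLogitError(ValueError):
    """A proportion of 0 or 1 reached the logit with correction disabled."""


@dataclass(frozen=True)
class TransformedEffect:
    """A proportion on the log-odds scale with its delta-method variance."""

    theta: float
    se: float
    source: tuple[str, str, str]  # (study_id, algorithm, metric)

    @property
    def var(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class PairwiseContrast:
    """A within-study log odds ratio between two algorithms.

    ``effect = theta_a - theta_b`` (log OR of correct classification, a vs
    b).  Storage orientation is lexicographic, ``treat_a < treat_b``.
    ``var_a``/``var_b`` are the two arms' logit variances and
    ``study_arm_vars`` the variances of *all* arms of the study carrying the
    metric; they allow the multi-arm variance adjustment to be re-derived at
    any between-study variance tau2 (arm variances inflate by ``tau2 / 2``).
    """

    study_id: str
    treat_a: str
    treat_b: str
    metric: str
    effect: float
    var_a: float
    var_b: float
    study_arm_vars: tuple[float, ...]

    @property
    def multiarm(self) -> bool:
        return len(self.study_arm_vars) > 2

    def adjusted_var(self, tau2: float = 0.0) -> float:
        """Contrast variance after multi-arm adjustment at heterogeneity tau2."""
        va = self.var_a + tau2 / 2.0
        vb = self.var_b + tau2 / 2.0
        if not self.multiarm:
            return va + vb
        s = sum(1.0 / (v + tau2 / 2.0) for v in self.study_arm_vars)
        return va * vb * s

    @property
    def se(self) -> float:
        """Adjusted standard error at tau2 = 0."""
        return math.sqrt(self.adjusted_var(0.0))

    def reversed(self) -> "PairwiseContrast":
        return replace(
            self,
            treat_a=self.treat_b,
            treat_b=self.treat_a,
            effect=-self.effect,
            var_a=self.var_b,
            var_b=self.var_a,
        )


def logit_with_se(
    obs: MetricObservation,
    *,
    correction: Literal["halves", "none"] = "halves",
) -> TransformedEffect:
    """Logit-transform one observation with its delta-method standard error.

    At ``p`` of exactly 0 or 1 the logit and its variance are infinite; the
    default continuity correction adds 0.5 to both implied cells (``x`` and
    ``n - x``) and recomputes ``p`` and the variance ``1/x' + 1/(n' - x')``
    from the corrected counts.
    """
    if obs.n <= 0:
        raise ValueError("denominator must be positive")
    p, n = obs.p, float(obs.n)
    source = ("", "", obs.metric.value)
    if p in (0.0, 1.0):
        if correction == "none":
            raise NonFiniteLogitError(
                f"proportion {p} yields a non-finite logit and correction is disabled"
            )
        x = p * n  # exactly 0 or n
        x_corr, n_corr = x + 0.5, n + 1.0
        p_corr = x_corr / n_corr
        theta = math.log(p_corr / (1.0 - p_corr))
        var = 1.0 / x_corr + 1.0 / (n_corr - x_corr)
        return TransformedEffect(theta=theta, se=math.sqrt(var), source=source)
    theta = math.log(p / (1.0 - p))
    var = 1.0 / (n * p * (1.0 - p))
    return TransformedEffect(theta=theta, se=math.sqrt(var), source=source)


def build_contrasts(
    study: StudyRecord,
    metric: Metric | str,
    *,
    denominator_policy: Optional[DenominatorPolicy] = None,
    correction: Literal["halves", "none"] = "halves",
) -> list[PairwiseContrast]:
    """All pairwise log-OR contrasts of one study for one metric.

    Arms lacking the metric are ignored; fewer than two arms with the metric
    yield an empty list.  When ``denominator_policy`` is given, metric
    denominators are re-resolved from the study's group counts (overriding
    the denominators stored at load time).
    """
    metric = Metric(metric)
    arms = study.arms_with(metric)
    if len(arms) < 2:
        return []
    transformed: dict[str, TransformedEffect] = {}
    for arm in arms:
        obs = arm.observation(metric)
        assert obs is not None
        if denominator_policy is not None:
            n = resolve_denominator(study, metric, denominator_policy)
            obs = MetricObservation(p=obs.p, n=n, metric=metric)
        te = logit_with_se(obs, correction=correction)
        transformed[arm.algorithm] = TransformedEffect(
            theta=te.theta,
            se=te.se,
            source=(study.study_id, arm.algorithm, metric.value),
        )
    arm_vars = tuple(te.var for te in transformed.values())
    out = []
    for a, b in combinations(sorted(transformed), 2):
        out.append(
            PairwiseContrast(
                study_id=study.study_id,
                treat_a=a,
                treat_b=b,
                metric=metric.value,
                effect=transformed[a].theta - transformed[b].theta,
                var_a=transformed[a].var,
                var_b=transformed[b].var,
                study_arm_vars=arm_vars,
            )
        )
    return out


def contrasts_from_studies(
    studies: Iterable[StudyRecord],
    metric: Metric | str,
    *,
    denominator_policy: Optional[DenominatorPolicy] = None,
    correction: Literal["halves", "none"] = "halves",
) -> list[PairwiseContrast]:
    """Concatenate :func:`build_contrasts` over an evidence base."""
    out: list[PairwiseContrast] = []
    for study in studies:
        out.extend(
            build_contrasts(
                study, metric,
                denominator_policy=denominator_policy, correction=correction,
            )
        )
    return out


def contrasts_to_frame(contrasts: Sequence[PairwiseContrast]) -> pd.DataFrame:
    """Contrast list as a tidy table (exportable as CSV)."""
    return pd.DataFrame(
        {
            "study_id": [c.study_id for c in contrasts],
            "treat_a": [c.treat_a for c in contrasts],
            "treat_b": [c.treat_b for c in contrasts],
            "metric": [c.metric for c in contrasts],
            "logOR": [c.effect for c in contrasts],
            "se": [c.se for c in contrasts],
            "multiarm": [c.multiarm for c in contrasts],
        }
    )
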
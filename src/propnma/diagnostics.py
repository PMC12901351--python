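"""Inconsistency and small-study-effect diagnostics.

Node-splitting separates one comparison's direct evidence (its own studies,
pooled pairwise under the shared network tau^2) from the indirect remainder
(the network refitted with those direct contrasts removed) and tests their
disagreement with a Z statistic.  Small-study effects are assessed on a
comparison-adjusted funnel plot — every contrast centred on its own
comparison's fixed-effect pooled estimate so all comparisons share one
funnel — and with Egger's regression of the standardised effect on
precision, testing the intercept with a t statistic on n - 2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import PairwiseContrast
from .model import DisconnectedNetworkError, NetworkMetaAnalysis, UnderdeterminedNetworkError

__all__ = [
    "NodeSplitResult",
    "EggerResult",
    "node_split",
    "node_split_all",
    "splittable_comparisons",
    "funnel_data",
    "egger_test",
]


@dataclass(frozen=True)
class NodeSplitResult:
    comparison: tuple[str, str]
    direct_effect: float
    direct_se: float
    indirect_effect: Optional[float]
    indirect_se: Optional[float]
    z: Optional[float]
    p: Optional[float]
    note: str = ""

    @property
    def splittable(self) -> bool:
        return self.z is not None

    def to_dict(self) -> dict:
        return {
            "treat_a": self.comparison[0],
            "treat_b": self.comparison[1],
            "direct_effect": self.direct_effect,
            "direct_se": self.direct_se,
            "indirect_effect": self.indirect_effect,
            "indirect_se": self.indirect_se,
            "z": self.z,
            "p": self.p,
            "note": self.note,
        }


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    t: float
    p: float
    n_contrasts: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "slope": self.slope,
            "t": self.t,
            "p": self.p,
            "n_contrasts": self.n_contrasts,
        }


def _oriented(c: PairwiseContrast, a: str, b: str) -> float:
    return c.effect if (c.treat_a, c.treat_b) == (a, b) else -c.effect


def node_split(
    model: NetworkMetaAnalysis,
    comparison: tuple[str, str],
    tau2: Optional[float] = None,
) -> NodeSplitResult:
    """Direct-versus-indirect disagreement for one comparison.

    The direct estimate pools the comparison's own contrasts by inverse
    variance at the shared network ``tau2`` (defaulting to the network DL
    estimate).  The indirect estimate refits the network with exactly those
    contrasts removed; contrasts of multi-arm studies that involve other
    treatment pairs are retained.
    """
    a, b = comparison
    pair = frozenset(comparison)
    if tau2 is None:
        tau2 = model.fit("random").tau2
    direct = [c for c in model.contrasts if frozenset((c.treat_a, c.treat_b)) == pair]
    if not direct:
        return NodeSplitResult((a, b), math.nan, math.nan, None, None, None, None,
                               note="no direct evidence")
    w = np.array([1.0 / c.adjusted_var(tau2) for c in direct])
    d = np.array([_oriented(c, a, b) for c in direct])
    direct_effect = float(np.sum(w * d) / np.sum(w))
    direct_se = float(1.0 / math.sqrt(np.sum(w)))

    rest = [c for c in model.contrasts if frozenset((c.treat_a, c.treat_b)) != pair]
    try:
        sub = NetworkMetaAnalysis(rest, reference=model.reference)
    except (DisconnectedNetworkError, UnderdeterminedNetworkError):
        return NodeSplitResult((a, b), direct_effect, direct_se, None, None, None, None,
                               note="no indirect evidence")
    if a not in sub.treatments or b not in sub.treatments:
        return NodeSplitResult((a, b), direct_effect, direct_se, None, None, None, None,
                               note="no indirect evidence")
    res = sub.fit("random", tau2=tau2)
    ind_effect, ind_se = res.contrast(a, b)
    z = (direct_effect - ind_effect) / math.sqrt(direct_se**2 + ind_se**2)
    p = 2 * stats.norm.sf(abs(z))
    return NodeSplitResult((a, b), direct_effect, direct_se, ind_effect, ind_se,
                           float(z), float(p))


def splittable_comparisons(model: NetworkMetaAnalysis) -> list[tuple[str, str]]:
    """Comparisons with direct evidence and an indirect path after removal."""
    out = []
    edges = sorted({(c.treat_a, c.treat_b) for c in model.contrasts})
    for a, b in edges:
        rest = [c for c in model.contrasts
                if frozenset((c.treat_a, c.treat_b)) != frozenset((a, b))]
        g = {t for c in rest for t in (c.treat_a, c.treat_b)}
        if a in g and b in g:
            import networkx as nx
            graph = nx.Graph((c.treat_a, c.treat_b) for c in rest)
            if nx.has_path(graph, a, b):
                out.append((a, b))
    return out


def node_split_all(
    model: NetworkMetaAnalysis, tau2: Optional[float] = None
) -> pd.DataFrame:
    """Node-splitting table over every splittable comparison."""
    if tau2 is None:
        tau2 = model.fit("random").tau2
    rows = [node_split(model, cmp, tau2=tau2).to_dict()
            for cmp in splittable_comparisons(model)]
    return pd.DataFrame(rows)


def funnel_data(model: NetworkMetaAnalysis) -> pd.DataFrame:
    """Comparison-adjusted funnel points: one row per contrast.

    Centring uses each comparison's fixed-effect pooled estimate, so the
    asymmetry under test is not absorbed into the centring.
    """
    edges: dict[tuple[str, str], list[PairwiseContrast]] = {}
    for c in model.contrasts:
        edges.setdefault((c.treat_a, c.treat_b), []).append(c)
    rows = []
    for (a, b), group in sorted(edges.items()):
        w = np.array([1.0 / c.adjusted_var(0.0) for c in group])
        d = np.array([c.effect for c in group])
        pooled = float(np.sum(w * d) / np.sum(w))
        for c in group:
            rows.append(
                {
                    "study_id": c.study_id,
                    "comparison": f"{a} vs {b}",
                    "effect": c.effect - pooled,
                    "se": c.se,
                }
            )
    return pd.DataFrame(rows)


def egger_test(points: pd.DataFrame) -> EggerResult:
    """Egger's regression test for funnel asymmetry.

    Ordinary least squares of the standardised centred effect
    (``effect / se``) on precision (``1 / se``); the intercept's deviation
    from zero is tested with a t statistic on n - 2 degrees of freedom.
    Algebraically identical to the weighted (1/se^2) regression of effect
    on se.
    """
    if len(points) < 3:
        raise ValueError("insufficient contrasts for Egger regression (need >= 3)")
    y = np.asarray(points["effect"], dtype=float) / np.asarray(points["se"], dtype=float)
    x = 1.0 / np.asarray(points["se"], dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 2
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_int = math.sqrt(s2 * xtx_inv[0, 0])
    if se_int > 0:
        t = coef[0] / se_int
        p = 2 * stats.t.sf(abs(t), dof)
    else:  # exact fit: intercept either exactly 0 or unambiguously nonzero
        t = 0.0 if coef[0] == 0 else math.copysign(math.inf, coef[0])
        p = 1.0 if coef[0] == 0 else 0.0
    return EggerResult(
        intercept=float(coef[0]),
        intercept_se=se_int,
        slope=float(coef[1]),
        t=float(t),
        p=float(p),
        n_contrasts=n,
    )
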
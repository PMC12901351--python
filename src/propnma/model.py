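"""Frequentist network meta-analysis on the log-odds-ratio scale.

The model is the graph-theoretical weighted least-squares formulation: each
pairwise contrast is an edge observation ``d_i = X_i beta + e_i`` on the
treatment graph, where ``beta`` holds the basic parameters (log ORs of every
treatment versus a reference) and the weights are inverse adjusted contrast
variances.  The normal equations are solved with a Moore-Penrose
pseudo-inverse, which handles the rank deficiency of the incidence structure
cleanly and makes estimates invariant to the reference choice up to
re-expression.

Heterogeneity is quantified by Cochran's Q of the fixed (common-effect) fit,
decomposed into within- and between-design parts, by the network I^2
statistic ``max(0, (Q - df) / Q) * 100``, and by the between-study variance
tau^2 estimated with the DerSimonian-Laird-type method of moments
generalised to networks: ``tau2 = max(0, (Q - df) / c)`` with
``c = tr(P Delta)``, where ``P`` is the weighted residual-projection matrix
of the fixed fit and ``Delta`` the correlation structure of study random
effects (1 on the diagonal, +-1/2 between contrasts of the same study
sharing an arm).  The random-effects model refits the same least squares
with arm variances inflated by ``tau2 / 2`` (so two-arm contrast variances
gain ``tau2`` and the multi-arm adjustment is re-derived at the inflated
variances).  A single tau^2 is shared by all comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import DenominatorPolicy, Metric, StudyRecord
from .effects import PairwiseContrast, contrasts_from_studies

__all__ = [
    "NetworkMetaAnalysis",
    "NMAResults",
    "DisconnectedNetworkError",
    "UnderdeterminedNetworkError",
    "heterogeneity_band",
]

_BANDS = [
    (30.0, "unimportant heterogeneity"),
    (50.0, "moderate heterogeneity"),
    (75.0, "large heterogeneity"),
    (100.0, "important heterogeneity"),
]


def heterogeneity_band(i2: float) -> str:
    """Qualitative label for a network I^2 percentage (four fixed bands)."""
    for upper, label in _BANDS:
        if i2 <= upper:
            return label
    raise ValueError(f"I^2 must lie in [0, 100], got {i2}")


class DisconnectedNetworkError(ValueError):
    def __init__(self, components: Sequence[set[str]]):
        self.components = [set(c) for c in components]
        super().__init__(
            "treatment network is disconnected; components: "
            + "; ".join(sorted("{" + ", ".join(sorted(c)) + "}" for c in self.components))
        )


class UnderdeterminedNetworkError(ValueError):
    pass


class NetworkMetaAnalysis:
    """Network meta-analysis model over a list of pairwise contrasts.

    Parameters
    ----------
    contrasts
        Within-study log-OR contrasts (see :mod:`propnma.effects`).
    reference
        Reference treatment for the basic parameters.  Defaults to ``SVM``,
        the hub of the packaged evidence network.
    component
        How to handle a disconnected treatment graph: ``None`` raises
        :class:`DisconnectedNetworkError`; a treatment label restricts the
        model to the connected component containing that label (the
        reference is moved into the component if necessary).
    """

    def __init__(
        self,
        contrasts: Sequence[PairwiseContrast],
        *,
        reference: str = "SVM",
        component: Optional[str] = None,
    ):
        if not contrasts:
            raise UnderdeterminedNetworkError("no contrasts supplied")
        graph = nx.Graph()
        for c in contrasts:
            graph.add_edge(c.treat_a, c.treat_b)
        comps = list(nx.connected_components(graph))
        if len(comps) > 1:
            if component is None:
                raise DisconnectedNetworkError(comps)
            anchor = component if component in graph else reference
            keep = next(c for c in comps if anchor in c)
            contrasts = [c for c in contrasts if c.treat_a in keep]
            graph = graph.subgraph(keep).copy()
        self.contrasts: list[PairwiseContrast] = list(contrasts)
        self.graph = graph
        self.treatments: list[str] = sorted(graph.nodes)
        if reference not in graph:
            reference = self.treatments[0]
        self.reference = reference
        # independent contrasts: k - 1 per study design, not k(k-1)/2
        study_arms: dict[str, set[str]] = {}
        for c in self.contrasts:
            study_arms.setdefault(c.study_id, set()).update((c.treat_a, c.treat_b))
        self.n_studies = len(study_arms)
        self.n_independent = sum(len(a) - 1 for a in study_arms.values())
        if self.n_independent < len(self.treatments) - 1:
            raise UnderdeterminedNetworkError(
                f"{self.n_independent} independent contrasts cannot identify "
                f"{len(self.treatments) - 1} basic parameters"
            )
        self._study_arms = study_arms

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_studies(
        cls,
        studies: Sequence[StudyRecord],
        metric: Metric | str,
        *,
        reference: str = "SVM",
        component: Optional[str] = None,
        denominator_policy: Optional[DenominatorPolicy] = None,
        correction: Literal["halves", "none"] = "halves",
    ) -> "NetworkMetaAnalysis":
        """Build the model straight from an evidence base for one metric."""
        contrasts = contrasts_from_studies(
            studies, metric,
            denominator_policy=denominator_policy, correction=correction,
        )
        return cls(contrasts, reference=reference, component=component)

    # -- linear algebra ------------------------------------------------------

    def _design(self) -> np.ndarray:
        """Edge-incidence design matrix over non-reference treatments."""
        non_ref = [t for t in self.treatments if t != self.reference]
        idx = {t: j for j, t in enumerate(non_ref)}
        X = np.zeros((len(self.contrasts), len(non_ref)))
        for i, c in enumerate(self.contrasts):
            if c.treat_a != self.reference:
                X[i, idx[c.treat_a]] = 1.0
            if c.treat_b != self.reference:
                X[i, idx[c.treat_b]] = -1.0
        return X

    def _weights(self, tau2: float) -> np.ndarray:
        return np.array([1.0 / c.adjusted_var(tau2) for c in self.contrasts])

    def _wls(self, tau2: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        X = self._design()
        w = self._weights(tau2)
        d = np.array([c.effect for c in self.contrasts])
        A = X.T @ (w[:, None] * X)
        vcov = np.linalg.pinv(A)
        beta = vcov @ X.T @ (w * d)
        resid = d - X @ beta
        q = float(resid @ (w * resid))
        return beta, vcov, X, q

    def _delta(self) -> np.ndarray:
        """Random-effect correlation structure across contrasts.

        Study random effects act as iid arm-level effects with variance
        tau2/2, so contrasts of one study correlate +-1/2 when sharing an
        arm; contrasts of different studies are independent.
        """
        m = len(self.contrasts)
        D = np.zeros((m, m))
        for i, ci in enumerate(self.contrasts):
            for j, cj in enumerate(self.contrasts):
                if ci.study_id != cj.study_id:
                    continue
                D[i, j] = 0.5 * (
                    (ci.treat_a == cj.treat_a) + (ci.treat_b == cj.treat_b)
                    - (ci.treat_a == cj.treat_b) - (ci.treat_b == cj.treat_a)
                )
        return D

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        method: Literal["random", "fixed"] = "random",
        tau2: Optional[float] = None,
    ) -> "NMAResults":
        """Fit the model.

        ``method='fixed'`` is the common-effect (tau2 = 0) weighted least
        squares; ``method='random'`` first runs the fixed stage, estimates
        tau2 by the DL method of moments (unless ``tau2`` is supplied), and
        refits at the inflated variances.
        """
        beta0, vcov0, X, q_total = self._wls(0.0)
        df = self.n_independent - (len(self.treatments) - 1)
        tau2_dl, dl_defined = self._tau2_dl(q_total, df, X)
        q_within, q_between, df_within, df_between = self._q_decomposition()
        i2 = max(0.0, (q_total - df) / q_total) * 100.0 if q_total > 0 else 0.0
        if method == "fixed":
            used_tau2 = 0.0 if tau2 is None else float(tau2)
        else:
            used_tau2 = tau2_dl if tau2 is None else float(tau2)
        if used_tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if used_tau2 > 0:
            beta, vcov, _, _ = self._wls(used_tau2)
        else:
            beta, vcov = beta0, vcov0
        return NMAResults(
            model=self,
            method=method,
            tau2=used_tau2,
            tau2_dl=tau2_dl,
            tau2_defined=dl_defined,
            _beta=beta,
            _vcov=vcov,
            Q_total=q_total,
            Q_within_design=q_within,
            Q_between_design=q_between,
            df_total=df,
            df_within=df_within,
            df_between=df_between,
            I2_network=i2,
        )

    def _tau2_dl(self, q_total: float, df: int, X: np.ndarray) -> tuple[float, bool]:
        if df <= 0:
            return 0.0, False
        w = self._weights(0.0)
        W = np.diag(w)
        H = X @ np.linalg.pinv(X.T @ W @ X) @ X.T @ W
        P = W - W @ H
        c = float(np.trace(P @ self._delta()))
        if c <= 0:
            return 0.0, False
        return max(0.0, (q_total - df) / c), True

    def _q_decomposition(self) -> tuple[float, float, int, int]:
        """Split Q into within-design and between-design parts.

        A design is the set of treatments a study compared.  Within each
        design with >= 2 studies, a design-specific fixed fit absorbs the
        design's own mean effects; its residual Q sums to Q_within.
        """
        designs: dict[frozenset, list[str]] = {}
        for sid, arms in self._study_arms.items():
            designs.setdefault(frozenset(arms), []).append(sid)
        q_within = 0.0
        df_within = 0
        for design, sids in designs.items():
            if len(sids) < 2:
                continue
            sub = [c for c in self.contrasts if c.study_id in sids]
            model = NetworkMetaAnalysis.__new__(NetworkMetaAnalysis)
            model.contrasts = sub
            model.treatments = sorted(design)
            model.reference = model.treatments[0]
            _, _, _, q = NetworkMetaAnalysis._wls(model, 0.0)
            q_within += q
            df_within += (len(sids) - 1) * (len(design) - 1)
        _, _, _, q_total = self._wls(0.0)
        df_total = self.n_independent - (len(self.treatments) - 1)
        return q_within, max(0.0, q_total - q_within), df_within, df_total - df_within

    # -- geometry ------------------------------------------------------------

    def geometry(self) -> dict:
        """Network diagram data: nodes with arm counts, edges with study counts."""
        node_arms = {t: 0 for t in self.treatments}
        for arms in self._study_arms.values():
            for t in arms:
                node_arms[t] += 1
        edge_studies: dict[tuple[str, str], set[str]] = {}
        for c in self.contrasts:
            edge_studies.setdefault((c.treat_a, c.treat_b), set()).add(c.study_id)
        return {
            "nodes": [{"treatment": t, "n_studies": node_arms[t]} for t in self.treatments],
            "edges": [
                {"treat_a": a, "treat_b": b, "n_studies": len(s)}
                for (a, b), s in sorted(edge_studies.items())
            ],
            "reference": self.reference,
        }

    def to_dot(self) -> str:
        """Network geometry in Graphviz DOT form (edge width ~ study count)."""
        g = self.geometry()
        lines = ["graph network {", "  node [shape=circle];"]
        for node in g["nodes"]:
            lines.append(f'  "{node["treatment"]}" [label="{node["treatment"]}\\n{node["n_studies"]}"];')
        for e in g["edges"]:
            lines.append(
                f'  "{e["treat_a"]}" -- "{e["treat_b"]}" '
                f'[label="{e["n_studies"]}", penwidth={e["n_studies"]}];'
            )
        lines.append("}")
        return "\n".join(lines)


@dataclass
class NMAResults:
    """Fitted network meta-analysis: estimates, uncertainty, heterogeneity."""

    model: NetworkMetaAnalysis
    method: str
    tau2: float
    tau2_dl: float
    tau2_defined: bool
    _beta: np.ndarray = field(repr=False)
    _vcov: np.ndarray = field(repr=False)
    Q_total: float
    Q_within_design: float
    Q_between_design: float
    df_total: int
    df_within: int
    df_between: int
    I2_network: float

    # -- basic accessors -----------------------------------------------------

    @property
    def treatments(self) -> list[str]:
        return self.model.treatments

    @property
    def reference(self) -> str:
        return self.model.reference

    @property
    def heterogeneity_band(self) -> str:
        return heterogeneity_band(self.I2_network)

    @property
    def effects(self) -> pd.Series:
        """Log OR of each treatment versus the reference (reference = 0)."""
        non_ref = [t for t in self.treatments if t != self.reference]
        s = pd.Series(0.0, index=self.treatments, name="logOR_vs_ref")
        s[non_ref] = self._beta
        return s

    @property
    def vcov(self) -> pd.DataFrame:
        """Covariance of the effects (reference row/column identically 0)."""
        out = pd.DataFrame(0.0, index=self.treatments, columns=self.treatments)
        non_ref = [t for t in self.treatments if t != self.reference]
        out.loc[non_ref, non_ref] = self._vcov
        return out

    def contrast(self, treat_a: str, treat_b: str) -> tuple[float, float]:
        """Pooled log OR (a vs b) and its standard error from the fit."""
        eff = self.effects
        v = self.vcov
        est = eff[treat_a] - eff[treat_b]
        var = v.loc[treat_a, treat_a] + v.loc[treat_b, treat_b] - 2 * v.loc[treat_a, treat_b]
        return float(est), math.sqrt(max(var, 0.0))

    def odds_ratio(self, treat_a: str, treat_b: str, alpha: float = 0.05):
        """Back-transformed pooled OR with Wald CI and two-sided p-value."""
        est, se = self.contrast(treat_a, treat_b)
        z = stats.norm.ppf(1 - alpha / 2)
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
        else:
            p = 2 * stats.norm.sf(abs(est) / se)
        return {
            "OR": math.exp(est),
            "ci_low": math.exp(est - z * se),
            "ci_high": math.exp(est + z * se),
            "p_value": p,
            "logOR": est,
            "se": se,
        }

    # -- league table ----------------------------------------------------------

    def league_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Long-format league table of all row-vs-column odds ratios."""
        rows = []
        for a in self.treatments:
            for b in self.treatments:
                entry = self.odds_ratio(a, b, alpha=alpha)
                rows.append({"treat_a": a, "treat_b": b, **entry})
        return pd.DataFrame(rows)

    def league_matrix(self) -> pd.DataFrame:
        """Square OR matrix (row vs column)."""
        mat = pd.DataFrame(1.0, index=self.treatments, columns=self.treatments)
        for a in self.treatments:
            for b in self.treatments:
                mat.loc[a, b] = math.exp(self.effects[a] - self.effects[b])
        return mat

    # -- ranking ---------------------------------------------------------------

    def p_scores(self) -> pd.DataFrame:
        """Frequentist P-scores (higher log OR of correct classification = better).

        P-score of treatment a is the mean over competitors b of
        Phi((d_ab) / se_ab): the average certainty that a outperforms b.
        Mean over treatments is exactly 0.5.
        """
        if len(self.treatments) < 2:
            raise ValueError("P-scores need at least two treatments")
        scores = {}
        for a in self.treatments:
            probs = []
            for b in self.treatments:
                if b == a:
                    continue
                est, se = self.contrast(a, b)
                probs.append(float(stats.norm.cdf(est / se)) if se > 0 else (1.0 if est > 0 else 0.0 if est < 0 else 0.5))
            scores[a] = float(np.mean(probs))
        out = pd.DataFrame({"p_score": pd.Series(scores)})
        out["rank"] = out["p_score"].rank(ascending=False, method="average")
        return out.sort_values("p_score", ascending=False)

    # -- contribution matrix ---------------------------------------------------

    def contribution_matrix(self) -> pd.DataFrame:
        """Proportional contribution of each direct comparison to each network estimate.

        Rows are all network comparisons, columns the direct comparisons
        (edges with data).  Entries are absolute hat-matrix weights
        aggregated per edge and normalised so every row sums to 1.
        """
        model = self.model
        X = model._design()
        w = model._weights(self.tau2)
        A_inv = np.linalg.pinv(X.T @ (w[:, None] * X))
        non_ref = [t for t in model.treatments if t != model.reference]
        idx = {t: j for j, t in enumerate(non_ref)}
        edges = sorted({(c.treat_a, c.treat_b) for c in model.contrasts})
        edge_col = {e: j for j, e in enumerate(edges)}
        rows = []
        labels = []
        for a, b in combinations(model.treatments, 2):
            cvec = np.zeros(len(non_ref))
            if a != model.reference:
                cvec[idx[a]] = 1.0
            if b != model.reference:
                cvec[idx[b]] = -1.0
            h = (cvec @ A_inv @ X.T) * w  # estimate = h . d
            contrib = np.zeros(len(edges))
            for i, c in enumerate(model.contrasts):
                contrib[edge_col[(c.treat_a, c.treat_b)]] += abs(h[i])
            total = contrib.sum()
            rows.append(contrib / total if total > 0 else contrib)
            labels.append(f"{a} vs {b}")
        return pd.DataFrame(
            rows, index=labels, columns=[f"{a} vs {b}" for a, b in edges]
        )

    # -- summary ---------------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Per-treatment effects versus the reference with Wald 95% CIs."""
        eff = self.effects
        se = pd.Series(
            [math.sqrt(max(self.vcov.loc[t, t], 0.0)) for t in self.treatments],
            index=self.treatments,
        )
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "logOR": eff,
                "se": se,
                "OR": np.exp(eff),
                "ci_low": np.exp(eff - z * se),
                "ci_high": np.exp(eff + z * se),
            }
        )

    def summary(self) -> str:
        lines = [
            "Network meta-analysis of logit-transformed proportions",
            f"  model: {self.method} effects   reference: {self.reference}",
            f"  studies: {self.model.n_studies}   treatments: {len(self.treatments)}"
            f"   contrasts: {len(self.model.contrasts)}",
            f"  tau^2 (DL) = {self.tau2_dl:.4f}   tau^2 used = {self.tau2:.4f}",
            f"  Q = {self.Q_total:.3f} (df {self.df_total})"
            f"  [within designs {self.Q_within_design:.3f} (df {self.df_within}),"
            f" between designs {self.Q_between_design:.3f} (df {self.df_between})]",
            f"  network I^2 = {self.I2_network:.1f}%  ({self.heterogeneity_band})",
            "",
            "Treatment effects vs reference (OR of correct classification):",
            self.summary_frame().round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        return {
            "method": self.method,
            "reference": self.reference,
            "treatments": self.treatments,
            "n_studies": self.model.n_studies,
            "effects_logOR": {t: float(self.effects[t]) for t in self.treatments},
            "tau2": self.tau2,
            "tau2_dl": self.tau2_dl,
            "Q_total": self.Q_total,
            "Q_within_design": self.Q_within_design,
            "Q_between_design": self.Q_between_design,
            "df_total": self.df_total,
            "df_within": self.df_within,
            "df_between": self.df_between,
            "I2_network": self.I2_network,
            "heterogeneity_band": self.heterogeneity_band,
        }
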
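"""Evidence-table data model, validation, and CSV ingest.

The unit of evidence is a *study*: one diagnostic-classification experiment
that evaluated two or more algorithms ("arms") on the same participants and
reported, per algorithm, proportions of correctly classified subjects
(accuracy) and optionally sensitivity and specificity.  Participant counts
are reported per clinical group (healthy controls, mild cognitive
impairment, Alzheimer's disease), never per metric, so the denominator that
enters a proportion's variance is a modelling choice exposed as an explicit
policy (:func:`resolve_denominator`).
"""

from __future__ import annotations

import enum
import importlib.resources
from pathlib import Path
from typing import Callable, Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Metric",
    "DiagnosticTask",
    "MriModality",
    "DataSource",
    "ALGORITHMS",
    "MetricObservation",
    "ArmRecord",
    "StudyRecord",
    "EvidenceError",
    "EmptyNetworkError",
    "load_evidence_table",
    "write_evidence_table",
    "load_fixture",
    "filter_network",
    "resolve_denominator",
]

#: Canonical algorithm labels accepted in evidence tables.
ALGORITHMS = (
    "Bayes", "SVM", "LR", "MP", "LDS", "ELM", "FFR", "NN",
    "CNN", "DenseNet", "ResNet",
)


class Metric(str, enum.Enum):
    accuracy = "accuracy"
    sensitivity = "sensitivity"
    specificity = "specificity"


class DiagnosticTask(str, enum.Enum):
    AD_vs_HC = "AD_vs_HC"
    AD_vs_MCI = "AD_vs_MCI"
    MCI_conversion = "MCI_conversion"


class MriModality(str, enum.Enum):
    T1 = "T1"
    T1_T2 = "T1_T2"


class DataSource(str, enum.Enum):
    ADNI = "ADNI"
    AddNeuroMed = "AddNeuroMed"
    local = "local"


class EvidenceError(ValueError):
    """Raised for schema or validation problems in an evidence table."""


class EmptyNetworkError(EvidenceError):
    """Raised when a subgroup filter leaves no studies."""


class MetricObservation(BaseModel):
    """A single reported proportion with its denominator."""

    model_config = {"frozen": True}

    p: float = Field(ge=0.0, le=1.0)
    n: int = Field(ge=1)
    metric: Metric


class ArmRecord(BaseModel):
    """One algorithm's reported metrics within a study."""

    model_config = {"frozen": True}

    algorithm: str
    accuracy: Optional[MetricObservation] = None
    sensitivity: Optional[MetricObservation] = None
    specificity: Optional[MetricObservation] = None

    @field_validator("algorithm")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("algorithm label must be non-empty")
        return v

    @model_validator(mode="after")
    def _at_least_one_metric(self) -> "ArmRecord":
        if self.accuracy is None and self.sensitivity is None and self.specificity is None:
            raise ValueError(f"arm {self.algorithm!r} carries no metric")
        return self

    def observation(self, metric: Metric | str) -> Optional[MetricObservation]:
        return getattr(self, Metric(metric).value)


class StudyRecord(BaseModel):
    """One study: shared participant counts plus >=2 algorithm arms."""

    model_config = {"frozen": True}

    study_id: str
    diagnostic_task: DiagnosticTask
    mri_modality: MriModality
    data_source: DataSource
    validation_strategy: Optional[Literal["kfold", "loocv", "holdout", "NR"]] = "NR"
    n_hc: int = Field(ge=0)
    n_mci: int = Field(ge=0)
    n_ad: int = Field(ge=0)
    arms: tuple[ArmRecord, ...]

    @model_validator(mode="after")
    def _validate(self) -> "StudyRecord":
        if len(self.arms) < 2:
            raise ValueError(f"study {self.study_id!r} needs >=2 arms")
        labels = [a.algorithm for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"study {self.study_id!r} has duplicate algorithm arms")
        any_metric = any(
            a.observation(m) is not None for a in self.arms for m in Metric
        )
        if any_metric and self.n_hc + self.n_mci + self.n_ad < 2:
            raise ValueError(f"study {self.study_id!r}: too few participants for its metrics")
        return self

    def arms_with(self, metric: Metric | str) -> list[ArmRecord]:
        metric = Metric(metric)
        return [a for a in self.arms if a.observation(metric) is not None]


# --- denominator policies ---------------------------------------------------

#: Participant groups compared in each diagnostic task.  Studies that
#: classify MCI conversion alongside diagnosis involve all three groups.
_TASK_GROUPS = {
    DiagnosticTask.AD_vs_HC: ("n_hc", "n_ad"),
    DiagnosticTask.AD_vs_MCI: ("n_mci", "n_ad"),
    DiagnosticTask.MCI_conversion: ("n_hc", "n_mci", "n_ad"),
}

DenominatorPolicy = Literal["task_total", "all_total", "metric_group"]


def resolve_denominator(
    study: StudyRecord,
    metric: Metric | str,
    policy: DenominatorPolicy = "task_total",
) -> int:
    """Number of participants assumed to contribute to a reported proportion.

    Policies:

    ``task_total``
        Sum of the participant groups the diagnostic task compares
        (e.g. HC + AD for AD-vs-HC classification).  Default: accuracy is
        evaluated on every classified subject of the task.
    ``all_total``
        All enrolled participants (HC + MCI + AD).
    ``metric_group``
        Cases only (AD) for sensitivity, non-cases of the task for
        specificity, task total for accuracy.
    """
    metric = Metric(metric)
    groups = _TASK_GROUPS[study.diagnostic_task]
    task_total = sum(getattr(study, g) for g in groups)
    if policy == "all_total":
        n = study.n_hc + study.n_mci + study.n_ad
    elif policy == "task_total":
        n = task_total
    elif policy == "metric_group":
        if metric is Metric.sensitivity:
            n = study.n_ad
        elif metric is Metric.specificity:
            n = task_total - study.n_ad
        else:
            n = task_total
    else:
        raise ValueError(f"unknown denominator policy {policy!r}")
    if n < 1:
        missing = [g for g in groups if getattr(study, g) == 0]
        raise EvidenceError(
            f"study {study.study_id!r}: denominator policy {policy!r} for "
            f"{metric.value} needs counts for group(s) {missing or list(groups)}"
        )
    return n


# --- CSV ingest -------------------------------------------------------------

_COLUMNS = [
    "study_id", "task", "modality", "source", "validation",
    "n_hc", "n_mci", "n_ad", "algorithm",
    "accuracy", "sensitivity", "specificity",
]


def _parse_proportion(cell: object, scale: str, where: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if s in ("", "NR", "nr", "-", "–"):
        return None
    value = float(s)
    if scale == "percent":
        if not 0.0 <= value <= 100.0:
            raise EvidenceError(f"{where}: percent value {value} outside [0, 100]")
        return value / 100.0
    if not 0.0 <= value <= 1.0:
        raise EvidenceError(f"{where}: fraction value {value} outside [0, 1]")
    return value


def load_evidence_table(
    path: str | Path,
    *,
    proportion_scale: Literal["percent", "fraction"] = "percent",
    denominator_policy: DenominatorPolicy = "task_total",
    algorithms: Optional[Iterable[str]] = ALGORITHMS,
) -> list[StudyRecord]:
    """Read a one-row-per-arm evidence CSV into :class:`StudyRecord` objects.

    The scale of the proportion columns is declared, never inferred from the
    magnitude of the values.  ``NR`` or blank cells mean the metric was not
    reported.  Metric denominators are resolved eagerly under
    ``denominator_policy`` so each :class:`MetricObservation` is
    self-contained.  ``algorithms`` is the accepted label set (``None``
    accepts any label, e.g. for synthetic networks).
    """
    allowed = None if algorithms is None else set(algorithms)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceError(f"evidence table {path} lacks columns {missing}")

    studies: list[StudyRecord] = []
    seen_arms: set[tuple[str, str]] = set()
    for study_id, grp in df.groupby("study_id", sort=False):
        head = grp.iloc[0]
        counts = {k: int(head[k]) for k in ("n_hc", "n_mci", "n_ad")}
        proto = StudyRecord.model_construct(  # counts needed before arms exist
            study_id=str(study_id),
            diagnostic_task=DiagnosticTask(head["task"]),
            mri_modality=MriModality(head["modality"]),
            data_source=DataSource(head["source"]),
            validation_strategy=str(head["validation"]) or "NR",
            **counts,
            arms=(),
        )
        arms = []
        for _, row in grp.iterrows():
            algo = str(row["algorithm"]).strip()
            if allowed is not None and algo not in allowed:
                raise EvidenceError(
                    f"unknown algorithm label {algo!r} in study {study_id!r}; "
                    f"canonical labels are {tuple(sorted(allowed))}"
                )
            key = (str(study_id), algo)
            if key in seen_arms:
                raise EvidenceError(f"duplicate arm {key} in evidence table")
            seen_arms.add(key)
            obs = {}
            for metric in Metric:
                where = f"study {study_id!r}, arm {algo!r}, {metric.value}"
                p = _parse_proportion(row[metric.value], proportion_scale, where)
                if p is not None:
                    n = resolve_denominator(proto, metric, denominator_policy)
                    obs[metric.value] = MetricObservation(p=p, n=n, metric=metric)
            arms.append(ArmRecord(algorithm=algo, **obs))
        record = proto.model_copy(update={"arms": tuple(arms)})
        studies.append(StudyRecord.model_validate(record.model_dump()))
    return studies


def write_evidence_table(
    studies: Sequence[StudyRecord],
    path: str | Path,
    *,
    proportion_scale: Literal["percent", "fraction"] = "percent",
) -> None:
    """Write studies back to the one-row-per-arm CSV schema."""
    rows = []
    for s in studies:
        for arm in s.arms:
            row = {
                "study_id": s.study_id,
                "task": s.diagnostic_task.value,
                "modality": s.mri_modality.value,
                "source": s.data_source.value,
                "validation": s.validation_strategy or "NR",
                "n_hc": s.n_hc,
                "n_mci": s.n_mci,
                "n_ad": s.n_ad,
                "algorithm": arm.algorithm,
            }
            for metric in Metric:
                o = arm.observation(metric)
                if o is None:
                    row[metric.value] = "NR"
                elif proportion_scale == "percent":
                    # exact decimal scaling so 0.92 renders as "92", not 92.00…01
                    from decimal import Decimal

                    row[metric.value] = format(
                        (Decimal(repr(o.p)) * 100).normalize(), "f"
                    )
                else:
                    row[metric.value] = repr(o.p)
            rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


_FIXTURES = {"table1": "table1.csv"}


def load_fixture(
    name: str = "table1",
    *,
    denominator_policy: DenominatorPolicy = "task_total",
) -> list[StudyRecord]:
    """Load a packaged evidence table by name (``table1``: the 10-study,
    21-arm, 11-algorithm MRI Alzheimer's-classification evidence base)."""
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise EvidenceError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    ref = importlib.resources.files("propnma.datasets") / fname
    with importlib.resources.as_file(ref) as p:
        return load_evidence_table(
            p, proportion_scale="percent", denominator_policy=denominator_policy
        )


def filter_network(
    studies: Iterable[StudyRecord],
    predicate: Callable[[StudyRecord], bool] | None = None,
    *,
    task: DiagnosticTask | str | None = None,
    modality: MriModality | str | None = None,
    source: DataSource | str | None = None,
) -> list[StudyRecord]:
    """Subset the evidence base for a prespecified subgroup analysis.

    Either pass an arbitrary ``predicate`` or any combination of the keyword
    filters (combined with AND).  An empty result raises
    :class:`EmptyNetworkError` rather than silently fitting nothing.
    """
    def keep(s: StudyRecord) -> bool:
        if predicate is not None and not predicate(s):
            return False
        if task is not None and s.diagnostic_task != DiagnosticTask(task):
            return False
        if modality is not None and s.mri_modality != MriModality(modality):
            return False
        if source is not None and s.data_source != DataSource(source):
            return False
        return True

    subset = [s for s in studies if keep(s)]
    if not subset:
        raise EmptyNetworkError("subgroup filter matched no studies")
    return subset
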
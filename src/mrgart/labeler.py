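"""Dosimetric ground-truth engine for adaptive-strategy selection.

In MR-guided adaptive radiotherapy of the prostate, each fraction's
re-calculated adapt-to-position (ATP) plan and adapt-to-shape (ATS) plan are
scored against per-structure dose-volume criteria, each with a clinical
tolerance that relaxes the limit. The fraction's ground-truth strategy is
ATP when the ATP plan is acceptable under the relaxed criteria, and ATS
otherwise (ATS, the full replanning route, is always available; if even the
ATS plan violates a criterion the case is flagged).

Criteria are strict inequalities. For a ``<`` criterion with tolerance
``t >= 0`` a value ``v`` is ``pass_strict`` when ``v < limit``,
``pass_within_tolerance`` when ``limit <= v < limit + t``, else ``violated``;
the logic mirrors for ``>`` criteria whose tolerances are negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd
import yaml


class StrategyLabel(enum.IntEnum):
    """Adaptive-strategy label: adapt-to-position (0) or adapt-to-shape (1)."""

    ATP = 0
    ATS = 1


class CriterionStatus(str, enum.Enum):
    PASS_STRICT = "pass_strict"
    PASS_WITHIN_TOLERANCE = "pass_within_tolerance"
    VIOLATED = "violated"


@dataclass(frozen=True)
class DosimetricCriterion:
    """One dose-volume rule, e.g. rectum D_max < 40 Gy with 0 Gy tolerance.

    ``metric`` is a key like ``"V_40Gy"`` (volume receiving >= 40 Gy),
    ``"D_max"`` (maximum dose) or ``"D_50%"`` (dose to 50% of the volume);
    ``unit`` is the unit of both ``limit`` and ``tolerance`` ("%", "cc" or
    "Gy"). The signed ``tolerance`` relaxes the limit: non-negative for
    ``<`` criteria, non-positive for ``>`` criteria.
    """

    structure: str
    metric: str
    comparator: str  # "<" or ">"
    limit: float
    tolerance: float
    unit: str

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError(f"comparator must be '<' or '>', got {self.comparator!r}")
        if self.comparator == "<" and self.tolerance < 0:
            raise ValueError("a '<' criterion relaxes upward: tolerance must be >= 0")
        if self.comparator == ">" and self.tolerance > 0:
            raise ValueError("a '>' criterion relaxes downward: tolerance must be <= 0")

    @property
    def relaxed_limit(self) -> float:
        return self.limit + self.tolerance

    def status(self, value: float) -> CriterionStatus:
        if self.comparator == "<":
            if value < self.limit:
                return CriterionStatus.PASS_STRICT
            if value < self.relaxed_limit:
                return CriterionStatus.PASS_WITHIN_TOLERANCE
            return CriterionStatus.VIOLATED
        if value > self.limit:
            return CriterionStatus.PASS_STRICT
        if value > self.relaxed_limit:
            return CriterionStatus.PASS_WITHIN_TOLERANCE
        return CriterionStatus.VIOLATED


def default_criteria() -> List[DosimetricCriterion]:
    """The 12 clinical criteria for prostate MRgART plan acceptance."""
    C = DosimetricCriterion
    return [
        C("CTV4000", "V_40Gy", ">", 95.0, -5.0, "%"),
        C("PTV", "V_36.25Gy", ">", 95.0, -5.0, "%"),
        C("PTV", "V_34.4Gy", ">", 98.0, -5.0, "%"),
        C("Rectum", "D_max", "<", 40.0, 0.0, "Gy"),
        C("Rectum", "V_38Gy", "<", 0.1, 0.0, "cc"),
        C("Rectum", "V_36Gy", "<", 1.0, 1.0, "cc"),
        C("Rectum", "V_29Gy", "<", 20.0, 1.0, "%"),
        C("Bladder", "V_37Gy", "<", 10.0, 0.5, "cc"),
        C("Bladder", "V_18.1Gy", "<", 50.0, 2.5, "%"),
        C("Femur_R", "V_14.5Gy", "<", 5.0, 0.5, "%"),
        C("Femur_L", "V_14.5Gy", "<", 5.0, 0.5, "%"),
        C("Urethra", "D_50%", "<", 41.0, 1.5, "Gy"),
    ]


MetricKey = Tuple[str, str]  # (structure, metric)


@dataclass
class DVHMetricTable:
    """Map of (structure, metric) -> (value, unit) for one plan."""

    values: Dict[MetricKey, Tuple[float, str]] = field(default_factory=dict)

    def set(self, structure: str, metric: str, value: float, unit: str) -> None:
        if not (value >= 0 and value < float("inf")):
            raise ValueError(f"DVH metric {structure}/{metric} must be finite and >= 0")
        self.values[(structure, metric)] = (float(value), unit)

    def get(self, structure: str, metric: str) -> float:
        try:
            return self.values[(structure, metric)][0]
        except KeyError:
            raise KeyError(f"DVH table is missing ({structure}, {metric})") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"structure": s, "metric": m, "value": v, "unit": u}
            for (s, m), (v, u) in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["structure", "metric", "value", "unit"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DVHMetricTable":
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.structure), str(row.metric), float(row.value), str(row.unit))
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "DVHMetricTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PlanEvaluation:
    """Per-criterion statuses plus the overall acceptability verdict."""

    statuses: Dict[MetricKey, CriterionStatus]

    @property
    def acceptable(self) -> bool:
        return all(s is not CriterionStatus.VIOLATED for s in self.statuses.values())

    @property
    def violations(self) -> List[MetricKey]:
        return [k for k, s in self.statuses.items() if s is CriterionStatus.VIOLATED]


def evaluate_plan(
    dvh: DVHMetricTable, criteria: Iterable[DosimetricCriterion] | None = None
) -> PlanEvaluation:
    """Score one plan's DVH metrics against the criteria."""
    criteria = list(criteria) if criteria is not None else default_criteria()
    statuses: Dict[MetricKey, CriterionStatus] = {}
    for c in criteria:
        value = dvh.get(c.structure, c.metric)
        statuses[(c.structure, c.metric)] = c.status(value)
    return PlanEvaluation(statuses)


@dataclass
class StrategyDecision:
    """Outcome of the ATP-vs-ATS decision for one fraction.

    ``flagged`` is set when even the ATS plan violates a criterion — ATS is
    still returned because no better option exists in the strategy menu.
    """

    label: StrategyLabel
    atp_evaluation: PlanEvaluation
    ats_evaluation: PlanEvaluation
    flagged: bool = False


def determine_strategy(
    dvh_atp: DVHMetricTable,
    dvh_ats: DVHMetricTable,
    criteria: Iterable[DosimetricCriterion] | None = None,
) -> StrategyDecision:
    """ATP when the ATP plan is acceptable (within tolerances), else ATS."""
    criteria = list(criteria) if criteria is not None else default_criteria()
    atp_eval = evaluate_plan(dvh_atp, criteria)
    ats_eval = evaluate_plan(dvh_ats, criteria)
    if atp_eval.acceptable:
        return StrategyDecision(StrategyLabel.ATP, atp_eval, ats_eval)
    return StrategyDecision(StrategyLabel.ATS, atp_eval, ats_eval, flagged=not ats_eval.acceptable)


# -- criteria (de)serialization --------------------------------------------


def criteria_to_yaml(criteria: Iterable[DosimetricCriterion], path: str | Path) -> None:
    rows = [
        {
            "structure": c.structure,
            "metric": c.metric,
            "comparator": c.comparator,
            "limit": c.limit,
            "tolerance": c.tolerance,
            "unit": c.unit,
        }
        for c in criteria
    ]
    Path(path).write_text(yaml.safe_dump({"criteria": rows}, sort_keys=False))


def criteria_from_yaml(path: str | Path) -> List[DosimetricCriterion]:
    payload = yaml.safe_load(Path(path).read_text())
    return [DosimetricCriterion(**row) for row in payload["criteria"]]
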
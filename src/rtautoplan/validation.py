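"""Planning integrity checks and the parameter-change audit log.

Each check returns a :class:`ValidationResult` in one of four states —
``pass``, ``tracked``, ``warning``, ``flag`` — ordered by severity. Checks
are pure functions of the case context and an injected clock: nothing here
reads the wall clock, so a rerun with the same inputs reproduces the same
report.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Any

from .templates import ClinicalGoal

__all__ = [
    "CaseContext",
    "ValidationResult",
    "ChangeRecord",
    "ChangeLog",
    "check_other_plans",
    "check_image_age",
    "check_image_modality",
    "check_protocol_interpretation",
    "track_parameter",
    "check_clinical_goals",
    "validation_report",
    "STATE_ORDER",
]

STATE_ORDER = ("pass", "tracked", "warning", "flag")


@dataclass
class CaseContext:
    """Everything the structure-set/image checks need, gathered up front."""

    structure_set_id: str = ""
    image_modality: str | None = None
    image_acquisition_date: _dt.date | None = None
    referencing_plan_ids: list[str] = field(default_factory=list)
    user_overrides: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass(frozen=True)
class ValidationResult:
    check_id: str
    state: str
    message: str = ""
    timestamp: _dt.datetime | None = None

    def __post_init__(self) -> None:
        if self.state not in STATE_ORDER:
            raise ValueError(f"unknown validation state {self.state!r}")
        if self.state != "pass" and not self.message:
            raise ValueError(f"check {self.check_id!r}: non-pass state requires a message")


@dataclass(frozen=True)
class ChangeRecord:
    parameter: str
    template_value: str
    user_value: str
    timestamp: _dt.datetime


class ChangeLog:
    """Append-only audit log of template-parameter overrides."""

    def __init__(self) -> None:
        self.records: list[ChangeRecord] = []

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def check_other_plans(ctx: CaseContext) -> ValidationResult:
    """Warn when the structure set is referenced by other plans (possibly stale)."""
    if ctx.referencing_plan_ids:
        ids = ", ".join(ctx.referencing_plan_ids)
        return ValidationResult(
            "other_plans",
            "warning",
            f"structure set {ctx.structure_set_id!r} is used by other plan(s): {ids}",
        )
    return ValidationResult("other_plans", "pass")


def check_image_age(
    ctx: CaseContext, today: _dt.date, threshold_days: int = 14
) -> ValidationResult:
    """Flag a planning image more than ``threshold_days`` whole days old.

    The boundary is strict: an image exactly ``threshold_days`` old passes.
    """
    if ctx.image_acquisition_date is None:
        return ValidationResult("image_age", "flag", "image acquisition date is missing")
    age = (today - ctx.image_acquisition_date).days
    if age < 0:
        return ValidationResult(
            "image_age",
            "flag",
            f"image acquisition date {ctx.image_acquisition_date} is in the future",
        )
    if age > threshold_days:
        return ValidationResult(
            "image_age",
            "flag",
            f"planning image is {age} days old (> {threshold_days} days)",
        )
    return ValidationResult("image_age", "pass")


def check_image_modality(ctx: CaseContext) -> ValidationResult:
    """Planning must be on a CT image series."""
    if ctx.image_modality is None:
        return ValidationResult("image_modality", "flag", "image modality is missing")
    if ctx.image_modality.upper() != "CT":
        return ValidationResult(
            "image_modality",
            "flag",
            f"planning image modality is {ctx.image_modality!r}, expected CT",
        )
    return ValidationResult("image_modality", "pass")


def check_protocol_interpretation(
    parse_outcome: Any,
    target_resolved: bool = True,
) -> ValidationResult:
    """Pass iff the protocol parsed into a creatable plan.

    ``parse_outcome`` is either a :class:`~rtautoplan.templates.ClinicalProtocol`
    or the exception raised while parsing. A protocol whose target cannot be
    matched to a planning structure is also flagged.
    """
    if isinstance(parse_outcome, BaseException):
        return ValidationResult(
            "protocol_interpretation",
            "flag",
            f"clinical protocol could not be interpreted: {parse_outcome}",
        )
    if parse_outcome is None:
        return ValidationResult(
            "protocol_interpretation", "flag", "no clinical protocol supplied"
        )
    if not getattr(parse_outcome, "field_templates", None):
        return ValidationResult(
            "protocol_interpretation", "flag", "protocol declares no treatment fields"
        )
    if not target_resolved:
        target = parse_outcome.prescription.target_id
        return ValidationResult(
            "protocol_interpretation",
            "flag",
            f"protocol target {target!r} could not be matched to a planning structure",
        )
    return ValidationResult("protocol_interpretation", "pass")


def track_parameter(
    name: str,
    template_value: str,
    user_value: str,
    log: ChangeLog,
    timestamp: _dt.datetime | None = None,
) -> ChangeRecord | None:
    """Record a template-parameter override; identical values record nothing.

    Idempotent: repeating an identical call appends no duplicate record.
    """
    if template_value == user_value:
        return None
    for rec in log.records:
        if (
            rec.parameter == name
            and rec.template_value == template_value
            and rec.user_value == user_value
        ):
            return rec
    rec = ChangeRecord(
        parameter=name,
        template_value=template_value,
        user_value=user_value,
        timestamp=timestamp or _dt.datetime(1970, 1, 1),
    )
    log.records.append(rec)
    return rec


def check_clinical_goals(
    goals: list[ClinicalGoal],
    metrics: dict[str, float | None],
) -> list[ValidationResult]:
    """Evaluate each clinical goal against its computed metric value.

    ``metrics`` maps a goal label (see :meth:`ClinicalGoal.label`) to the
    evaluated value, or None when the metric could not be evaluated (which
    flags the goal).
    """
    results = []
    for goal in goals:
        label = goal.label()
        key = f"{goal.structure_id}:{goal.metric.label()}"
        value = metrics.get(key)
        if value is None:
            results.append(
                ValidationResult(
                    f"goal:{key}", "flag", f"goal {label} not evaluated (metric missing)"
                )
            )
        elif goal.satisfied_by(value):
            results.append(ValidationResult(f"goal:{key}", "pass"))
        else:
            results.append(
                ValidationResult(
                    f"goal:{key}",
                    "flag",
                    f"goal {label} violated: value {value:.2f} {goal.metric.result_units}",
                )
            )
    return results


def validation_report(
    results: list[ValidationResult],
    changes: ChangeLog | None = None,
) -> dict:
    """Aggregate check outcomes into a machine-readable report.

    The overall status is the worst state present under the total order
    pass < tracked < warning < flag; tracked changes contribute a ``tracked``
    state even when every check passes.
    """
    changes = changes or ChangeLog()
    states = [r.state for r in results]
    if len(changes) > 0:
        states.append("tracked")
    overall = "pass"
    for s in states:
        if STATE_ORDER.index(s) > STATE_ORDER.index(overall):
            overall = s
    return {
        "overall": overall,
        "counts": {s: states.count(s) for s in STATE_ORDER},
        "checks": [
            {"check_id": r.check_id, "state": r.state, "message": r.message}
            for r in results
        ],
        "changes": [
            {
                "parameter": c.parameter,
                "template_value": c.template_value,
                "user_value": c.user_value,
                "timestamp": c.timestamp.isoformat(),
            }
            for c in changes
        ],
        "n_checks": len(results),
    }
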
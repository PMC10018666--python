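"""Execute declarative derivation rules to build planning structures.

Rules are interpreted in order; each rule is a short program of boolean,
margin, ring and crop instructions whose operands are resolved against the
structure set through the structure dictionary (so `Hippocampus` in a rule
finds `Hippocampi` in the set). A rule with an unresolvable operand is
flagged and skipped — remaining rules still run, mirroring the
pass-or-flag semantics of the planning validation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .templates import (
    AmbiguousMatchError,
    AutomationConfig,
    DerivationRule,
    StructureDictionary,
    match_structure,
    packaged_data_path,
    parse_automation_config,
)
from .volumetric import (
    GridMismatchError,
    StructureMask,
    boolean_combine,
    centroid,
    expand_margin,
    ring,
    volume_cc,
)

__all__ = [
    "RuleOutcome",
    "BuildReport",
    "build_derived_structures",
    "default_hawbrt_rules",
    "default_hawbrt_config",
]

_HALF_SPACE_DIRECTIONS = {
    # LPS: +x left, +y posterior, +z superior
    "left": (0, +1),
    "right": (0, -1),
    "posterior": (1, +1),
    "anterior": (1, -1),
    "superior": (2, +1),
    "inferior": (2, -1),
}


@dataclass
class RuleOutcome:
    output_id: str
    built: bool
    missing_operands: list[str] = field(default_factory=list)
    volume_cc: float | None = None
    message: str = ""


@dataclass
class BuildReport:
    outcomes: list[RuleOutcome] = field(default_factory=list)

    @property
    def flagged(self) -> list[RuleOutcome]:
        return [o for o in self.outcomes if not o.built]

    @property
    def all_built(self) -> bool:
        return all(o.built for o in self.outcomes)


def _half_space_mask(reference: StructureMask, directions: list[str]) -> np.ndarray:
    """Boolean array keeping voxels on the given side(s) of the reference centroid."""
    cx, cy, cz = centroid(reference)
    g = reference.grid
    keep = np.ones(g.shape_zyx, dtype=bool)
    coords = {
        0: g.axis_coords(0)[None, None, :],
        1: g.axis_coords(1)[None, :, None],
        2: g.axis_coords(2)[:, None, None],
    }
    center = {0: cx, 1: cy, 2: cz}
    for name in directions:
        if name not in _HALF_SPACE_DIRECTIONS:
            raise ValueError(
                f"unknown crop direction {name!r}; allowed: {sorted(_HALF_SPACE_DIRECTIONS)}"
            )
        axis, sign = _HALF_SPACE_DIRECTIONS[name]
        if sign > 0:
            keep &= coords[axis] > center[axis]
        else:
            keep &= coords[axis] < center[axis]
    return keep


def build_derived_structures(
    rules: list[DerivationRule],
    masks: dict[str, StructureMask],
    dictionary: StructureDictionary | None = None,
) -> tuple[dict[str, StructureMask], BuildReport]:
    """Run derivation rules against a structure set.

    Returns the newly derived masks (inputs are never modified) and a
    :class:`BuildReport` with one outcome per rule. Later rules may consume
    the outputs of earlier rules. A cyclic self-reference (a rule consuming
    its own output) is a hard error; a missing operand merely flags the rule.
    """
    if masks:
        grid = next(iter(masks.values())).grid
        for m in masks.values():
            if not grid.matches(m.grid):
                raise GridMismatchError(
                    f"structure {m.structure_id!r} is not on the shared grid"
                )
    derived: dict[str, StructureMask] = {}
    report = BuildReport()

    for rule in rules:
        for step in rule.steps:
            if rule.output_id in step.operands:
                raise ValueError(
                    f"rule {rule.output_id!r} references its own output (cycle)"
                )
        available = {**masks, **derived}
        step_results: list[StructureMask] = []
        missing: list[str] = []
        error_msg = ""

        def resolve(name: str) -> StructureMask | None:
            if name.startswith("$"):
                idx = int(name[1:])
                if idx >= len(step_results):
                    raise ValueError(
                        f"rule {rule.output_id!r}: step reference {name} precedes its definition"
                    )
                return step_results[idx]
            if name == rule.output_id:
                raise ValueError(
                    f"rule {rule.output_id!r} references its own output (cycle)"
                )
            try:
                match = match_structure(name, list(available), dictionary)
            except AmbiguousMatchError:
                return None
            if match.matched is None:
                return None
            return available[match.matched]

        result: StructureMask | None = None
        for step in rule.steps:
            operands = []
            for name in step.operands:
                m = resolve(name)
                if m is None:
                    missing.append(name)
                operands.append(m)
            if missing:
                break
            try:
                if step.verb in ("union", "intersection", "subtraction"):
                    result = boolean_combine(operands, step.verb, rule.output_id)
                elif step.verb == "margin":
                    result = expand_margin(
                        operands[0], float(step.params["mm"]), rule.output_id
                    )
                elif step.verb == "ring":
                    result = ring(
                        operands[0],
                        float(step.params.get("inner_mm", 0.0)),
                        float(step.params["outer_mm"]),
                        rule.output_id,
                    )
                elif step.verb == "crop_to":
                    directions = list(step.params.get("directions", []))
                    keep = _half_space_mask(operands[1], directions)
                    result = StructureMask(
                        operands[0].grid,
                        operands[0].occupancy & keep,
                        rule.output_id,
                    )
            except (ValueError, KeyError) as exc:
                error_msg = str(exc)
                result = None
                break
            step_results.append(result)

        if missing or result is None:
            report.outcomes.append(
                RuleOutcome(
                    output_id=rule.output_id,
                    built=False,
                    missing_operands=sorted(set(missing)),
                    message=error_msg
                    or f"unresolved operand(s): {', '.join(sorted(set(missing)))}",
                )
            )
            continue
        derived[rule.output_id] = result.copy(rule.output_id)
        report.outcomes.append(
            RuleOutcome(
                output_id=rule.output_id,
                built=True,
                volume_cc=volume_cc(result),
            )
        )
    return derived, report


def default_hawbrt_config() -> AutomationConfig:
    """The packaged HA-WBRT automation configuration."""
    return parse_automation_config(packaged_data_path("hawbrt_config.yaml").read_text())


def default_hawbrt_rules() -> list[DerivationRule]:
    """The four packaged HA-WBRT derivation rules.

    Hippocampi_05 — 5 mm planning-risk margin on the hippocampi;
    NS_Ring_05 — 5 mm ring just outside the whole-brain PTV;
    PTV_WBopt — optimization target, PTV minus the hippocampal PRV;
    NS_FaceAvoid — anterior-inferior face avoidance (Body cropped anterior
    and inferior of the PTV center, minus a 10 mm PTV expansion).
    """
    return default_hawbrt_config().derivation_rules
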
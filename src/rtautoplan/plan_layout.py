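"""Isocenter placement and VMAT plan-skeleton generation.

The plan skeleton carries arcs, collimator/couch angles and fitted jaws; MLC
leaves are parked open and no monitor units are assigned — inverse
optimization and dose calculation are outside this package's scope.

Angle conventions (IEC 61217, head-first supine): gantry 0 places the source
anterior to the patient, angles increase clockwise viewed from the foot of
the couch. In patient LPS coordinates the beam direction at gantry g is
``(-sin g, cos g, 0)`` and the collimator X axis before collimator rotation
is ``(cos g, sin g, 0)``; the collimator rotates the jaw axes about the beam
axis. Arcs between 180.1 and 179.9 travel through gantry 0 (across the
anterior side), i.e. a 359.8-degree arc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .templates import ClinicalProtocol, FieldTemplate
from .volumetric import StructureMask, bounding_box_mm

__all__ = [
    "PlannedField",
    "PlanLayout",
    "place_isocenter",
    "build_fields",
    "fit_jaws",
    "arc_sample_angles",
]

_MAX_HALF_FIELD_MM = 200.0


@dataclass(frozen=True)
class PlannedField:
    """One instantiated treatment field with jaw settings at the isocenter plane."""

    field_id: str
    technique: str
    gantry_start: float
    gantry_stop: float
    rotation_direction: str
    collimator_angle: float
    couch_angle: float
    energy_label: str
    x1_mm: float = -50.0
    x2_mm: float = 50.0
    y1_mm: float = -50.0
    y2_mm: float = 50.0

    def __post_init__(self) -> None:
        if not (self.x1_mm < self.x2_mm and self.y1_mm < self.y2_mm):
            raise ValueError(
                f"field {self.field_id!r}: jaws must satisfy X1 < X2 and Y1 < Y2"
            )

    @property
    def arc_span_deg(self) -> float:
        """Angular travel along the stated rotation direction, in (0, 360)."""
        if self.technique != "arc":
            return 0.0
        if self.rotation_direction == "CW":
            span = (self.gantry_stop - self.gantry_start) % 360.0
        else:
            span = (self.gantry_start - self.gantry_stop) % 360.0
        return span if span > 0 else 360.0


@dataclass
class PlanLayout:
    plan_id: str
    machine_id: str
    isocenter_mm: tuple[float, float, float]
    fields: list[PlannedField]
    prescription_target: str
    total_dose_gy: float
    fractions: int
    machine_overridden: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("plan layout requires at least one field")


def place_isocenter(target: StructureMask) -> tuple[float, float, float]:
    """Center of the target's axis-aligned bounding box, rounded to 0.1 mm.

    The bounding-box center is preferred over the centroid for robustness to
    asymmetric inferior extent of the brain target; the centroid is reported
    separately in logs where transparency is useful.
    """
    lo, hi = bounding_box_mm(target)
    center = (lo + hi) / 2.0
    return tuple(round(float(v), 1) for v in center)


def build_fields(
    protocol: ClinicalProtocol,
    isocenter: tuple[float, float, float],
    machine_id: str | None = None,
    plan_id: str = "AutoPlan",
    machine_registry: list[str] | None = None,
) -> PlanLayout:
    """Instantiate one :class:`PlannedField` per template field.

    ``machine_id`` overrides the template's default machine; the override is
    recorded in the layout notes (tracked-change semantics).
    """
    machine = protocol.default_machine_id
    overridden = False
    notes: list[str] = []
    if machine_id is not None and machine_id != protocol.default_machine_id:
        machine = machine_id
        overridden = True
        notes.append(
            f"machine overridden: template {protocol.default_machine_id!r} -> {machine_id!r}"
        )
    if machine_registry is not None and machine not in machine_registry:
        raise ValueError(f"machine {machine!r} is not in the machine registry")

    fields = [
        PlannedField(
            field_id=t.field_id,
            technique=t.technique,
            gantry_start=t.gantry_start,
            gantry_stop=t.gantry_stop,
            rotation_direction=t.rotation_direction,
            collimator_angle=t.collimator_angle,
            couch_angle=t.couch_angle,
            energy_label=t.energy_label,
        )
        for t in protocol.field_templates
    ]
    return PlanLayout(
        plan_id=plan_id,
        machine_id=machine,
        isocenter_mm=tuple(float(v) for v in isocenter),
        fields=fields,
        prescription_target=protocol.prescription.target_id,
        total_dose_gy=protocol.prescription.total_dose_gy,
        fractions=protocol.prescription.fractions,
        machine_overridden=overridden,
        notes=notes,
    )


def arc_sample_angles(field_: PlannedField, step_deg: float = 10.0) -> np.ndarray:
    """Gantry angles sampled along the field's travel (endpoints included)."""
    if field_.technique != "arc":
        return np.array([field_.gantry_start])
    span = field_.arc_span_deg
    n = max(2, int(math.ceil(span / step_deg)) + 1)
    offsets = np.linspace(0.0, span, n)
    sign = 1.0 if field_.rotation_direction == "CW" else -1.0
    return (field_.gantry_start + sign * offsets) % 360.0


def _bev_axes(gantry_deg: float, collimator_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Jaw X and Y unit vectors in patient coordinates for one gantry angle."""
    g = math.radians(gantry_deg)
    beam = np.array([-math.sin(g), math.cos(g), 0.0])
    u = np.array([math.cos(g), math.sin(g), 0.0])  # crossplane (X jaws)
    v = np.array([0.0, 0.0, 1.0])  # inplane (Y jaws), toward superior
    c = math.radians(collimator_deg)
    # rotate (u, v) about the beam axis by the collimator angle
    u_rot = math.cos(c) * u + math.sin(c) * np.cross(beam, u)
    v_rot = math.cos(c) * v + math.sin(c) * np.cross(beam, v)
    return u_rot, v_rot


def fit_jaws(
    target: StructureMask,
    field_: PlannedField,
    isocenter: tuple[float, float, float],
    margin_mm: float = 7.0,
    angular_step_deg: float = 10.0,
) -> PlannedField:
    """Fit jaws to enclose the target's beam's-eye-view projection over the arc.

    The projection is orthographic: occupied voxels (as axis-aligned boxes,
    not just centers) are projected onto the collimator-rotated jaw axes at
    gantry angles sampled every ``angular_step_deg`` along the arc, and the
    jaw rectangle is the union of those footprints plus ``margin_mm`` on all
    sides.
    """
    if target.is_empty:
        raise ValueError(f"cannot fit jaws to empty target {target.structure_id!r}")
    g = target.grid
    zi, yi, xi = np.nonzero(target.occupancy)
    centers = np.column_stack(
        [
            g.origin[0] + g.spacing[0] * xi,
            g.origin[1] + g.spacing[1] * yi,
            g.origin[2] + g.spacing[2] * zi,
        ]
    ) - np.asarray(isocenter, dtype=float)
    half = np.array(g.spacing) / 2.0

    x_lo = y_lo = math.inf
    x_hi = y_hi = -math.inf
    for gantry in arc_sample_angles(field_, angular_step_deg):
        u, v = _bev_axes(gantry, field_.collimator_angle)
        pu = centers @ u
        pv = centers @ v
        # max over the 8 voxel corners = center projection +/- half-extent
        hu = float(np.abs(u) @ half)
        hv = float(np.abs(v) @ half)
        x_lo = min(x_lo, float(pu.min()) - hu)
        x_hi = max(x_hi, float(pu.max()) + hu)
        y_lo = min(y_lo, float(pv.min()) - hv)
        y_hi = max(y_hi, float(pv.max()) + hv)

    x1, x2 = x_lo - margin_mm, x_hi + margin_mm
    y1, y2 = y_lo - margin_mm, y_hi + margin_mm
    if max(abs(x1), abs(x2), abs(y1), abs(y2)) > _MAX_HALF_FIELD_MM:
        raise ValueError(
            f"field {field_.field_id!r}: projection exceeds the "
            f"{_MAX_HALF_FIELD_MM:g} mm half-field limit"
        )
    return replace(field_, x1_mm=x1, x2_mm=x2, y1_mm=y1, y2_mm=y2)
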
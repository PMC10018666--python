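"""Seeded synthetic HA-WBRT cases: CT, structure set and dose.

The phantom stands in for a planning CT of a hippocampal-avoidance whole
brain case: an ellipsoidal head (Body), a whole-brain target (PTV_3000),
bilateral hippocampi combined into one structure, both optic nerves and the
optic chiasm. The dose model emulates the characteristic HA-WBRT dose
pattern — a prescription-level plateau over the PTV with a mild ripple,
deep cold wells carved around each hippocampus, exponential falloff outside
the target — with seeded additive noise. It is a geometric emulation, not a
physical dose calculation.

All randomness (sub-voxel center jitter, dose noise) flows from the spec
seed, so a given spec is bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .templates import packaged_data_path
from .volumetric import DoseGrid, SpatialGrid, StructureMask

__all__ = [
    "PhantomSpec",
    "DoseModelSpec",
    "load_default_spec",
    "generate_phantom",
    "generate_dose",
]


@dataclass
class DoseModelSpec:
    rx_gy: float = 30.0
    ripple_amplitude: float = 0.04
    ripple_wavelength_mm: float = 70.0
    cold_well_depth: float = 0.73  # fraction of the in-target dose removed at the hippocampi
    cold_well_width_mm: float = 2.5  # Gaussian width of the well shoulder
    falloff_length_mm: float = 12.0  # exponential dose falloff outside the PTV
    noise_sigma_gy: float = 0.15
    seed: int = 1234

    def __post_init__(self) -> None:
        if not 0 <= self.cold_well_depth < 1:
            raise ValueError("cold_well_depth must lie in [0, 1)")
        if self.falloff_length_mm <= 0:
            raise ValueError("falloff_length_mm must be positive")


@dataclass
class PhantomSpec:
    grid: SpatialGrid
    structures: dict[str, dict]
    jitter_mm: float = 1.0
    ct_air_hu: int = -1000
    ct_tissue_hu: int = 30
    seed: int = 1234
    target_volumes_cc: dict[str, float] = field(default_factory=dict)
    dose_model: DoseModelSpec = field(default_factory=DoseModelSpec)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        g = data["grid"]
        grid = SpatialGrid(
            origin=tuple(g["origin_mm"]), spacing=tuple(g["spacing_mm"]), dims=tuple(g["dims"])
        )
        dm = dict(data.get("dose_model", {}))
        seed = int(data.get("seed", 1234))
        dose_model = DoseModelSpec(
            rx_gy=float(dm.get("rx_gy", 30.0)),
            ripple_amplitude=float(dm.get("ripple_amplitude", 0.04)),
            ripple_wavelength_mm=float(dm.get("ripple_wavelength_mm", 70.0)),
            cold_well_depth=float(dm.get("cold_well_depth", 0.73)),
            cold_well_width_mm=float(dm.get("cold_well_width_mm", 2.5)),
            falloff_length_mm=float(dm.get("falloff_length_mm", 12.0)),
            noise_sigma_gy=float(dm.get("noise_sigma_gy", 0.15)),
            seed=seed,
        )
        ct = data.get("ct", {})
        return cls(
            grid=grid,
            structures=data["structures"],
            jitter_mm=float(data.get("jitter_mm", 1.0)),
            ct_air_hu=int(ct.get("air_hu", -1000)),
            ct_tissue_hu=int(ct.get("tissue_hu", 30)),
            seed=seed,
            target_volumes_cc=dict(data.get("target_volumes_cc", {})),
            dose_model=dose_model,
        )


def load_default_spec(seed: int | None = None) -> PhantomSpec:
    """The packaged default phantom spec, optionally reseeded."""
    data = json.loads(packaged_data_path("phantom_default.json").read_text())
    spec = PhantomSpec.from_dict(data)
    if seed is not None:
        spec.seed = int(seed)
        spec.dose_model.seed = int(seed)
    return spec


def _coordinate_arrays(grid: SpatialGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadcastable (x, y, z) center coordinates for a (z, y, x) array."""
    x = grid.axis_coords(0)[None, None, :]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[:, None, None]
    return x, y, z


def _primitive_mask(grid: SpatialGrid, shape: dict, jitter: np.ndarray) -> np.ndarray:
    x, y, z = _coordinate_arrays(grid)
    cx, cy, cz = (np.asarray(shape["center"], dtype=float) + jitter).tolist()
    kind = shape["shape"]
    if kind == "ellipsoid":
        ax, ay, az = shape["semi_axes"]
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    if kind == "cylinder_y":
        r = float(shape["radius_mm"])
        h = float(shape["half_length_mm"])
        radial = ((x - cx) ** 2 + (z - cz) ** 2) <= r**2
        return radial & (np.abs(y - cy) <= h)
    raise ValueError(f"unknown phantom primitive {kind!r}")


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, dict[str, StructureMask]]:
    """Build the CT volume and the structure masks of a synthetic case.

    Returns ``(ct_hu, masks)`` where ``ct_hu`` is an int16 (z, y, x) array of
    Hounsfield units (two-tissue model: air outside Body, soft tissue inside)
    and ``masks`` contains Body, PTV_3000, Hippocampi (bilateral union),
    OpticNerve_L/R and OpticChiasm. Containment is enforced by construction
    and re-checked: Hippocampi within PTV_3000 within Body, and the optic
    structures disjoint from the hippocampi.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    masks: dict[str, StructureMask] = {}
    raw: dict[str, np.ndarray] = {}
    for name, shape in spec.structures.items():
        jitter = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
        raw[name] = _primitive_mask(grid, shape, jitter)

    body = raw.pop("Body")
    ptv = raw.pop("PTV_3000") & body
    hippo_parts = [raw.pop(k) for k in list(raw) if k.startswith("Hippocamp")]
    hippo = np.logical_or.reduce(hippo_parts) & ptv

    masks["Body"] = StructureMask(grid, body, "Body")
    masks["PTV_3000"] = StructureMask(grid, ptv, "PTV_3000")
    masks["Hippocampi"] = StructureMask(grid, hippo, "Hippocampi")
    for name, occ in raw.items():  # optic structures
        occ = occ & body & ~hippo
        masks[name] = StructureMask(grid, occ, name)

    for name in ("Body", "PTV_3000", "Hippocampi"):
        if masks[name].is_empty:
            raise ValueError(f"phantom spec produced an empty {name} structure")
    if not (hippo & ~ptv).sum() == 0:
        raise ValueError("hippocampi extend outside the PTV")
    if not (ptv & ~body).sum() == 0:
        raise ValueError("PTV extends outside the body")

    ct = np.where(body, spec.ct_tissue_hu, spec.ct_air_hu).astype(np.int16)
    return ct, masks


def generate_dose(
    masks: dict[str, StructureMask],
    model: DoseModelSpec,
) -> DoseGrid:
    """Synthesize the HA-WBRT dose pattern on the phantom grid.

    dose = rx * (1 + ripple) * plateau(PTV) * (1 - depth * exp(-d_h^2 / 2w^2))
    where ``d_h`` is the Euclidean distance to the hippocampi, the plateau
    decays as exp(-d_p / L) outside the PTV (``d_p`` distance to the PTV),
    plus seeded Gaussian noise, clipped at zero.
    """
    ptv = masks["PTV_3000"]
    hippo = masks["Hippocampi"]
    grid = ptv.grid
    sampling = (grid.spacing[2], grid.spacing[1], grid.spacing[0])

    x, y, z = _coordinate_arrays(grid)
    lam = model.ripple_wavelength_mm
    ripple = model.ripple_amplitude * (
        np.sin(2 * np.pi * x / lam) * np.sin(2 * np.pi * y / lam) * np.sin(2 * np.pi * z / lam)
    )

    dist_out = ndimage.distance_transform_edt(~ptv.occupancy, sampling=sampling)
    plateau = np.exp(-dist_out / model.falloff_length_mm)

    if hippo.is_empty or model.cold_well_depth == 0:
        well = np.zeros(grid.shape_zyx)
    else:
        dist_h = ndimage.distance_transform_edt(~hippo.occupancy, sampling=sampling)
        well = model.cold_well_depth * np.exp(
            -(dist_h**2) / (2 * model.cold_well_width_mm**2)
        )

    dose = model.rx_gy * (1.0 + ripple) * plateau * (1.0 - well)
    if model.noise_sigma_gy > 0:
        rng = np.random.default_rng(model.seed + 1)
        dose = dose + rng.normal(0.0, model.noise_sigma_gy, size=dose.shape)
    dose = np.clip(dose, 0.0, None)
    return DoseGrid(grid, dose, scaling_note=f"synthetic dose model, seed {model.seed}")
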
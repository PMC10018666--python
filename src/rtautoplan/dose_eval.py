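"""DVH computation, dose metrics, normalization and paired plan comparison.

The dose-volume histogram is sample-based: it keeps the empirical
distribution of per-voxel doses inside a structure rather than a pre-binned
curve, so Dx%/Dcc/VxGy are order statistics of the voxel doses and the
"95% of the target receives the prescription" property of prescription
normalization holds exactly on the empirical distribution. Binning (default
0.05 Gy) is applied only when a curve is exported for display.

Conventions
-----------
Dx% (Dv cc) is the greatest dose d such that at least x% of the structure
volume (v cm^3) receives >= d — a pure order statistic of the voxel-dose
samples, so D100% is the minimum and V(D(x%)) >= x% holds for every x.
VxGy is the percentage of samples >= x Gy. The homogeneity index is
100 x (D5% - D95%) / prescription, in percent.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .templates import AutomationConfig, ClinicalGoal, MetricSpec, StructureDictionary, match_structure, AmbiguousMatchError
from .volumetric import DoseGrid, SpatialGrid, StructureMask, boolean_combine

__all__ = [
    "DVHCurve",
    "MetricResult",
    "WilcoxonResult",
    "CohortComparison",
    "TimingLog",
    "resample_dose",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "normalize_prescription",
    "evaluate_metrics",
    "wilcoxon_signed_rank",
    "compare_cohorts",
]

# guards against round-off introduced by the normalization scale factor when
# thresholding at exactly the prescription dose
_REL_TOL = 1e-9


@dataclass
class DVHCurve:
    """Empirical voxel-dose distribution of one structure."""

    structure_id: str
    samples: np.ndarray  # sorted ascending, Gy
    voxel_volume_cc: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size == 0:
            raise ValueError(f"DVH for {self.structure_id!r} has no samples")
        self.samples = np.sort(s)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def volume_cc(self) -> float:
        return self.n * self.voxel_volume_cc

    def fraction_at_least(self, d: float) -> float:
        """Fraction of the structure volume receiving >= d Gy."""
        d_eff = d - _REL_TOL * max(1.0, abs(d))
        idx = np.searchsorted(self.samples, d_eff, side="left")
        return float(self.n - idx) / self.n

    def binned(self, bin_gy: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """(dose, fraction >= dose) sampled on a regular grid for export."""
        top = float(self.samples[-1]) + bin_gy
        doses = np.arange(0.0, top + bin_gy, bin_gy)
        fracs = np.array([self.fraction_at_least(d) for d in doses])
        return doses, fracs


def resample_dose(dose: DoseGrid, grid: SpatialGrid, mode: str = "trilinear") -> DoseGrid:
    """Resample a dose grid onto a structure grid (trilinear or nearest)."""
    if dose.grid.matches(grid):
        return dose
    order = {"trilinear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown resampling mode {mode!r}")
    # fractional indices of the target voxel centers in the source grid
    def frac_idx(axis: int) -> np.ndarray:
        return (grid.axis_coords(axis) - dose.grid.origin[axis]) / dose.grid.spacing[axis]

    zz, yy, xx = np.meshgrid(frac_idx(2), frac_idx(1), frac_idx(0), indexing="ij")
    values = ndimage.map_coordinates(
        dose.values, [zz, yy, xx], order=order, mode="nearest"
    )
    return DoseGrid(grid, values, scaling_note=f"{dose.scaling_note}; resampled ({mode})")


def compute_dvh(dose: DoseGrid, mask: StructureMask) -> DVHCurve:
    """DVH of the dose restricted to the structure's occupied voxels."""
    if not dose.grid.matches(mask.grid):
        raise ValueError(
            f"dose and structure {mask.structure_id!r} are on different grids; "
            "resample the dose first (resample_dose)"
        )
    if mask.is_empty:
        raise ValueError(f"cannot compute DVH of empty structure {mask.structure_id!r}")
    samples = dose.values[mask.occupancy]
    return DVHCurve(
        structure_id=mask.structure_id,
        samples=samples,
        voxel_volume_cc=mask.grid.voxel_volume_mm3 / 1000.0,
    )


def dose_at_volume(dvh: DVHCurve, spec: MetricSpec) -> float:
    """Dx% or Dv cc: greatest dose received by at least that much volume."""
    n = dvh.n
    if spec.kind == "D_percent":
        count = n * spec.argument / 100.0
    elif spec.kind == "D_cc":
        if spec.argument > dvh.volume_cc + _REL_TOL:
            raise ValueError(
                f"D{spec.argument:g}cc exceeds the structure volume "
                f"({dvh.volume_cc:.3f} cc) of {dvh.structure_id!r}"
            )
        count = spec.argument / dvh.voxel_volume_cc
    else:
        raise ValueError(f"dose_at_volume expects D_percent or D_cc, got {spec.kind}")
    k = int(math.ceil(count - _REL_TOL * max(1.0, count)))
    k = min(max(k, 1), n)
    return float(dvh.samples[n - k])


def volume_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """VxGy: percentage of the structure volume receiving at least ``d_gy``."""
    if d_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    return 100.0 * dvh.fraction_at_least(d_gy)


def homogeneity_index(dvh: DVHCurve, rx_gy: float) -> float:
    """100 x (D5% - D95%) / prescription — target dose spread in percent."""
    if rx_gy <= 0:
        raise ValueError("prescription dose must be positive")
    d5 = dose_at_volume(dvh, MetricSpec("D_percent", 5))
    d95 = dose_at_volume(dvh, MetricSpec("D_percent", 95))
    return 100.0 * (d5 - d95) / rx_gy


def normalize_prescription(
    dose: DoseGrid, target: StructureMask, rx_gy: float
) -> tuple[DoseGrid, float]:
    """Rescale the dose so D95% of the target equals the prescription.

    Returns the scaled grid and the scale factor. After scaling, at least 95%
    of the target volume receives >= rx on the empirical distribution.
    """
    dvh = compute_dvh(dose, target)
    d95 = dose_at_volume(dvh, MetricSpec("D_percent", 95))
    if d95 <= 0:
        raise ValueError(
            f"cannot normalize: D95% of {target.structure_id!r} is {d95:g} Gy"
        )
    scale = rx_gy / d95
    scaled = DoseGrid(
        dose.grid,
        dose.values * scale,
        scaling_note=f"{dose.scaling_note}; normalized D95%({target.structure_id})={rx_gy:g} Gy",
    )
    return scaled, scale


@dataclass
class MetricResult:
    structure_id: str
    spec: MetricSpec
    value: float | None
    units: str
    flagged: bool = False
    message: str = ""

    def key(self) -> str:
        return f"{self.structure_id}:{self.spec.label()}"


def _resolve_goal_mask(
    structure_id: str,
    masks: dict[str, StructureMask],
    dictionary: StructureDictionary | None,
    bilateral: dict[str, list[str]],
) -> StructureMask | None:
    try:
        match = match_structure(structure_id, list(masks), dictionary)
    except AmbiguousMatchError:
        return None
    if match.matched is not None:
        return masks[match.matched]
    parts = bilateral.get(structure_id)
    if parts:
        resolved = []
        for p in parts:
            try:
                m = match_structure(p, list(masks), dictionary)
            except AmbiguousMatchError:
                return None
            if m.matched is None:
                return None
            resolved.append(masks[m.matched])
        return boolean_combine(resolved, "union", structure_id)
    return None


def evaluate_metrics(
    dose: DoseGrid,
    masks: dict[str, StructureMask],
    goals: list[ClinicalGoal],
    target_id: str | None = None,
    rx_gy: float | None = None,
    dictionary: StructureDictionary | None = None,
    config: AutomationConfig | None = None,
) -> list[MetricResult]:
    """Evaluate every clinical goal, plus the target homogeneity index.

    Goal structures are resolved through the structure dictionary; a goal
    naming a bilateral structure (e.g. ``OpticNerve``) is evaluated on the
    union of its configured left/right component masks. Unresolvable
    structures yield flagged results rather than exceptions.
    """
    bilateral = dict(config.bilateral_structures) if config else {}
    dvh_cache: dict[str, DVHCurve] = {}
    results: list[MetricResult] = []

    def dvh_for(structure_id: str) -> DVHCurve | None:
        if structure_id in dvh_cache:
            return dvh_cache[structure_id]
        mask = _resolve_goal_mask(structure_id, masks, dictionary, bilateral)
        if mask is None or mask.is_empty:
            return None
        curve = compute_dvh(dose, mask)
        dvh_cache[structure_id] = curve
        return curve

    for goal in goals:
        curve = dvh_for(goal.structure_id)
        if curve is None:
            results.append(
                MetricResult(
                    goal.structure_id,
                    goal.metric,
                    None,
                    goal.metric.result_units,
                    flagged=True,
                    message=f"structure {goal.structure_id!r} not found in structure set",
                )
            )
            continue
        spec = goal.metric
        if spec.kind in ("D_percent", "D_cc"):
            value = dose_at_volume(curve, spec)
        elif spec.kind == "V_gy":
            value = volume_at_dose(curve, spec.argument)
        elif spec.kind == "D_min":
            value = float(curve.samples[0])
        elif spec.kind == "D_max":
            value = float(curve.samples[-1])
        else:  # HI as an explicit goal
            if rx_gy is None:
                raise ValueError("HI goal requires the prescription dose")
            value = homogeneity_index(curve, rx_gy)
        results.append(MetricResult(goal.structure_id, spec, value, spec.result_units))

    if target_id is not None and rx_gy is not None:
        curve = dvh_for(target_id)
        if curve is None:
            results.append(
                MetricResult(
                    target_id,
                    MetricSpec("HI"),
                    None,
                    "%",
                    flagged=True,
                    message=f"target {target_id!r} not found in structure set",
                )
            )
        else:
            results.append(
                MetricResult(target_id, MetricSpec("HI"), homogeneity_index(curve, rx_gy), "%")
            )
    return results


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test and cohort comparison
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # sum of positive ranks
    p: float  # two-sided
    n_effective: int
    method: str  # "exact" | "normal" | "degenerate"
    note: str = ""


def _exact_two_sided_p(doubled_ranks: np.ndarray, w2: int) -> float:
    """Two-sided p over all 2^n sign assignments of the (doubled) ranks.

    The null distribution of the positive-rank sum is symmetric about half
    the total rank sum, so the two-sided p is the probability mass at least
    as far from the center as the observed statistic.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    center = total / 2.0
    dev = abs(w2 - center)
    sums = np.arange(total + 1)
    mass = counts[np.abs(sums - center) >= dev - 1e-9].sum()
    return float(mass / 2.0 ** len(doubled_ranks))


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]],
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Differences are a - b; zero differences are dropped (``wilcox``) or
    ranked and then discarded from the statistic (``pratt``). Ties receive
    average ranks. The p-value is exact — full enumeration over sign
    assignments via dynamic programming — for up to 25 effective pairs, and a
    tie-corrected normal approximation with continuity correction beyond.
    """
    if not 1 <= len(pairs) <= 50:
        raise ValueError("wilcoxon_signed_rank requires 1 <= n <= 50 pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return WilcoxonResult(
            w=0.0, p=1.0, n_effective=0, method="degenerate", note="all differences are zero"
        )

    if zero_method == "wilcox":
        d = nonzero
        ranks = stats.rankdata(np.abs(d))
    else:  # pratt: rank with zeros included, then drop the zero ranks
        all_ranks = stats.rankdata(np.abs(diffs))
        keep = diffs != 0
        d = diffs[keep]
        ranks = all_ranks[keep]
    n = d.size
    w = float(ranks[d > 0].sum())

    if n <= _EXACT_N_MAX:
        doubled = np.round(2 * ranks).astype(np.int64)
        p = _exact_two_sided_p(doubled, int(round(2 * w)))
        return WilcoxonResult(w=w, p=min(p, 1.0), n_effective=n, method="exact")

    # normal approximation with tie correction
    mu = float(ranks.sum()) / 2.0
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(w=w, p=1.0, n_effective=n, method="degenerate", note="zero variance")
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    p = 2.0 * stats.norm.sf(z)
    return WilcoxonResult(w=w, p=min(p, 1.0), n_effective=n, method="normal")


@dataclass
class CohortComparison:
    """Paired comparison of one dose metric between two planning techniques."""

    metric_label: str
    values_a: list[float]
    values_b: list[float]
    differences: list[float] = field(init=False)
    mean_difference: float = field(init=False)
    median_difference: float = field(init=False)
    w_statistic: float = field(init=False)
    p_value: float = field(init=False)
    significant: bool = field(init=False)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.values_a) != len(self.values_b):
            raise ValueError(
                f"paired cohorts must have equal length, got "
                f"{len(self.values_a)} vs {len(self.values_b)}"
            )
        if not self.values_a:
            raise ValueError("paired cohorts must be non-empty")
        diffs = [a - b for a, b in zip(self.values_a, self.values_b)]
        self.differences = diffs
        self.mean_difference = float(np.mean(diffs))
        self.median_difference = float(np.median(diffs))
        res = wilcoxon_signed_rank(list(zip(self.values_a, self.values_b)))
        self.w_statistic = res.w
        self.p_value = res.p
        self.significant = res.p < self.alpha

    def summary_row(self) -> dict:
        """One row of the comparison table (metric, A mean(sd), B mean(sd), diff(p))."""
        return {
            "metric": self.metric_label,
            "a_mean": float(np.mean(self.values_a)),
            "a_sd": float(np.std(self.values_a, ddof=1)) if len(self.values_a) > 1 else 0.0,
            "b_mean": float(np.mean(self.values_b)),
            "b_sd": float(np.std(self.values_b, ddof=1)) if len(self.values_b) > 1 else 0.0,
            "difference": self.mean_difference,
            "p": self.p_value,
            "significant": self.significant,
        }


def compare_cohorts(
    metric_label: str, values_a: list[float], values_b: list[float]
) -> CohortComparison:
    """Wilcoxon paired comparison of a metric across two plan cohorts."""
    return CohortComparison(metric_label, list(values_a), list(values_b))


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

_TIMING_ORDER = ("application_start", "plan_trigger", "planning_start", "planning_end")


@dataclass
class TimingLog:
    """Workflow timestamps and the derived efficiency endpoints.

    TTE (time to execute) is the interval from application launch to the
    plan-creation trigger; TPT (technical planning time) runs from planning
    start to planning end.
    """

    application_start: _dt.datetime
    plan_trigger: _dt.datetime
    planning_start: _dt.datetime
    planning_end: _dt.datetime

    def __post_init__(self) -> None:
        times = [getattr(self, name) for name in _TIMING_ORDER]
        for earlier, later, a, b in zip(times, times[1:], _TIMING_ORDER, _TIMING_ORDER[1:]):
            if later < earlier:
                raise ValueError(f"timestamp {b} precedes {a}")

    @property
    def tte_seconds(self) -> float:
        return (self.plan_trigger - self.application_start).total_seconds()

    @property
    def tpt_seconds(self) -> float:
        return (self.planning_end - self.planning_start).total_seconds()

    def as_dict(self) -> dict:
        return {
            **{name: getattr(self, name).isoformat() for name in _TIMING_ORDER},
            "tte_seconds": self.tte_seconds,
            "tpt_seconds": self.tpt_seconds,
        }
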
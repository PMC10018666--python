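# Methods

This note records the models, conventions and numerical choices behind
`rtautoplan`, and what the synthetic test bed does and does not demonstrate.

## Coordinate and geometry conventions

All geometry is in DICOM patient coordinates (LPS: +x left, +y posterior,
+z superior), in millimetres. Grids are axis-aligned with identity direction
cosines; oblique acquisitions are rejected at load rather than resampled,
which matches axial planning CTs and removes interpolation ambiguity from
every downstream geometric statement. A voxel is represented by its center;
indices are 0-based and arrays are ordered (z, y, x).

**Rasterization.** A voxel belongs to a structure iff its center lies inside
an odd number of that slice's contour polygons (even-odd rule), so inner
contours act as holes. This rule is deterministic and exactly invertible for
testing: re-rasterizing traced contours reproduces the occupancy away from
the half-voxel band around the traced curve, and the contour→mask→contour
cycle is idempotent after one pass. Mask-to-contour tracing uses marching
squares at the 0.5 iso-level on a zero-padded slice.

**Margins.** Margins are center-to-center Euclidean distances computed with
an anisotropy-aware distance transform: a positive margin d occupies every
voxel whose center lies within d of an occupied center; a negative margin is
the morphological dual (complement of dilating the complement). A 1e-6 mm
tolerance absorbs floating-point ties at exactly d. The margin engine is
verified against brute-force dilation with the discrete Euclidean ball. The
per-axis (box) margin used by some planning systems is *not* implemented;
the Euclidean choice is the documented convention of this package.

**Rings.** `ring(S, inner, outer)` is the set difference of the outer and
inner expansions. Because the inner expansion contains S whenever
inner ≥ 0, the ring always excludes the source structure itself — so the
5 mm dose-control ring `NS_Ring_05` never overlaps the target.

## Templates and matching

The clinical protocol is a package-defined XML schema
(`data/clinical_protocol.xsd`) carrying prescription (with the
total = fractions × dose/fraction consistency check), default machine,
templated fields in IEC 61217 angles, and clinical goals. Vendor protocol
grammars are intentionally not reproduced; the schema mirrors the *content*
a planning template exposes.

Structure-name resolution runs three deterministic tiers: case-insensitive
exact match, then dictionary synonym (the packaged dictionary maps canonical
ids to institutional synonyms, and lookup works in both directions), then a
normalized comparison with spaces/underscores/hyphens stripped. The first
tier with exactly one hit wins; two or more hits in one tier is an
ambiguity *error* rather than an arbitrary pick, because silently choosing
between `ptv_3000` and `PTV_3000` would be clinically unsafe. No hit in any
tier yields a flagged (never dropped) result. KBP model structure mapping is
one-to-one with flags; a one-to-many aggregation policy is known to exist in
some models and is deliberately not implemented.

## Derived structures

Derivation rules are small ordered programs over verbs
union/intersection/subtraction/margin/ring/crop_to, with operands resolved
through the matcher; later rules may consume earlier outputs, and `$k`
references step k within a rule. A rule with an unresolved operand is
flagged and skipped while the remaining rules still run (pass-or-flag
semantics); a rule consuming its own output is a hard error.

The packaged HA-WBRT rules build `Hippocampi_05` (5 mm hippocampal PRV),
`NS_Ring_05` (0–5 mm ring on the PTV), `PTV_WBopt` (PTV minus the
hippocampal PRV) and `NS_FaceAvoid` (Body cropped anterior and inferior of
the PTV centroid, minus a 10 mm PTV expansion). The exact clinical
definitions of the optimization PTV and the face-avoidance structure live in
an external KBP model description; the constructions here are simple,
fully configurable stand-ins consistent with their purpose (excluding the
spared region from the optimization target; keeping dose off the face), and
they are config entries, not code.

## Plan layout

The isocenter is the center of the target's axis-aligned bounding box,
rounded to 0.1 mm — preferred over the centroid for robustness to
asymmetric inferior target extent (the centroid is available separately).
The packaged template instantiates three full arcs between gantry 180.1°
and 179.9° travelling *through* 0° (359.8° span across the anterior side)
in alternating direction, collimators 345°/15°/90°.

Jaw fitting projects the target orthographically onto the collimator-rotated
beam's-eye-view axes at gantry samples every 10° (configurable) along the
arc. Voxels are projected as axis-aligned boxes (center ± half-spacing), so
the fitted rectangle encloses every occupied voxel entirely, plus the
requested margin (default 7 mm). The beam model places the source anterior
at gantry 0 with angles increasing clockwise seen from the couch foot;
projections beyond a 200 mm half-field raise an error. The written RT Plan
is a skeleton: two control points per arc, fitted jaws, parked MLC, no
monitor units.

## Validation checks

Checks are pure functions of an explicit case context and an injected date —
no hidden wall-clock reads — and return one of four states ordered
pass < tracked < warning < flag; a report's overall state is the maximum,
and recorded parameter overrides elevate an otherwise clean report to
"tracked". The image-age boundary is strict ("more than 14 days"): exactly
14 days passes. Future-dated images are flagged with a distinct message.
Flags never abort the pipeline; every outcome is reported and execution
continues, with the exit code reserved for hard errors.

## DVH and metrics

The DVH is sample-based: the empirical distribution of the per-voxel doses
inside the structure, with no pre-binning (the 0.05 Gy binning applies only
to exported display curves). Dx% and Dv cc are pure order statistics: the
greatest dose received by at least the requested volume, so D100% is the
minimum sample, V(D(x%)) ≥ x% holds for every x, and prescription
normalization (scale = D_Rx / D95%) yields V_Rx ≥ 95% *exactly* on the
empirical distribution — this exactness is why interpolated quantiles were
rejected. Dose comparisons carry a 1e-9 relative tolerance to absorb the
one-ulp round-off the normalization scale factor can introduce at the
prescription threshold. Bilateral goal structures (e.g. `OpticNerve`) are
evaluated on the union of their configured left/right component masks. Dose
grids on a different grid than the structures are resampled explicitly
(trilinear by default, nearest-neighbor by flag) before evaluation.

The homogeneity index is reported in percent, HI = 100 × (D5% − D95%)/D_Rx.

**Wilcoxon signed-rank.** Differences a − b; zeros dropped by default
(Pratt's zero-rank handling behind a flag); average ranks for ties. For up
to 25 effective pairs the two-sided p is exact: ranks are doubled to
integers and the null distribution of the positive-rank sum is built by
dynamic programming over all 2ⁿ sign assignments; since that distribution is
symmetric about half the total rank sum, the two-sided p is the mass at
least as far from the center as observed. Beyond 25 pairs a tie-corrected
normal approximation with continuity correction is used. The exact path is
tested against full brute-force enumeration and against an independent
library implementation on tie-free data.

## Synthetic phantom and dose model

The phantom emulates one HA-WBRT case on a 2.5 mm isotropic 96³ grid:
ellipsoidal Body and whole-brain `PTV_3000`, bilateral hippocampal
ellipsoids (3.0 cc per side nominal, merged into one `Hippocampi`
structure), optic nerve cylinders and an optic chiasm placed
anterior-inferior of the brain target with realistic clearance. The seed
drives a ±1 mm sub-voxel jitter of structure centers and the dose noise;
everything else is deterministic integer geometry, so a seeded case is
bit-reproducible.

The dose model is a geometric emulation, not physics:

    dose = Rx · (1 + ripple) · exp(−d_PTV / L) · (1 − depth · exp(−d_H² / 2w²)) + noise

with a smooth sinusoidal ripple (amplitude 0.04, wavelength 70 mm) over the
target plateau, exponential falloff (L = 12 mm) outside the PTV, Gaussian
cold wells (depth 0.73, shoulder w = 2.5 mm) carved around the hippocampi
via the distance transform, additive Gaussian noise (σ = 0.15 Gy) and
clipping at zero. `scripts/calibrate_phantom.py` is the committed
calibration: it sweeps the cold-well depth against the packaged goal set and
the frozen default is one step deeper than the shallowest passing well,
landing the hippocampal minimum dose near the ~8 Gy typical of clinical
HA-WBRT plans with margin to the 9 Gy limit.

What passing tests on this phantom *do* show: the whole pipeline — template
interpretation, derivation, matching, layout, validation, metric evaluation,
DICOM round trips — behaves correctly on a case with the right topology,
containment and dose pattern. What they do *not* show: performance on real
anatomy (no gyri, no heterogeneity, no contour noise), realistic dose
gradients from a physical optimizer, or the clinical cohort statistics
reported for real patients, which require patient data and a commercial
optimization engine.

## Problem sizes and tolerances

Default test problem sizes: 16³–24³ grids for morphology/boolean oracle
equivalence, 20³ for the 100-case metric-oracle sweep, the 96³ phantom for
end-to-end runs. Oracle comparisons are exact (bit-equality for masks,
`pytest.approx` at default relative tolerance for doses); the only
deliberate slack values are the 1e-6 mm geometric tie tolerance, the 1e-9
relative dose-threshold tolerance, and the 5% mask round-trip band for
contour tracing, each documented above. CT voxel values use a two-tissue
model (air/soft tissue) and nothing downstream reads Hounsfield units.

## Known limitations

- No oblique grids, deformable operations or partial-volume fractions.
- Plan skeletons only: no MLC sequencing, MU, or collimator optimization.
- One-to-one KBP structure mapping (no many-to-one aggregation).
- The synthetic dose model cannot stand in for dosimetric validation of a
  real optimizer; it exists to exercise the evaluation machinery.
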
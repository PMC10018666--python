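# rtautoplan

A vendor-independent Python library and command-line tool that reproduces the
scaffold of template-guided automated radiotherapy planning, using
hippocampal-avoidance whole brain radiotherapy (HA-WBRT) as the packaged use
case. It is aimed at medical-physics developers who want to prototype and
test planning-automation logic — template interpretation, derived-structure
building, structure-name matching, VMAT field layout, planning integrity
checks and DVH-based plan evaluation — without a commercial treatment
planning system, on fully synthetic DICOM cases.

What it deliberately does **not** do: inverse optimization, physical dose
calculation, knowledge-based-planning (KBP) DVH estimation, or any TPS
integration. Plans produced here are *skeletons* (arcs, jaws, isocenter, open
MLC); dose grids come either from a DICOM RT Dose file or from a synthetic
dose model that emulates the HA-WBRT dose pattern.

## What it computes

For a structure with per-voxel dose samples, the evaluator computes standard
dose-volume metrics on the empirical distribution:

- **Dx% / Dv cc** — the greatest dose d such that at least x% of the
  structure volume (or v cm³) receives ≥ d; D100% is the minimum dose.
- **Vx Gy** — the percentage of the structure volume receiving ≥ x Gy.
- **Homogeneity index** — HI = 100 × (D5% − D95%) / D_Rx, in percent.
- **Prescription normalization** — the dose grid is rescaled so that
  D95%(target) = D_Rx, after which V_Rx(target) ≥ 95% holds exactly on the
  empirical distribution.
- **Paired plan comparison** — two-sided Wilcoxon signed-rank test with an
  exact enumerated null distribution up to n = 25 (ties handled with average
  ranks; zero differences dropped, Pratt handling optional), significance at
  p < 0.05.

The packaged HA-WBRT template prescribes 30 Gy in 10 fractions to the
whole-brain target `PTV_3000` with three full VMAT arcs (gantry
180.1° → 179.9° through 0°, alternating travel direction, collimators
345°/15°/90°), isocenter at the center of the PTV bounding box, and the
NRG-CC001 clinical goals (e.g. hippocampi D100% ≤ 9 Gy, optic apparatus
D0.03 cm³ ≤ 30 Gy, PTV V30Gy ≥ 95%).

## Worked example

Generate the seeded default phantom case and run the whole pipeline with the
synthetic dose engine:

```bash
rtautoplan phantom --seed 1234 --out case/ --today 2024-01-01
rtautoplan run --ct case/ct --rtstruct case/rtstruct.dcm \
    --dose-engine synthetic --out plan/ --seed 1234 --today 2024-01-05
```

This writes `rtstruct_derived.dcm` (with the derived structures
`Hippocampi_05`, `NS_Ring_05`, `PTV_WBopt`, `NS_FaceAvoid`),
`rtplan_skeleton.dcm`/`.json`, `validation_report.json`, `metrics.csv`,
`dvh.csv`, `timing.json` and `events.log`. The same evaluation through the
library:

```python
from rtautoplan import phantom, dose_eval
from rtautoplan.templates import parse_clinical_protocol, packaged_data_path
from rtautoplan.structure_builder import default_hawbrt_config

spec = phantom.load_default_spec(seed=1234)
ct, masks = phantom.generate_phantom(spec)
dose = phantom.generate_dose(masks, spec.dose_model)
dose, scale = dose_eval.normalize_prescription(dose, masks["PTV_3000"], 30.0)
protocol = parse_clinical_protocol(packaged_data_path("hawbrt_protocol.xml").read_text())
for m in dose_eval.evaluate_metrics(dose, masks, protocol.clinical_goals,
                                    target_id="PTV_3000", rx_gy=30.0,
                                    config=default_hawbrt_config()):
    print(f"{m.structure_id:12s} {m.spec.label():8s} {m.value:7.2f} {m.units}")
```

prints:

```
PTV_3000     D2%        31.97 Gy
PTV_3000     D98%       29.54 Gy
PTV_3000     V30Gy      95.00 %
Hippocampi   D100%       7.76 Gy
Hippocampi   D0.03cc     8.79 Gy
OpticNerve   D0.03cc    17.25 Gy
OpticChiasm  D0.03cc    17.03 Gy
PTV_3000     HI          5.88 %
```

Read: after normalization the prescription covers exactly 95% of the target
(V30Gy), the hottest 2% of the target stays well under the 37.5 Gy limit,
the minimum hippocampal dose is spared below 9 Gy, and the optic structures
sit in the dose falloff far below their 30 Gy limits — all seven packaged
goals pass, so the validation report's goal section is all "pass".

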
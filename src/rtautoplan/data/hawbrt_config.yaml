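# Automation configuration for the HA-WBRT template.
#
# derivation_rules: declarative instructions executed in order by the
# structure builder. Operands name existing structures or the outputs of
# earlier rules; "$k" refers to the result of step k (0-based) within the
# same rule. Distances are millimetres.
#
# The optimization target PTV_WBopt (whole-brain PTV minus the hippocampal
# planning-risk volume) and the anterior-inferior face avoidance structure
# NS_FaceAvoid are configurable stand-ins: their exact clinical definitions
# live in the published knowledge-based-planning model description, so the
# constructions below are deliberately simple and fully parameterized here.

protocol_id: HA-WBRT_30Gy_10fx

derivation_rules:
  - output: Hippocampi_05
    steps:
      - {verb: margin, operands: [Hippocampi], mm: 5}
  - output: NS_Ring_05
    steps:
      - {verb: ring, operands: [PTV_3000], inner_mm: 0, outer_mm: 5}
  - output: PTV_WBopt
    steps:
      - {verb: subtraction, operands: [PTV_3000, Hippocampi_05]}
  - output: NS_FaceAvoid
    steps:
      - {verb: crop_to, operands: [Body, PTV_3000], directions: [anterior, inferior]}
      - {verb: margin, operands: [PTV_3000], mm: 10}
      - {verb: subtraction, operands: ["$0", "$1"]}

model_structure_map:
  - {planning: PTV_WBopt, model: PTV_WB}
  - {planning: Hippocampi_05, model: Hippocampi_PRV}
  - {planning: Hippocampi, model: Hippocampi}
  - {planning: OpticNerve_L, model: OpticNerve_L}
  - {planning: OpticNerve_R, model: OpticNerve_R}
  - {planning: OpticChiasm, model: OpticChiasm}
  - {planning: NS_Ring_05, model: NS_Ring}
  - {planning: NS_FaceAvoid, model: NS_FaceAvoid}

target_dose_map:
  - {target: PTV_WBopt, dose_gy: 30.0}

bilateral_structures:
  OpticNerve: [OpticNerve_L, OpticNerve_R]
  Hippocampi: [Hippocampi_L, Hippocampi_R]

algorithm_overrides:
  dose_calculation.grid_mm: "2.5"
  optimization.mr_level: "4"
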
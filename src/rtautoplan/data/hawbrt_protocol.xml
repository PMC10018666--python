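<?xml version="1.0" encoding="UTF-8"?>
<!-- Hippocampal-avoidance whole brain radiotherapy (HA-WBRT) template:
     30 Gy in 10 fractions to the whole-brain PTV with a 3-arc VMAT layout.
     Each arc runs between gantry 180.1 and 179.9 (through 0 degrees, i.e. a
     full arc across the anterior side) in alternating travel direction, with
     collimator angles 345, 15 and 90 degrees. Clinical goals follow the
     NRG-CC001 dose constraints. -->
<ClinicalProtocol id="HA-WBRT_30Gy_10fx">
  <Prescription totalDoseGy="30" fractions="10" dosePerFractionGy="3" target="PTV_3000"/>
  <Machine id="TB1"/>
  <Fields>
    <Field id="CW1" technique="arc" gantryStart="180.1" gantryStop="179.9" rotation="CW" collimator="345" couch="0" energy="6X"/>
    <Field id="CC1" technique="arc" gantryStart="179.9" gantryStop="180.1" rotation="CC" collimator="15" couch="0" energy="6X"/>
    <Field id="CW2" technique="arc" gantryStart="180.1" gantryStop="179.9" rotation="CW" collimator="90" couch="0" energy="6X"/>
  </Fields>
  <Goals>
    <Goal structure="PTV_3000" metric="D2%" compare="le" threshold="37.5"/>
    <Goal structure="PTV_3000" metric="D98%" compare="ge" threshold="25"/>
    <Goal structure="PTV_3000" metric="V30Gy" compare="ge" threshold="95"/>
    <Goal structure="Hippocampi" metric="D100%" compare="le" threshold="9"/>
    <Goal structure="Hippocampi" metric="D0.03cc" compare="le" threshold="16"/>
    <Goal structure="OpticNerve" metric="D0.03cc" compare="le" threshold="30"/>
    <Goal structure="OpticChiasm" metric="D0.03cc" compare="le" threshold="30"/>
  </Goals>
  <ExpectedStructures>
    <Structure id="Body"/>
    <Structure id="PTV_3000"/>
    <Structure id="Hippocampi"/>
    <Structure id="OpticNerve_L"/>
    <Structure id="OpticNerve_R"/>
    <Structure id="OpticChiasm"/>
  </ExpectedStructures>
</ClinicalProtocol>
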
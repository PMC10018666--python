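<?xml version="1.0" encoding="UTF-8"?>
<!-- Structure name dictionary: canonical ids with institutional synonyms,
     used to locate template structures in structure sets whose identifiers
     do not match the template nomenclature exactly. -->
<StructureDictionary>
  <Structure id="PTV_3000">
    <Synonym>PTV_Brain</Synonym>
    <Synonym>PTV Brain 30Gy</Synonym>
    <Synonym>PTV30</Synonym>
  </Structure>
  <Structure id="Hippocampi">
    <Synonym>Hippocampus</Synonym>
    <Synonym>Hippocampus_Comb</Synonym>
  </Structure>
  <Structure id="OpticChiasm">
    <Synonym>Optic Chiasm</Synonym>
    <Synonym>Chiasm</Synonym>
  </Structure>
  <Structure id="OpticNerve_L">
    <Synonym>Optic Nerve L</Synonym>
    <Synonym>Lt Optic Nerve</Synonym>
  </Structure>
  <Structure id="OpticNerve_R">
    <Synonym>Optic Nerve R</Synonym>
    <Synonym>Rt Optic Nerve</Synonym>
  </Structure>
  <Structure id="Body">
    <Synonym>External</Synonym>
    <Synonym>BODY</Synonym>
  </Structure>
</StructureDictionary>
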
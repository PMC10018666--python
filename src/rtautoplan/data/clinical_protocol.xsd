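<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:element name="ClinicalProtocol">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Prescription">
          <xs:complexType>
            <xs:attribute name="totalDoseGy" type="xs:double" use="required"/>
            <xs:attribute name="fractions" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="dosePerFractionGy" type="xs:double" use="required"/>
            <xs:attribute name="target" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="Machine">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="Fields">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Field" minOccurs="1" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="technique" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="arc"/>
                        <xs:enumeration value="static"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="gantryStart" type="xs:double" use="required"/>
                  <xs:attribute name="gantryStop" type="xs:double" use="required"/>
                  <xs:attribute name="rotation" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="CW"/>
                        <xs:enumeration value="CC"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="collimator" type="xs:double" use="required"/>
                  <xs:attribute name="couch" type="xs:double"/>
                  <xs:attribute name="energy" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="Goals" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Goal" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="structure" type="xs:string" use="required"/>
                  <xs:attribute name="metric" type="xs:string" use="required"/>
                  <xs:attribute name="compare" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="le"/>
                        <xs:enumeration value="ge"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="threshold" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="ExpectedStructures" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Structure" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
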
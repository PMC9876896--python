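<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:attributeGroup name="hitAttrs">
    <xs:attribute name="name" type="xs:string" use="required"/>
    <xs:attribute name="target_len" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="query_len" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="hmm_from" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="hmm_to" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="ali_from" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="ali_to" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="env_from" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="env_to" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="full_evalue" type="xs:double" use="required"/>
    <xs:attribute name="c_evalue" type="xs:double" use="required"/>
    <xs:attribute name="i_evalue" type="xs:double" use="required"/>
    <xs:attribute name="bitscore" type="xs:double" use="required"/>
    <xs:attribute name="acc" type="xs:double" use="required"/>
    <xs:attribute name="score" type="xs:double" use="required"/>
  </xs:attributeGroup>

  <xs:complexType name="hitType">
    <xs:attributeGroup ref="hitAttrs"/>
  </xs:complexType>

  <xs:element name="protein">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="length" type="xs:positiveInteger"/>
        <xs:element name="description" type="xs:string"/>
        <xs:element name="sequence" type="xs:string"/>
        <xs:element name="families">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="family" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="architecture">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="domain" type="hitType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
            <xs:attribute name="total_score" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="hits">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="hit" type="hitType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
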
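<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="urn:cohortfusion:acpa:1"
           xmlns="urn:cohortfusion:acpa:1"
           elementFormDefault="qualified">

  <xs:annotation>
    <xs:documentation>
      Service-contract schema for ACPA (anti-citrullinated protein antibody)
      result messages pushed from the research data store to a clinical
      decision support system. Each result carries exactly the four ACPA
      parameters measured in serum: the anti-CCP titre and the three fine
      specificities (citrullinated C1, enolase and fibrinogen IgG).
      Reconstruction of the described message content; the production WSDL/XSD
      of the source deployment is not reproduced verbatim.
    </xs:documentation>
  </xs:annotation>

  <xs:simpleType name="Titre">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="AcpaResult">
    <xs:sequence>
      <xs:element name="PatientId" type="xs:string"/>
      <xs:element name="ResultDate" type="xs:date"/>
      <xs:element name="CcpSerum" type="Titre" nillable="true"/>
      <xs:element name="CitC1IgGSerum" type="Titre" nillable="true"/>
      <xs:element name="CitEnoIgGSerum" type="Titre" nillable="true"/>
      <xs:element name="CitFibIgGSerum" type="Titre" nillable="true"/>
    </xs:sequence>
    <xs:attribute name="messageId" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:element name="GetACPAresultResponse">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Result" type="AcpaResult" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="schemaVersion" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
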
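<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="urn:cohortfusion:queryresult:1"
           xmlns="urn:cohortfusion:queryresult:1"
           elementFormDefault="qualified">

  <xs:annotation>
    <xs:documentation>
      Generic export schema for cross-source query results: a flat list of
      rows whose cells carry the originating source table as provenance.
    </xs:documentation>
  </xs:annotation>

  <xs:element name="QueryResult">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Row" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Cell" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="column" type="xs:string" use="required"/>
                      <xs:attribute name="source" type="xs:string" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="granularity" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
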
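<?xml version="1.0" encoding="UTF-8"?>
<!-- Structural schema for RSML 1.0 documents as produced by this
     package: rsml > metadata + scene*; scene > plant*; plant > root*
     with nested roots, polyline geometry and per-root properties. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">

  <xs:element name="rsml">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata" type="metadataType"/>
        <xs:element name="scene" type="sceneType" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="metadataType">
    <xs:sequence>
      <xs:element name="version" type="xs:string"/>
      <xs:element name="unit" type="xs:string"/>
      <xs:element name="resolution" type="xs:decimal"/>
      <xs:element name="software" type="xs:string" minOccurs="0"/>
      <xs:element name="property-definitions" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="property-definition" minOccurs="0"
                        maxOccurs="unbounded">
              <xs:complexType>
                <xs:sequence>
                  <xs:element name="label" type="xs:string"/>
                  <xs:element name="type" type="xs:string"/>
                  <xs:element name="unit" type="xs:string" minOccurs="0"/>
                </xs:sequence>
              </xs:complexType>
            </xs:element>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="last-modified" type="xs:string" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="sceneType">
    <xs:sequence>
      <xs:element name="plant" maxOccurs="unbounded">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="root" type="rootType" minOccurs="0"
                        maxOccurs="unbounded"/>
          </xs:sequence>
          <xs:attribute name="ID" type="xs:string" use="required"/>
          <xs:attribute name="label" type="xs:string"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="label" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="rootType">
    <xs:sequence>
      <xs:element name="properties" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:any processContents="skip" minOccurs="0"
                    maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="geometry">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="polyline">
              <xs:complexType>
                <xs:sequence>
                  <xs:element name="point" maxOccurs="unbounded">
                    <xs:complexType>
                      <xs:attribute name="x" type="xs:decimal"
                                    use="required"/>
                      <xs:attribute name="y" type="xs:decimal"
                                    use="required"/>
                    </xs:complexType>
                  </xs:element>
                </xs:sequence>
              </xs:complexType>
            </xs:element>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="root" type="rootType" minOccurs="0"
                  maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="ID" type="xs:string" use="required"/>
    <xs:attribute name="label" type="xs:string"/>
  </xs:complexType>

</xs:schema>
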
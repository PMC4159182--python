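{
  "contract": "ACPA result exchange",
  "version": "1.0",
  "schema": "acpa_result.xsd",
  "namespace": "urn:cohortfusion:acpa:1",
  "operations": {
    "GetACPAresultRequest": {
      "direction": "consumer->provider",
      "payload": "list of coded patient identifiers, or an updated-since timestamp"
    },
    "GetACPAresultResponse": {
      "direction": "provider->consumer",
      "payload": "GetACPAresultResponse document validating against acpa_result.xsd"
    },
    "update-notification": {
      "direction": "provider->exchange-index->consumer",
      "payload": "message identifier and coded patient identifier of a newly available result"
    }
  },
  "pairing": [["GetACPAresultRequest", "GetACPAresultResponse"]]
}
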
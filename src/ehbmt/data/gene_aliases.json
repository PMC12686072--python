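{
  "EARP1": "ESRP1",
  "C1ORF116": "C1ORF116",
  "C1orf116": "C1ORF116",
  "E-CADHERIN": "CDH1",
  "E-CAD": "CDH1",
  "VIMENTIN": "VIM"
}
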
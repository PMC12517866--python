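{
 "n_reports": 204,
 "n_cases": 21,
 "soc_tables": {
  "atorvastatin": [
   10,
   19,
   11,
   164
  ],
  "rosuvastatin": [
   5,
   26,
   16,
   157
  ]
 },
 "tto": {
  "atorvastatin": [
   6,
   3.0,
   1.25,
   27.25
  ],
  "rosuvastatin": [
   2,
   162.0,
   103.0,
   221.0
  ]
 }
}
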
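{
 "name": "scenario2",
 "fractions": [
  0.2,
  0.2,
  0.2,
  0.2,
  0.2
 ],
 "risks": [
  0.05,
  0.02,
  0.01,
  0.005,
  0.002
 ]
}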
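{
 "name": "scenario1",
 "fractions": [
  0.14285714285714285,
  0.14285714285714285,
  0.14285714285714285,
  0.14285714285714285,
  0.14285714285714285,
  0.14285714285714285,
  0.14285714285714285
 ],
 "risks": [
  0.1,
  0.05,
  0.02,
  0.01,
  0.005,
  0.002,
  0.001
 ]
}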
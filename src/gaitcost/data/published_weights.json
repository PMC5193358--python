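{
 "am": [
  -0.000227,
  -6.4e-05,
  0.000161,
  0.00143,
  1820.0
 ],
 "sl": [
  0.979,
  0.0345,
  1.07,
  -1.46,
  -0.00697
 ],
 "scales": {
  "mass": 100.0,
  "age": 100.0,
  "height": 10.0,
  "torque": 100.0
 },
 "provenance": "published"
}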
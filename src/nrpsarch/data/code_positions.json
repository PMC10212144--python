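{
 "g_center_offset": 4,
 "positions": {
  "s1": 179,
  "s10": 459,
  "s2": 189,
  "s3": 201,
  "s4": 211,
  "s5": 221,
  "s6": 231,
  "s7": 239,
  "s8": 247,
  "s9": 253
 },
 "reference": "refA",
 "version": "1"
}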
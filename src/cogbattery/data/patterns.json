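{
 "description": "Canonical 18-pattern rotation-task stimulus set; each code is a 9-bit grid, bit 3*row+col = cell (row,col), selected by deterministic enumeration in ascending code order.",
 "codes": [
  3,
  6,
  12,
  13,
  14,
  15,
  19,
  22,
  28,
  29,
  30,
  31,
  33,
  35,
  37,
  39,
  41,
  43
 ]
}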
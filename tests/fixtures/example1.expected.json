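{
 "identifier": ">chr",
 "residues": "ATTGCATGTcgatggATGGggaAAAATCGataggatAGATTTTTAAAACCCNNNNYYY",
 "case_runs": [
  [
   9,
   6
  ],
  [
   4,
   3
  ],
  [
   7,
   7
  ]
 ],
 "specials": [
  [
   55,
   24
  ],
  [
   1,
   24
  ],
  [
   1,
   24
  ]
 ],
 "line_rle": [
  [
   25,
   2
  ],
  [
   8,
   1
  ]
 ],
 "block_length": 58,
 "core": "ATTGCATGTCGATGGATGGGGAAAAATCGATAGGATAGATTTTTAAAACCCNNNN",
 "n_seq": 58,
 "n_spl": 3
}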
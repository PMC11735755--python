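{
 "frequencies": {
  "A": 50,
  "C": 14,
  "G": 10,
  "T": 80,
  "N": 4
 },
 "ranking": [
  "N",
  "G",
  "C",
  "T",
  "A"
 ],
 "sequence": "ATTGCATGTCGATGGATGGGGAAAAATCGATAGGATAGATTTTTAAAACCCNNNN",
 "rule1_prefix": "ATTZTZAATZTT",
 "digit_prefix": "1002021102",
 "pair_prefix": "RSSVS",
 "n_tar": 158,
 "expanded_total": 186,
 "added_characters": 28
}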
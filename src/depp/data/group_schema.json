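{
 "groups": {
  "G": 1, "A": 1, "V": 1, "L": 1, "I": 1,
  "F": 2, "W": 2, "Y": 2,
  "C": 3, "M": 3,
  "K": 4, "R": 4, "H": 4,
  "D": 5, "E": 5,
  "S": 6, "T": 6, "N": 6, "Q": 6,
  "P": 7
 },
 "names": {
  "1": "hydrocarbon-R",
  "2": "aromatic-uncharged",
  "3": "sulphur",
  "4": "positive",
  "5": "negative",
  "6": "polar-uncharged",
  "7": "proline"
 }
}
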
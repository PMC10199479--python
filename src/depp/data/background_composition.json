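{
 "A": 0.082591,
 "C": 0.013715,
 "D": 0.05456,
 "E": 0.067574,
 "F": 0.038643,
 "G": 0.070778,
 "H": 0.022725,
 "I": 0.059666,
 "K": 0.058464,
 "L": 0.096706,
 "M": 0.024227,
 "N": 0.040645,
 "P": 0.047052,
 "Q": 0.039343,
 "R": 0.055361,
 "S": 0.065672,
 "T": 0.053459,
 "V": 0.068776,
 "W": 0.010812,
 "Y": 0.029232
}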
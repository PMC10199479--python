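{
 "A": 0.089067,
 "C": 0.008068,
 "D": 0.066861,
 "E": 0.049686,
 "F": 0.03599,
 "G": 0.093675,
 "H": 0.020051,
 "I": 0.05557,
 "K": 0.042988,
 "L": 0.075847,
 "M": 0.016626,
 "N": 0.057778,
 "P": 0.046128,
 "Q": 0.034714,
 "R": 0.037992,
 "S": 0.083698,
 "T": 0.070753,
 "V": 0.070797,
 "W": 0.01219,
 "Y": 0.031524
}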
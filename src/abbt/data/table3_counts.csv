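participant,session,hand,abbt,bbt,epsilon_printed
P1,1,dominant,29,32,0.094
P2,1,dominant,46,50,0.080
P3,1,dominant,45,46,0.022
P4,1,dominant,38,42,0.095
P5,1,dominant,55,59,0.068
P6,1,dominant,47,52,0.096
P7,1,dominant,41,45,0.089
P8,1,dominant,38,40,0.050
P9,1,dominant,45,49,0.082
P1,1,non_dominant,25,29,0.038
P2,1,non_dominant,41,45,0.089
P3,1,non_dominant,39,42,0.071
P4,1,non_dominant,32,35,0.086
P5,1,non_dominant,47,51,0.078
P6,1,non_dominant,41,45,0.089
P7,1,non_dominant,37,37,0.000
P8,1,non_dominant,34,36,0.056
P9,1,non_dominant,45,46,0.022
P1,2,dominant,48,49,0.020
P2,2,dominant,42,46,0.087
P3,2,dominant,48,53,0.094
P4,2,dominant,48,53,0.094
P5,2,dominant,54,55,0.018
P6,2,dominant,52,58,0.003
P7,2,dominant,43,45,0.044
P8,2,dominant,41,43,0.047
P9,2,dominant,44,47,0.064
P1,2,non_dominant,40,40,0.000
P2,2,non_dominant,43,47,0.085
P3,2,non_dominant,41,42,0.024
P4,2,non_dominant,47,49,0.041
P5,2,non_dominant,46,48,0.042
P6,2,non_dominant,52,54,0.037
P7,2,non_dominant,38,40,0.050
P8,2,non_dominant,36,39,0.077
P9,2,non_dominant,38,40,0.050
P1,3,dominant,45,47,0.043
P2,3,dominant,50,50,0.000
P3,3,dominant,42,44,0.045
P4,3,dominant,52,55,0.055
P5,3,dominant,58,65,0.008
P6,3,dominant,43,46,0.065
P7,3,dominant,36,39,0.077
P8,3,dominant,41,45,0.089
P9,3,dominant,49,51,0.039
P1,3,non_dominant,37,37,0.000
P2,3,non_dominant,47,50,0.060
P3,3,non_dominant,37,40,0.075
P4,3,non_dominant,42,42,0.000
P5,3,non_dominant,55,60,0.083
P6,3,non_dominant,44,47,0.064
P7,3,non_dominant,36,39,0.077
P8,3,non_dominant,38,41,0.073
P9,3,non_dominant,46,48,0.042
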
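participant,session,hand,nc,vavg,pt_mean,pt_sd
P1,1,dominant,29,0.520,2.21,0.06
P1,1,non_dominant,25,0.503,2.27,1.19
P2,1,dominant,46,0.751,1.10,0.05
P2,1,non_dominant,41,0.729,1.14,0.02
P3,1,dominant,45,0.845,1.19,1.17
P3,1,non_dominant,39,0.718,1.11,1.11
P4,1,dominant,38,0.691,1.15,1.19
P4,1,non_dominant,32,0.540,1.17,0.03
P5,1,dominant,55,1.076,1.18,1.15
P5,1,non_dominant,47,0.852,1.18,1.15
P6,1,dominant,47,0.825,1.12,0.09
P6,1,non_dominant,41,0.759,1.14,0.04
P7,1,dominant,41,0.808,1.13,0.08
P7,1,non_dominant,37,0.664,1.15,1.13
P8,1,dominant,38,0.658,1.15,0.08
P8,1,non_dominant,34,0.550,1.16,1.19
P9,1,dominant,45,0.787,1.10,0.02
P9,1,non_dominant,45,0.789,1.10,0.08
P1,2,dominant,48,0.835,1.15,0.03
P1,2,non_dominant,40,0.681,1.19,0.03
P2,2,dominant,42,0.782,1.11,0.04
P2,2,non_dominant,43,0.776,1.10,0.09
P3,2,dominant,48,0.828,1.15,0.05
P3,2,non_dominant,41,0.712,1.16,0.02
P4,2,dominant,48,0.878,1.13,0.05
P4,2,non_dominant,47,0.855,1.16,0.09
P5,2,dominant,54,0.900,1.10,0.09
P5,2,non_dominant,46,0.818,1.10,0.06
P6,2,dominant,52,0.862,1.15,0.01
P6,2,non_dominant,52,1.035,1.15,0.07
P7,2,dominant,43,0.720,1.18,0.03
P7,2,non_dominant,38,0.687,1.16,1.17
P8,2,dominant,41,0.692,1.14,0.09
P8,2,non_dominant,36,0.637,1.16,0.08
P9,2,dominant,44,0.751,1.16,0.06
P9,2,non_dominant,38,0.636,1.14,0.06
P1,3,dominant,45,0.797,1.12,1.13
P1,3,non_dominant,37,0.622,1.19,0.03
P2,3,dominant,50,0.846,1.10,0.05
P2,3,non_dominant,47,0.824,1.15,0.07
P3,3,dominant,42,0.737,1.11,0.09
P3,3,non_dominant,37,0.613,1.11,0.01
P4,3,dominant,52,0.887,1.13,0.06
P4,3,non_dominant,42,0.693,1.12,1.12
P5,3,dominant,58,1.055,1.13,0.08
P5,3,non_dominant,55,0.967,1.19,0.06
P6,3,dominant,43,0.758,1.17,0.08
P6,3,non_dominant,44,0.757,1.13,0.07
P7,3,dominant,36,0.601,1.16,1.12
P7,3,non_dominant,36,0.657,1.18,0.01
P8,3,dominant,41,0.728,1.15,0.05
P8,3,non_dominant,38,0.658,1.17,0.06
P9,3,dominant,49,0.813,1.11,0.07
P9,3,non_dominant,46,0.808,1.10,0.07
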
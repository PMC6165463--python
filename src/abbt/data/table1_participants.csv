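participant,age,gender,dominant_hand,diagnosis_year
P1,72,male,left,2002
P2,57,female,left,2006
P3,54,female,left,2012
P4,55,male,left,2013
P5,45,male,left,2017
P6,70,male,left,2011
P7,65,female,right,2016
P8,73,male,left,2009
P9,71,female,right,2004
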
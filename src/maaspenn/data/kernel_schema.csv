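kernel_name,rank
SOFT,1.5
STANDARD,2.0
CHEST,2.5
DETAIL,3.5
BONE,4.5
BONEPLUS,5.0
LUNG,5.0
EDGE,5.5
B10f,1.0
B20f,1.5
B30f,2.0
B31f,2.0
B40f,2.5
B41f,2.5
B45f,3.0
B50f,3.5
B60f,4.5
B70f,5.0
B80f,5.5
A,1.5
B,2.0
C,2.5
D,3.5
L,4.0
E,4.5
EB,5.0
FC01,1.5
FC02,1.8
FC03,2.0
FC08,2.2
FC13,2.4
FC18,3.0
FC30,3.5
FC50,4.5
FC51,5.0
FC52,5.2
FC81,5.5
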
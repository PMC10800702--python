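Alternatives,C1,C2,C3,C4,C5,C6,C7,C8
Ap1,4,6,9,3,5,8,2,7
Ap2,7,3,2,4,6,5,9,8
Ap3,2,4,6,7,5,3,8,4
Ap4,5,7,3,2,4,8,5,2
Ap5,3,2,5,6,2,4,7,9
Ap6,9,8,4,3,6,7,2,5
Ap7,2,6,7,5,4,6,3,2
Ap8,6,5,4,6,3,2,7,8
OV,9,8,9,7,6,8,9,9
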
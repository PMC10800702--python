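Criteria,C1,C2,C3,C4,C5,C6,C7,C8
C1,1.00,5.00,3.00,0.50,3.00,0.33,0.25,9.00
C2,0.20,1.00,0.50,0.14,0.11,0.20,0.11,2.00
C3,0.33,2.00,1.00,0.50,3.00,0.25,0.13,9.00
C4,2.00,7.00,2.00,1.00,3.00,0.50,0.33,5.00
C5,0.33,9.00,0.33,0.33,1.00,2.00,0.14,4.00
C6,3.00,5.00,4.00,2.00,0.50,1.00,0.33,7.00
C7,4.00,9.00,8.00,3.00,7.00,3.00,1.00,9.00
C8,0.11,0.50,0.11,0.20,0.25,0.14,0.11,1.00
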
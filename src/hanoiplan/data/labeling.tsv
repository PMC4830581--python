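S1	1,1,1
S2	2,1,1
S3	3,1,1
S4	2,3,1
S5	3,2,1
S6	3,3,1
S7	1,3,1
S8	1,2,1
S9	2,2,1
S10	3,3,2
S11	2,2,3
S12	1,3,2
S13	2,3,2
S14	3,2,3
S15	1,2,3
S16	1,2,2
S17	2,1,2
S18	3,1,3
S19	1,3,3
S20	2,2,2
S21	3,2,2
S22	3,1,2
S23	1,1,2
S24	1,1,3
S25	2,1,3
S26	2,3,3
S27	3,3,3
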
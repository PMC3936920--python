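# Mitochondrial D-loop haplotype of each study female ("??" = undetermined).
id,haplotype
06-09,H6
19-10,??
41-11,H6
51-10,H6
58-10,H6
11-11,H6
10-10,H6
112-10,H6
45-10,H3
101-10,H3
113-10,H3
52-11,H3
28-09,H4
17-10,H4
36-11,H4
46-11,H4
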
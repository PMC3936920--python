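# Published pairwise matrices for the 16 study females.
# Upper triangle: Queller-Goodnight pairwise relatedness.
# Lower triangle: acoustic distance (Euclidean distance between mean PC1 scores).
,06-09,10-10,11-11,101-10,112-10,113-10,17-10,19-10,28-09,36-11,41-11,45-10,46-11,51-10,52-11,58-10
06-09,0.00,0.11,0.25,-0.18,0.03,-0.15,-0.17,0.61,-0.22,-0.20,0.29,0.12,0.05,0.12,-0.14,0.09
10-10,0.38,0.00,0.04,-0.08,0.41,-0.02,-0.15,0.10,-0.03,-0.09,0.00,-0.02,0.00,-0.02,-0.02,0.01
11-11,1.27,1.65,0.00,0.06,0.28,0.05,-0.17,0.24,-0.22,-0.03,-0.03,0.14,0.16,0.34,-0.04,0.62
101-10,0.14,0.24,1.41,0.00,0.08,0.01,-0.10,-0.20,0.00,-0.05,0.03,0.51,-0.22,0.01,0.16,-0.12
112-10,1.00,0.62,2.27,0.85,0.00,-0.01,-0.12,-0.06,0.06,-0.07,-0.14,0.08,0.09,-0.09,0.07,0.09
113-10,0.15,0.23,1.42,0.01,0.85,0.00,-0.05,-0.08,-0.02,0.01,0.19,0.09,0.11,0.09,0.36,0.02
17-10,1.96,2.34,0.69,2.10,2.95,2.11,0.00,-0.28,0.52,0.49,-0.02,-0.14,0.44,-0.05,-0.04,-0.19
19-10,0.08,0.46,1.19,0.22,1.08,0.23,1.88,0.00,-0.31,-0.05,0.44,0.10,-0.06,0.20,-0.24,0.16
28-09,1.02,1.40,0.25,1.16,2.01,1.17,0.94,0.94,0.00,0.23,-0.08,-0.19,0.17,-0.02,0.06,-0.15
36-11,2.82,3.20,1.55,2.96,3.82,2.97,0.87,2.74,1.81,0.00,-0.06,-0.08,0.38,0.10,0.01,-0.05
41-11,0.50,0.89,0.77,0.65,1.50,0.65,1.45,0.42,0.51,2.32,0.00,0.28,0.03,0.10,-0.08,-0.01
45-10,0.17,0.55,1.10,0.31,1.17,0.32,1.79,0.09,0.85,2.65,0.33,0.00,0.01,0.09,-0.10,-0.03
46-11,0.07,0.45,1.20,0.21,1.07,0.22,1.89,0.01,0.95,2.75,0.43,0.10,0.00,-0.09,0.01,0.08
51-10,0.95,1.33,0.32,1.09,1.94,1.10,1.01,0.87,0.07,1.88,0.44,0.78,0.88,0.00,-0.19,0.29
52-11,0.38,0.77,0.88,0.53,1.38,0.53,1.57,0.31,0.63,2.44,0.12,0.22,0.32,0.56,0.00,-0.07
58-10,0.42,0.81,0.85,0.57,1.42,0.57,1.53,0.34,0.59,2.40,0.08,0.25,0.35,0.52,0.04,0.00
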
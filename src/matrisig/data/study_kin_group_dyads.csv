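# Within-kin-group dyads of the 16 study females: co-sleeping status,
# Queller-Goodnight relatedness with kinship-test significance tier
# (a: p<0.001, b: p<0.01, c: p<0.05) and allelic exclusion counts.
group,a,b,cosleep,relatedness,p_tier,allelic_exclusions
1,06-09,19-10,no,0.61,a,0
1,06-09,41-11,unknown,0.29,b,1
1,19-10,41-11,yes,0.44,a,0
2,51-10,58-10,yes,0.29,b,0
2,51-10,11-11,yes,0.34,c,2
2,58-10,11-11,yes,0.62,a,0
3,10-10,112-10,yes,0.41,a,0
4,45-10,101-10,yes,0.51,a,0
5,113-10,52-11,no,0.36,a,0
6,28-09,17-10,yes,0.52,a,0
6,28-09,36-11,unknown,0.23,b,3
6,28-09,46-11,unknown,0.17,b,2
6,17-10,36-11,yes,0.49,a,0
6,17-10,46-11,yes,0.44,a,0
6,36-11,46-11,yes,0.38,a,1
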
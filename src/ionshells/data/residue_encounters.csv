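residue,variant,binding_time_ps,primary_encounters,secondary_encounters
E4,WT,4681,5,0
E4,E60D,3282,4,0
E5,WT,1,1,0
E5,E60D,0,0,0
E11,WT,3769,6,1
E11,E60D,1331,1,1
Y13,WT,0,0,0
Y13,E60D,1,0,1
A14,WT,0,0,0
A14,E60D,0,0,0
A15,WT,0,0,0
A15,E60D,1080,5,1
K16,WT,2966,4,2
K16,E60D,3296,5,2
E17,WT,139336,51,10
E17,E60D,269478,57,8
G18,WT,1434,5,1
G18,E60D,2878,4,0
D19,WT,15339,10,7
D19,E60D,1520,8,2
A21,WT,4491,4,2
A21,E60D,45288,6,3
Q22,WT,67512,52,16
Q22,E60D,176169,37,18
L23,WT,55,19,1
L23,E60D,0,0,0
S24,WT,1463,3,8
S24,E60D,21335,15,11
E26,WT,18961,6,5
E26,E60D,18842,8,6
E27,WT,24807,4,5
E27,E60D,29762,6,5
K41,WT,657,0,3
K41,E60D,722,3,1
G42,WT,841,9,2
G42,E60D,1935,3,1
P43,WT,89505,16,11
P43,E60D,31363,8,2
S44,WT,3254,4,10
S44,E60D,1469,2,2
T45,WT,1874,0,2
T45,E60D,1,0,1
D47,WT,62462,37,11
D47,E60D,40492,25,4
E48,WT,176802,55,7
E48,E60D,92731,10,7
E51,WT,159179,62,14
E51,E60D,130802,42,8
E52,WT,12894,15,3
E52,E60D,3911,9,1
L53,WT,0,0,0
L53,E60D,2,0,1
D54,WT,96269,17,22
D54,E60D,94526,19,4
K55,WT,1427,7,3
K55,E60D,8392,16,2
A56,WT,36670,28,6
A56,E60D,85218,17,11
G57,WT,73675,28,11
G57,E60D,7737,11,2
D58,WT,191748,58,19
D58,E60D,385846,88,12
F59,WT,20194,9,10
F59,E60D,486,2,7
E60,WT,269285,71,35
E60,E60D,527753,165,27
S62,WT,1033,14,16
S62,E60D,3118,175,14
E64,WT,31634,26,11
E64,E60D,17635,28,2
E65,WT,157857,26,12
E65,E60D,21236,24,7
Q67,WT,0,0,0
Q67,E60D,1,0,1
K72,WT,0,0,0
K72,E60D,56253,15,2
I73,WT,22122,6,3
I73,E60D,7630,15,2
S74,WT,2531,16,2
S74,E60D,11640,33,6
Q75,WT,80,1,0
Q75,E60D,1238,2,1
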
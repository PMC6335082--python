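map_id,layer,n_cells,P,D,A,V,tendency
1II,II,6,1,3,0,2,Undetermined
4II,II,6,1,2,1,2,Undetermined
5II,II,6,0,1,1,4,Partly V
6II,II,6,0,2,1,3,Undetermined
7II,II,6,3,1,2,0,Undetermined
8II,II,6,0,1,2,3,Partly A-V
9II,II,6,1,0,1,4,Partly V
10II,II,6,0,0,2,4,A-V
1III,III,6,0,2,2,2,Undetermined
5III,III,6,1,2,2,1,Undetermined
6III,III,6,2,1,0,3,Undetermined
7III,III,6,0,1,2,3,Partly A-V
8III,III,6,0,0,5,1,A
13III,III,6,0,3,2,1,Partly D-A
14III,III,6,1,0,0,5,V
16III,III,6,1,1,2,2,Undetermined
17IV,IV,15,4,2,3,6,Undetermined
18IV,IV,17,5,3,5,4,Undetermined
19IV,IV,11,3,1,4,3,Undetermined
20IV,IV,5,2,1,2,0,Undetermined
1Va,Va,6,2,1,1,2,Undetermined
3Va,Va,6,0,2,3,1,Partly A-D
5Va,Va,6,0,1,1,4,Partly V
8Va,Va,6,1,2,3,0,Partly A-D
13Va,Va,6,2,1,2,1,Undetermined
14Va,Va,6,1,2,1,2,Undetermined
15Va,Va,5,0,3,2,0,A-D
16Va,Va,7,0,3,2,2,Undetermined
3Vb,Vb,6,0,0,0,6,V
4Vb,Vb,6,1,1,3,1,Undetermined
9Vb,Vb,6,3,2,0,1,Partly P-D
10Vb,Vb,6,2,2,1,1,Undetermined
12Vb,Vb,6,1,0,0,5,V
13Vb,Vb,6,1,0,2,3,Partly A-V
14Vb,Vb,6,0,3,1,2,Undetermined
15Vb,Vb,6,1,2,2,1,Undetermined
5VI,VI,6,2,0,1,3,Partly P-V
6VI,VI,6,2,3,1,0,Partly P-D
8VI,VI,6,2,3,0,1,Partly P-D
9VI,VI,6,2,1,1,2,Undetermined
10VI,VI,6,5,1,0,0,P
11VI,VI,6,2,0,1,3,Partly P-V
12VI,VI,6,2,0,1,3,Partly P-V
16VI,VI,6,1,1,1,3,Undetermined
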
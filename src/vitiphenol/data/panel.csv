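global_code,abbreviation,family,family_index,aglycone,b_ring_oh,methylated,acylated,conjugate,tannin_unit,galloylated,loq
1,AN-Pg-glc,AN,1,Pg,1,0,0,glc,,0,0.0134
2,AN-Cy-glc,AN,2,Cy,2,0,0,glc,,0,1.14
3,AN-Dp-glc,AN,3,Dp,3,0,0,glc,,0,0.516
4,AN-Pt-glc,AN,4,Pt,3,1,0,glc,,0,0.547
5,AN-Pn-glc,AN,5,Pn,2,1,0,glc,,0,1.18
6,AN-Mv-glc,AN,6,Mv,3,1,0,glc,,0,3.89
7,AN-Cy-diglc,AN,7,Cy,2,0,0,diglc,,0,0.0048
8,AN-Dp-diglc,AN,8,Dp,3,0,0,diglc,,0,0.0056
9,AN-Pt-diglc,AN,9,Pt,3,1,0,diglc,,0,0.0006
10,AN-Pn-diglc,AN,10,Pn,2,1,0,diglc,,0,0.0012
11,AN-Mv-diglc,AN,11,Mv,3,1,0,diglc,,0,0.0022
12,AN-Pg-acglc,AN,12,Pg,1,0,1,acglc,,0,0.0012
13,AN-Cy-acglc,AN,13,Cy,2,0,1,acglc,,0,0.055
14,AN-Dp-acglc,AN,14,Dp,3,0,1,acglc,,0,0.154
15,AN-Pt-acglc,AN,15,Pt,3,1,1,acglc,,0,0.157
16,AN-Pn-acglc,AN,16,Pn,2,1,1,acglc,,0,0.207
17,AN-Mv-acglc,AN,17,Mv,3,1,1,acglc,,0,1.28
18,AN-Pg-coumglc,AN,18,Pg,1,0,1,coumglc,,0,0.0054
19,AN-Cy-coumglc,AN,19,Cy,2,0,1,coumglc,,0,0.226
20,AN-Dp-coumglc,AN,20,Dp,3,0,1,coumglc,,0,0.626
21,AN-Pt-coumglc,AN,21,Pt,3,1,1,coumglc,,0,0.54
22,AN-Pn-coumglc,AN,22,Pn,2,1,1,coumglc,,0,0.716
23,AN-Mv-coumglc,AN,23,Mv,3,1,1,coumglc,,0,3.72
24,AN-Cy-caffglc,AN,24,Cy,2,0,1,caffglc,,0,0.0018
25,AN-Dp-caffglc,AN,25,Dp,3,0,1,caffglc,,0,0.0014
26,AN-Pt-caffglc,AN,26,Pt,3,1,1,caffglc,,0,0.0022
27,AN-Pn-caffglc,AN,27,Pn,2,1,1,caffglc,,0,0.0078
28,AN-Mv-caffglc,AN,28,Mv,3,1,1,caffglc,,0,0.0198
29,AN-Mv-glc-Pn-glc,AN,29,,0,0,0,other,,0,0.0016
30,AN-Mv-glc-dimer,AN,30,,0,0,0,other,,0,0.0016
31,AP-py-Pn-glc,AP,1,Pn,2,1,0,glc,,0,0.061
32,AP-py-Mv-glc,AP,2,Mv,3,1,0,glc,,0,0.261
33,AP-hp-py-Pn-glc,AP,3,Pn,2,1,0,glc,,0,0.0006
34,AP-hp-py-Mv-glc,AP,4,Mv,3,1,0,glc,,0,0.0008
35,AP-ctc-py-Pn-glc,AP,5,Pn,2,1,0,glc,,0,0.0008
36,AP-ctc-py-Mv-glc,AP,6,Mv,3,1,0,glc,,0,0.0008
37,AP-cbx-py-Pn-glc,AP,7,Pn,2,1,0,glc,,0,0.0008
38,AP-cbx-py-Mv-glc,AP,8,Mv,3,1,0,glc,,0,0.0064
39,AF-Pt-glc-(epi)cat,AF,1,,0,0,0,other,,0,0.0014
40,AF-Pn-glc-(epi)cat,AF,2,,0,0,0,other,,0,0.0032
41,AF-Mv-glc-(epi)gallocat,AF,3,,0,0,0,other,,0,0.0016
42,AF-Mv-glc-(epi)cat,AF,4,,0,0,0,other,,0,0.00174
43,AF-(epi)gallocat-Pn-glc,AF,5,,0,0,0,other,,0,0.003
44,AF-(epi)gallocat-Mv-glc,AF,6,,0,0,0,other,,0,0.0054
45,AF-(epi)cat-Pn-glc,AF,7,,0,0,0,other,,0,0.0022
46,AF-(epi)cat-Mv-glc,AF,8,,0,0,0,other,,0,0.0038
47,AF-(epi)cat-eth-Pn-glc-i1,AF,9,,0,0,0,other,,0,0.00078
48,AF-(epi)cat-eth-Pn-glc-i2,AF,10,,0,0,0,other,,0,0.00104
49,AF-(epi)cat-eth-Pn-glc-i3,AF,11,,0,0,0,other,,0,0.00154
50,AF-(epi)cat-eth-Pn-glc-i4,AF,12,,0,0,0,other,,0,0.00096
51,AF-(epi)cat-eth-Mv-glc-i1,AF,13,,0,0,0,other,,0,0.00108
52,AF-(epi)cat-eth-Mv-glc-i2,AF,14,,0,0,0,other,,0,0.0014
53,AF-(epi)cat-eth-Mv-glc-i3+4,AF,15,,0,0,0,other,,0,0.0036
54,AC-caft-Pn-glc,AC,1,Pn,2,1,0,other,,0,0.0007
55,AC-caft-Mv-glc,AC,2,Mv,3,1,0,other,,0,0.00074
56,HF-taxif,HF,1,taxif,2,0,0,aglycone,,0,0.0136
57,HF-astilb,HF,2,astilb,2,0,0,other,,0,0.051
58,FO-syring-glucur,FO,1,syring,3,1,0,glucur,,0,0.0008
59,FO-syring-glc,FO,2,syring,3,1,0,glc,,0,0.179
60,FO-querc-glucur,FO,3,querc,2,0,0,glucur,,0,1.59
61,FO-querc-glc,FO,4,querc,2,0,0,glc,,0,4.92
62,FO-myric-glucur,FO,5,myric,3,0,0,glucur,,0,0.0066
63,FO-myric-glc,FO,6,myric,3,0,0,glc,,0,0.274
64,FO-laric-glucur,FO,7,laric,3,1,0,glucur,,0,0.00122
65,FO-laric-glc,FO,8,laric,3,1,0,glc,,0,0.195
66,FO-kaempf-glucur,FO,9,kaempf,1,0,0,glucur,,0,0.0036
67,FO-kaempf-glc,FO,10,kaempf,1,0,0,glc,,0,3.66
68,FO-isorham-glucur,FO,11,isorham,2,1,0,glucur,,0,0.0024
69,FO-isorham-glc,FO,12,isorham,2,1,0,glc,,0,0.425
70,ST-c-resver,ST,1,resver,0,0,0,aglycone,,0,0.004
71,ST-t-resver,ST,2,resver,0,0,0,aglycone,,0,0.114
72,ST-c-piceid,ST,3,resver,0,0,0,glc,,0,0.493
73,ST-t-piceid,ST,4,resver,0,0,0,glc,,0,0.125
74,ST-piceat-glc,ST,5,piceat,0,0,0,glc,,0,0.014
75,ST-piceat,ST,6,piceat,0,0,0,aglycone,,0,0.005
76,ST-resver-dimer,ST,7,resver,0,0,0,other,,0,0.0198
77,FA-gallocat,FA,1,gallocat,3,0,0,aglycone,,0,0.0626
78,FA-epigallocat,FA,2,epigallocat,3,0,0,aglycone,,0,0.0202
79,FA-epicat,FA,3,epicat,2,0,0,aglycone,,0,0.0598
80,FA-cat,FA,4,cat,2,0,0,aglycone,,0,0.231
81,FA-(epi)cat-eth-(epi)cat-i1,FA,5,,2,0,0,aglycone,,0,0.00082
82,FA-(epi)cat-eth-(epi)cat-i2+3,FA,6,,2,0,0,aglycone,,0,0.0028
83,FA-gallocat-term,FA,7,gallocat,3,0,0,aglycone,terminal,0,0.565
84,FA-epigallocat-term,FA,8,epigallocat,3,0,0,aglycone,terminal,0,0.105
85,FA-epicat-term,FA,9,epicat,2,0,0,aglycone,terminal,0,0.167
86,FA-epicat-gall-term,FA,10,epicat-gall,2,0,0,aglycone,terminal,1,0.075
87,FA-cat-term,FA,11,cat,2,0,0,aglycone,terminal,0,1.74
88,FA-(epi)gallocat-phlo,FA,12,epigallocat,3,0,0,aglycone,extension,0,17.5
89,FA-epicat-phlo,FA,13,epicat,2,0,0,aglycone,extension,0,32.1
90,FA-epicat-gall-phlo,FA,14,epicat-gall,2,0,0,aglycone,extension,1,1.93
91,FA-cat-phlo,FA,15,cat,2,0,0,aglycone,extension,0,0.157
92,HB-glucogall,HB,1,,0,0,0,glc,,0,0.0136
93,HB-vanill-ac,HB,2,,0,0,0,aglycone,,0,0.002
94,HB-syring-ac,HB,3,,0,0,0,aglycone,,0,0.0066
95,HB-protocat-ac,HB,4,,0,0,0,aglycone,,0,0.003
96,HB-gall-ac,HB,5,,0,0,0,aglycone,,0,0.0054
97,HC-ct-coutar-ac,HC,1,,0,0,0,other,,0,1.61
98,HC-ct-caftar-ac,HC,2,,0,0,0,other,,0,2.44
99,HC-t-fertar-ac,HC,3,,0,0,0,other,,0,0.0912
100,HC-t-caffeic-ac,HC,4,,0,0,0,other,,0,0.0008
101,HC-t-coumar-ac,HC,5,,0,0,0,other,,0,0.00132
102,HC-t-ferul-ac,HC,6,,0,0,0,other,,0,0.0008
103,OT-OH-tyrosol,OT,1,,0,0,0,other,,0,0.00142
104,OT-GSSG,OT,2,,0,0,0,other,,0,0.0348
105,OT-GSH,OT,3,,0,0,0,other,,0,0.0964
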
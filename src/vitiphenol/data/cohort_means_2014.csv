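abbreviation,ni_ug_per_berry,ir_ug_per_berry
AN-Pg-glc,0.67,0.59
AN-Cy-glc,56.79,53.36
AN-Dp-glc,25.78,22.2
AN-Pt-glc,27.33,24.6
AN-Pn-glc,58.77,57.99
AN-Mv-glc,194.41,179.54
AN-Cy-diglc,0.24,0.23
AN-Dp-diglc,0.28,0.22
AN-Pt-diglc,0.03,0.04
AN-Pn-diglc,0.06,0.06
AN-Mv-diglc,0.11,0.1
AN-Pg-acglc,0.06,0.06
AN-Cy-acglc,2.75,3.0
AN-Dp-acglc,7.69,7.84
AN-Pt-acglc,7.85,8.23
AN-Pn-acglc,10.33,10.34
AN-Mv-acglc,63.98,69.97
AN-Pg-coumglc,0.27,0.27
AN-Cy-coumglc,11.31,11.77
AN-Dp-coumglc,31.29,29.68
AN-Pt-coumglc,26.99,26.4
AN-Pn-coumglc,35.8,36.63
AN-Mv-coumglc,185.94,191.62
AN-Cy-caffglc,0.09,0.11
AN-Dp-caffglc,0.07,0.09
AN-Pt-caffglc,0.11,0.12
AN-Pn-caffglc,0.39,0.42
AN-Mv-caffglc,0.99,1.18
AN-Mv-glc-Pn-glc,0.08,0.09
AN-Mv-glc-dimer,0.08,0.08
AP-py-Pn-glc,3.05,2.3
AP-py-Mv-glc,13.05,9.0
AP-hp-py-Pn-glc,0.03,0.04
AP-hp-py-Mv-glc,0.04,0.044
AP-ctc-py-Pn-glc,0.04,0.04
AP-ctc-py-Mv-glc,0.04,0.04
AP-cbx-py-Pn-glc,0.04,0.04
AP-cbx-py-Mv-glc,0.32,0.34
AF-Pt-glc-(epi)cat,0.07,0.08
AF-Pn-glc-(epi)cat,0.16,0.17
AF-Mv-glc-(epi)gallocat,0.08,0.08
AF-Mv-glc-(epi)cat,0.087,0.096
AF-(epi)gallocat-Pn-glc,0.15,0.13
AF-(epi)gallocat-Mv-glc,0.27,0.24
AF-(epi)cat-Pn-glc,0.11,0.11
AF-(epi)cat-Mv-glc,0.19,0.16
AF-(epi)cat-eth-Pn-glc-i1,0.039,0.045
AF-(epi)cat-eth-Pn-glc-i2,0.052,0.086
AF-(epi)cat-eth-Pn-glc-i3,0.077,0.25
AF-(epi)cat-eth-Pn-glc-i4,0.048,0.07
AF-(epi)cat-eth-Mv-glc-i1,0.054,0.081
AF-(epi)cat-eth-Mv-glc-i2,0.07,0.13
AF-(epi)cat-eth-Mv-glc-i3+4,0.18,0.49
AC-caft-Pn-glc,0.035,0.041
AC-caft-Mv-glc,0.037,0.043
HF-taxif,0.68,0.82
HF-astilb,2.55,3.72
FO-syring-glucur,0.04,0.043
FO-syring-glc,8.97,9.68
FO-querc-glucur,79.49,80.57
FO-querc-glc,245.77,242.26
FO-myric-glucur,0.33,0.28
FO-myric-glc,13.72,12.96
FO-laric-glucur,0.061,0.056
FO-laric-glc,9.73,10.15
FO-kaempf-glucur,0.18,0.17
FO-kaempf-glc,182.92,197.16
FO-isorham-glucur,0.12,0.11
FO-isorham-glc,21.24,21.14
ST-c-resver,0.2,0.21
ST-t-resver,5.69,6.13
ST-c-piceid,24.63,24.56
ST-t-piceid,6.26,7.02
ST-piceat-glc,0.7,0.91
ST-piceat,0.25,0.33
ST-resver-dimer,0.99,1.18
FA-gallocat,3.13,3.8
FA-epigallocat,1.01,1.22
FA-epicat,2.99,4.52
FA-cat,11.57,16.72
FA-(epi)cat-eth-(epi)cat-i1,0.041,0.049
FA-(epi)cat-eth-(epi)cat-i2+3,0.14,0.16
FA-gallocat-term,28.23,30.43
FA-epigallocat-term,5.26,5.4
FA-epicat-term,8.35,10.48
FA-epicat-gall-term,3.75,3.87
FA-cat-term,87.11,116.11
FA-(epi)gallocat-phlo,874.66,894.32
FA-epicat-phlo,1604.34,1897.39
FA-epicat-gall-phlo,96.59,105.63
FA-cat-phlo,7.84,9.23
HB-glucogall,0.68,0.68
HB-vanill-ac,0.1,0.11
HB-syring-ac,0.33,0.32
HB-protocat-ac,0.15,0.15
HB-gall-ac,0.27,0.26
HC-ct-coutar-ac,80.54,90.26
HC-ct-caftar-ac,122.0,140.83
HC-t-fertar-ac,4.56,4.38
HC-t-caffeic-ac,0.04,0.05
HC-t-coumar-ac,0.066,0.067
HC-t-ferul-ac,0.04,0.044
OT-OH-tyrosol,0.071,0.074
OT-GSSG,1.74,2.13
OT-GSH,4.82,5.24
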
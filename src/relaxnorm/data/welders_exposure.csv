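subject_id,age,group,cei_3m,cei_life,air_mn
W01,48,welder,0.12,1.49,0.16
W02,50,welder,0.05,2.44,0.12
W03,34,welder,0.05,0.36,0.12
W04,56,welder,0.05,4.8,0.48
W05,29,welder,0.06,0.93,0.48
W06,37,welder,0.04,0.56,0.08
W07,37,welder,0.01,0.68,0.08
W08,46,welder,0.02,1.37,0.15
W09,31,welder,0.02,0.51,0.20
W10,29,welder,0.03,0.31,0.07
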
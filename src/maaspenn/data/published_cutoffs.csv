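pct_threshold,score_cutoff,auc,ci95_lower,ci95_upper,specificity,sensitivity,false_alarm
10,0.75,0.86,0.855,0.867,0.81,0.74,0.19
20,0.77,0.85,0.842,0.851,0.76,0.77,0.24
25,0.80,0.85,0.843,0.852,0.80,0.74,0.20
30,0.83,0.86,0.851,0.860,0.84,0.73,0.16
40,0.85,0.87,0.868,0.878,0.81,0.80,0.19
50,0.88,0.90,0.892,0.904,0.83,0.85,0.17
60,0.88,0.92,0.910,0.925,0.79,0.92,0.21
70,0.94,0.96,0.952,0.966,0.94,0.89,0.06
75,0.95,0.97,0.967,0.977,0.95,0.93,0.05
80,0.96,0.98,0.971,0.983,0.95,0.95,0.05
90,0.98,0.99,0.982,0.996,0.97,0.97,0.03
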
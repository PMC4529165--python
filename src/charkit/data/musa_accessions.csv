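section,name,itc_code,two_c_pg,sd_pg,monoploid_mbp,letters,two_n,n_45s,n_5s
Musa,Musa rubinea,1518,1.310,0.016,641,E,22,2,4
Musa,Musa x fennicae,1522,1.261,0.012,617,BC,22,2,6
Musa,Musa itinerans var. xishuangbannaensis,1526,1.311,0.017,641,E,22,2,4
Musa,Musa siamensis,1534,1.280,0.006,626,BC,22,2,6
Musa,Musa itinerans var. itinerans,1571,1.217,0.004,595,A,22,2,4
Musa,Musa yunnanensis,1573,1.259,0.011,616,B,22,2,6
Musa,Musa mannii,1574,1.282,0.008,627,C,22,2,3
Musa,Musa laterita,1575,1.315,0.006,643,E,22,2,6
Musa,Musa rubra,1590,1.306,0.010,639,DE,22,2,6
Musa,Musa rosea x siamensis,1592,1.279,0.006,625,C,22,2,7
Musa,Musa rosea (hybrid),1598,1.285,0.002,628,CD,22,2,4
Callimusa,Musa violascens,1514,1.428,0.011,698,GH,20,2,4
Callimusa,Musa lutea,1515,1.432,0.009,700,GH,20,2,2
Callimusa,Musa beccarii var. beccarii,1516,1.537,0.017,752,J,18,6,4
Callimusa,Musa campestris var. sarawakensis,1517,1.417,0.008,693,G,20,2,2
Callimusa,Musa monticola,1528,1.390,0.016,680,F,20,2,4
Callimusa,Musa beccarii var. hottana,1529,1.673,0.020,818,K,18,6,4
Callimusa,Musa borneensis,1531,1.772,0.006,867,L,20,5,8
Callimusa,Musa exotica,1532,1.442,0.006,705,H,,,
Callimusa,Musa campestris var. limbangensis,1535,1.454,0.003,711,H,,,
Callimusa,Musa barioensis,1568,1.480,0.014,724,I,20,2,3
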
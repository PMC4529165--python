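accession,its_type,gc_its1,gc_58s,gc_its2,motif_m1,motif_m2,motif_m3,its2_structure,r58s_structure,note
Musa rubinea,1518_type1,57.67,53.55,63.76,conserved,conserved,conserved,four-helices,conserved,
Musa rubinea,1518_type2,58.14,52.26,63.76,conserved,conserved,conserved,four-helices,conserved,
Musa rubinea,1518_type3,62.96,57.42,69.55,conserved,conserved,conserved,four-helices,conserved,
Musa x fennicae,1522_type1,62.50,57.42,69.63,conserved,conserved,conserved,four-helices,conserved,
Musa x fennicae,1522_type2,62.50,57.42,69.63,conserved,conserved,conserved,four-helices,conserved,
Musa x fennicae,1522_type3,61.57,57.42,69.16,conserved,conserved,conserved,four-helices,conserved,
Musa x fennicae,1522_type4,61.11,57.42,69.16,conserved,conserved,conserved,four-helices,conserved,
Musa x fennicae,1522_type5,62.50,57.42,69.16,conserved,conserved,conserved,four-helices,conserved,
Musa itinerans var. xishuangbannaensis,1526,57.67,53.55,63.76,conserved,conserved,conserved,four-helices,conserved,
Musa siamensis,1534_type1,58.80,52.26,62.74,nt-12 'A',nt-9 'T',conserved,four-helices,conserved,pseudogene
Musa siamensis,1534_type2,57.41,46.45,62.15,nt-2 'A'; nt-9 'T'; nt-14 'T',nt-6 'A'; nt-9 'T',nt-8 'A',not formed,conserved,
Musa itinerans var. itinerans,1571,57.67,53.55,63.76,conserved,conserved,conserved,four-helices,conserved,
Musa yunnanensis,1573_type1,63.59,57.42,68.84,conserved,conserved,conserved,four-helices,conserved,
Musa yunnanensis,1573_type2,60.47,53.59,60.57,nt-2 'A',conserved,conserved,not formed,not formed,pseudogene
Musa yunnanensis,1573_type3,60.93,54.90,62.91,nt-2 'A',conserved,conserved,four-helices,not formed,pseudogene
Musa yunnanensis,1573_type4,57.41,48.94,64.02,nt-16 'T',nt-9 'A',nt-8 'A'; nt-9 'T',not formed,not formed,pseudogene
Musa mannii,1574_type1,57.62,50.97,64.49,conserved,conserved,conserved,four-helices,conserved,
Musa mannii,1574_type2,58.72,53.55,68.22,conserved,conserved,conserved,four-helices,conserved,
Musa mannii,1574_type3,63.30,57.42,69.19,conserved,conserved,conserved,four-helices,conserved,
Musa mannii,1574_type4,57.80,52.26,63.55,conserved,nt-14 'T',nt-8 'A',not formed,conserved,pseudogene
Musa laterita,1575_type1,58.33,55.48,62.74,conserved,nt-9 'A',conserved,four-helices,conserved,
Musa laterita,1575_type2,58.33,55.48,63.21,conserved,nt-9 'A',conserved,four-helices,conserved,
Musa rubra,1590_type1,58.33,55.48,62.74,conserved,nt-9 'A',conserved,four-helices,conserved,
Musa rubra,1590_type2,58.33,55.48,63.21,conserved,nt-9 'A',conserved,four-helices,conserved,
Musa rubra,1590_type3,59.26,59.63,65.26,nt-11 'T',not present-deletion,not present-deletion,not formed,not formed,pseudogene
Musa rosea x siamensis,1592_type1,61.29,57.42,68.69,conserved,conserved,conserved,four-helices,conserved,
Musa rosea x siamensis,1592_type2,60.65,54.48,66.05,conserved,conserved,conserved,not formed,conserved,pseudogene
Musa rosea x siamensis,1592_type3,58.80,55.86,63.51,conserved,nt1-nt3 'deletion'; nt-9 'A',conserved,four-helices,not formed,pseudogene
Musa rosea (hybrid),1598,63.59,57.42,68.37,conserved,conserved,conserved,four-helices,conserved,
Musa violascens,1514,65.02,58.06,66.83,conserved,conserved,conserved,four-helices,conserved,
Musa lutea,1515,59.28,54.19,63.26,nt-11 'T'; nt-12 'A',conserved,nt-6 'T',four-helices,conserved,
Musa beccarii var. beccarii,1516_type1,65.77,58.06,65.85,conserved,conserved,conserved,four-helices,conserved,
Musa beccarii var. beccarii,1516_type2,64.86,58.06,65.37,conserved,conserved,conserved,four-helices,conserved,
Musa beccarii var. beccarii,1516_type3,65.32,58.06,65.20,conserved,conserved,conserved,four-helices,conserved,
Musa campestris var. sarawakensis,1517,59.64,48.95,61.46,nt-11 'T'; nt-12 'A',nt-7 'T',conserved,four-helices,conserved,
Musa monticola,1528,65.92,58.71,68.29,conserved,conserved,nt-3 'C',four-helices,conserved,
Musa beccarii var. hottana,1529,65.32,58.06,65.37,conserved,conserved,conserved,four-helices,conserved,
Musa borneensis,1531_type1,65.02,57.42,65.37,conserved,conserved,conserved,four-helices,conserved,
Musa borneensis,1531_type2,65.47,56.13,66.83,conserved,conserved,conserved,four-helices,conserved,
Musa borneensis,1531_type3,65.92,56.77,68.29,conserved,conserved,conserved,four-helices,conserved,
Musa borneensis,1531_type4,65.02,57.42,66.34,conserved,conserved,conserved,not formed,conserved,pseudogene
Musa exotica,1532_type1,63.68,58.06,66.83,conserved,conserved,conserved,four-helices,conserved,
Musa exotica,1532_type2,63.68,58.06,66.34,conserved,conserved,conserved,four-helices,conserved,
Musa exotica,1532_type3,65.02,58.06,66.83,conserved,conserved,conserved,four-helices,conserved,
Musa campestris var. limbangensis,1535_type1,64.13,58.06,65.85,conserved,conserved,conserved,four-helices,conserved,
Musa campestris var. limbangensis,1535_type2,64.57,58.06,66.83,conserved,conserved,conserved,four-helices,conserved,
Musa campestris var. limbangensis,1535_type3,56.50,50.32,59.51,nt-12 'A'; nt-16 'A',conserved,conserved,not formed,conserved,pseudogene
Musa barioensis,1568_type1,61.88,56.13,62.80,nt-10 'G'; nt-11 'A',nt-9 'A',nt-9 'T',four-helices,conserved,
Musa barioensis,1568_type2,63.77,56.13,62.80,nt-10 'G'; nt-11 'A',nt-9 'A',nt-9 'T',four-helices,conserved,
Musa barioensis,1568_type3,65.92,58.06,68.29,conserved,conserved,conserved,four-helices,conserved,
Musa barioensis,1568_type4,60.99,54.19,63.77,conserved,conserved,conserved,not formed,conserved,pseudogene
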
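item,unit,base,low,high
enzalutamide,per 40 mg tablet,48.61,38.888,58.332
bicalutamide,per 50 mg tablet,6.04,4.832,7.248
flutamide,per 125 mg tablet,1.28,1.024,1.536
nilutamide,per 150 mg tablet,,,
docetaxel,per 20 mg vial,169.1,135.28,202.92
goserelin,per 3.6 mg depot,321.43,257.144,385.716
leuprolide,per 3.75 mg depot,195.83,156.664,234.996
triptorelin,per 3.75 mg depot,311.68,249.344,374.016
histrelin,per 50 mg implant,,,
degarelix,per 80 mg depot,435.22,348.176,522.264
orchiectomy,per procedure,83.11,66.488,99.732
laboratory_tests,per panel,30.68,24.544,36.816
psa_test,per test,6.95,5.56,8.34
ct,per scan,211.56,169.248,253.872
bone_scan,per scan,141.34,113.072,169.608
febrile_neutropenia,per event,953,762.4,1143.6
hypertension,per event,12.15,9.72,14.58
neutrophil_count_decreased,per event,466,372.8,559.2
fatigue,per event,108.73,86.984,130.476
bsc_per_cycle,per cycle,117.1,93.68,140.52
follow_up,per visit,51.5,41.2,61.8
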
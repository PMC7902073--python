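item,unit,base,low,high
enzalutamide,per 40 mg capsule,115.486,92.389,138.583
bicalutamide,per 50 mg tablet,19.826,15.861,23.791
flutamide,per 125 mg tablet,2.939,2.351,3.527
nilutamide,per 150 mg tablet,261.909,209.527,314.291
docetaxel,per 20 mg vial,187.576,150.061,225.091
goserelin,per 3.6 mg depot,740.52,592.416,888.624
leuprolide,per 3.75 mg depot,1560.44,1248.352,1872.528
triptorelin,per 3.75 mg depot,975.89,780.712,1171.068
histrelin,per 50 mg implant,23908.415,19126.732,28690.098
degarelix,per 80 mg depot,586.14,468.912,703.368
orchiectomy,per procedure,13194,10555.2,15832.8
laboratory_tests,per panel,76,60.8,91.2
psa_test,per test,25,20,30
ct,per scan,828,662.4,993.6
bone_scan,per scan,253.46,202.768,304.152
febrile_neutropenia,per event,18507,14805.6,22208.4
hypertension,per event,201.9,161.52,242.28
neutrophil_count_decreased,per event,5937,4749.6,7124.4
fatigue,per event,139,111.2,166.8
bsc_per_cycle,per cycle,1213,970.4,1455.6
follow_up,per visit,422,337.6,506.4
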
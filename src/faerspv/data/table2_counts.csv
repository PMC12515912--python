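endpoint,drug,a,b,c,d
qt_tdp,citalopram,381,2290,49824,694012
qt_tdp,escitalopram,299,2372,50299,693537
qt_tdp,sertraline,272,2399,81996,661840
qt_tdp,venlafaxine,250,2421,78129,665707
qt_tdp,fluoxetine,265,2406,50427,693409
qt_tdp,mirtazapine,136,2535,35629,708207
qt_tdp,duloxetine,60,2701,79205,664541
qt_tdp,quetiapine,120,2551,22643,721193
af,citalopram,80,609,50125,695693
af,escitalopram,61,628,50537,695281
af,sertraline,97,592,82171,663647
af,venlafaxine,67,622,78312,667506
af,fluoxetine,75,614,50617,695201
af,mirtazapine,25,664,35740,710078
af,duloxetine,78,611,79187,666631
af,quetiapine,8,681,22755,723063
heart_block,citalopram,59,596,50146,695706
heart_block,escitalopram,48,607,50550,695302
heart_block,sertraline,85,570,82183,663669
heart_block,venlafaxine,52,603,78327,667525
heart_block,fluoxetine,43,612,50649,695203
heart_block,mirtazapine,43,612,35722,710130
heart_block,duloxetine,20,635,79245,666607
heart_block,quetiapine,28,627,22735,723117
ventricular_arrhythmia,citalopram,62,554,50150,695741
ventricular_arrhythmia,escitalopram,61,555,50537,695354
ventricular_arrhythmia,sertraline,65,551,82203,663688
ventricular_arrhythmia,venlafaxine,71,545,78308,667583
ventricular_arrhythmia,fluoxetine,42,574,50650,695241
ventricular_arrhythmia,mirtazapine,25,591,35740,710151
ventricular_arrhythmia,duloxetine,18,598,79247,666644
ventricular_arrhythmia,quetiapine,43,573,22720,723171
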
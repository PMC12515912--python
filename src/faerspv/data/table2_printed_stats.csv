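endpoint,drug,prr,prr_low,prr_high,prr_bold,chi2,ror,ror_low,ror_high,ror_bold,ic,ic025,ic975,ic_bold
qt_tdp,citalopram,2.31,2.07,2.57,1,241.669,2.32,2.08,2.58,1,1.08,0.91,1.21,1
qt_tdp,escitalopram,1.73,1.54,1.95,0,82.044,1.74,1.54,1.96,1,0.72,0.53,0.86,1
qt_tdp,sertraline,0.92,0.81,1.04,0,1.830,0.92,0.81,1.04,0,-0.11,-0.31,0.03,0
qt_tdp,venlafaxine,0.88,0.77,1.00,0,1.418,0.88,0.77,1.00,0,-0.17,-0.37,-0.01,0
qt_tdp,fluoxetine,1.51,1.33,1.72,0,41.018,1.51,1.33,1.72,1,0.55,0.34,0.69,1
qt_tdp,mirtazapine,1.07,0.90,1.27,0,0.467,1.07,0.90,1.27,0,0.09,-0.20,0.29,0
qt_tdp,duloxetine,0.17,0.14,0.24,0,207.354,0.19,0.14,0.24,0,-2.28,-2.71,-1.97,0
qt_tdp,quetiapine,1.50,1.25,1.80,0,18.405,1.50,1.25,1.80,1,0.56,0.25,0.77,1
af,citalopram,1.82,1.44,2.30,0,25.468,1.82,1.44,2.30,1,0.78,0.41,1.05,1
af,escitalopram,1.34,1.03,1.74,0,4.378,1.34,1.03,1.74,1,0.38,-0.04,0.69,0
af,sertraline,1.32,1.07,1.64,0,6.268,1.32,1.07,1.64,1,0.35,0.01,0.59,1
af,venlafaxine,0.92,0.71,1.81,0,0.362,0.92,0.71,1.18,0,-0.11,-0.52,0.18,0
af,fluoxetine,1.68,1.32,2.13,0,17.627,1.68,1.32,2.13,1,0.68,0.29,0.95,1
af,mirtazapine,0.75,0.50,1.12,0,1.796,0.75,0.50,1.12,0,-0.39,-1.06,0.08,0
af,duloxetine,1.08,0.85,1.36,0,0.288,1.08,0.85,1.36,0,0.09,-0.28,0.36,0
af,quetiapine,0.37,0.19,0.75,0,7.69,0.37,0.19,0.75,0,-1.34,-2.55,-0.54,0
heart_block,citalopram,1.37,1.05,1.79,0,5.086,1.37,1.05,1.80,1,0.42,-0.01,0.73,0
heart_block,escitalopram,1.09,0.81,1.46,0,0.233,1.09,0.81,1.46,0,0.11,-0.37,0.45,0
heart_block,sertraline,1.20,0.96,1.51,0,2.364,1.20,0.96,1.51,0,0.23,-0.13,0.49,0
heart_block,venlafaxine,0.74,0.55,0.98,0,4.305,0.73,0.55,0.98,0,-0.40,-0.86,-0.07,0
heart_block,fluoxetine,0.96,0.71,1.31,0,0.023,0.96,0.71,1.31,0,-0.05,-0.56,0.31,0
heart_block,mirtazapine,1.40,1.03,1.90,0,4.142,1.40,1.03,1.90,1,0.45,-0.06,0.81,0
heart_block,duloxetine,0.27,0.17,0.41,0,38.734,0.26,0.17,0.41,0,-1.77,-2.52,-1.25,0
heart_block,quetiapine,1.42,0.97,2.07,0,2.929,1.42,0.97,2.07,0,0.48,-0.15,0.92,0
ventricular_arrhythmia,citalopram,1.55,1.19,2.02,0,10.427,1.55,1.19,2.02,1,0.58,0.15,0.88,1
ventricular_arrhythmia,escitalopram,1.51,1.16,1.97,0,9.038,1.51,1.16,1.97,1,0.54,0.12,0.85,1
ventricular_arrhythmia,sertraline,0.95,0.74,1.23,0,13.787,0.95,0.74,1.23,0,-0.06,-0.47,0.23,0
ventricular_arrhythmia,venlafaxine,1.11,0.87,1.42,0,0.586,1.11,0.87,1.42,0,0.13,-0.26,0.42,0
ventricular_arrhythmia,fluoxetine,1.01,0.73,1.37,0,0.003,1.01,0.73,1.37,0,-0.01,-0.51,0.37,0
ventricular_arrhythmia,mirtazapine,0.84,0.56,1.25,0,0.573,0.84,0.56,1.25,0,-0.24,-0.90,0.24,0
ventricular_arrhythmia,duloxetine,0.25,0.16,0.41,0,37.668,0.25,0.16,0.40,0,-1.83,-2.63,-1.28,0
ventricular_arrhythmia,quetiapine,2.39,1.75,3.25,1,30.912,2.39,1.75,3.26,1,1.17,0.67,1.54,1
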
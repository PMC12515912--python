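# Verbatim-name -> generic mapping for the eight study antidepressants
# (SSRIs, SNRIs, mirtazapine, and quetiapine as the comparator SGA).
# Matching is exact after normalization (case-fold, trim, dosage/salt
# suffix stripping), so salt forms of the generic need no separate entry;
# brand names do. Extend per deployment.
citalopram: [celexa, cipramil]
escitalopram: [lexapro, cipralex]
sertraline: [zoloft, lustral]
venlafaxine: [effexor, effexor xr]
fluoxetine: [prozac, sarafem]
mirtazapine: [remeron, zispin]
duloxetine: [cymbalta, yentreve]
quetiapine: [seroquel, seroquel xr]
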
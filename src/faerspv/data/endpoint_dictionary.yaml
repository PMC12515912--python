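# Preferred-term groups for the four arrhythmia endpoints.
#
# These are EDITABLE PLACEHOLDER lists in the spirit of the narrow-scope
# standardised MedDRA queries for each condition. The licensed SMQ term
# lists cannot be redistributed; substitute them here (YAML: endpoint ->
# list of PTs) for production use. The four groups must stay pairwise
# disjoint because the endpoints are tabulated separately.
qt_tdp:
  - Electrocardiogram QT prolonged
  - Torsade de pointes
  - Long QT syndrome
  - Electrocardiogram QT interval abnormal
  - Long QT syndrome congenital
af:
  - Atrial fibrillation
  - Atrial flutter
heart_block:
  - Atrioventricular block
  - Atrioventricular block first degree
  - Atrioventricular block second degree
  - Atrioventricular block complete
  - Bundle branch block left
  - Bundle branch block right
  - Bifascicular block
  - Trifascicular block
ventricular_arrhythmia:
  - Ventricular arrhythmia
  - Ventricular tachycardia
  - Ventricular fibrillation
  - Ventricular flutter
  - Ventricular extrasystoles
  - Ventricular tachyarrhythmia
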
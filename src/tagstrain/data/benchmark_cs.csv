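slice_level,sector,mean,sd
basal,anteroseptal,-0.17,0.03
basal,inferoseptal,-0.17,0.03
basal,anterior,-0.20,0.03
basal,anterolateral,-0.21,0.03
basal,inferolateral,-0.21,0.03
basal,inferior,-0.16,0.03
midventricular,anteroseptal,-0.16,0.03
midventricular,inferoseptal,-0.16,0.03
midventricular,anterior,-0.23,0.04
midventricular,anterolateral,-0.22,0.03
midventricular,inferolateral,-0.22,0.03
midventricular,inferior,-0.16,0.05
apical,anteroseptal,-0.18,0.03
apical,inferoseptal,-0.18,0.03
apical,anterior,-0.24,0.06
apical,anterolateral,-0.24,0.04
apical,inferolateral,-0.24,0.04
apical,inferior,-0.23,0.04
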
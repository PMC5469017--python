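# group_a,group_b  (unordered mutual-exclusion pairs)
atrium,ventricle
atrium,mitral
atrium,tricuspid
volume,dimension
volume,velocity
volume,pressure
mitral,tricuspid
mitral,aortic
tricuspid,aortic
aortic,pulmonary
diastole,systole
extremum,mean
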
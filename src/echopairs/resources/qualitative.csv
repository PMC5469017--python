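# surface,grade_rank (ordering supports ranges such as "low to moderate")
normal,0
preserved,0
hyperdynamic,0
trace,1
trivial,1
borderline,1
low,2
reduced,2
depressed,2
mild,2
moderate,3
moderately severe,4
severe,5
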
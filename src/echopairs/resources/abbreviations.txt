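# One regular expression per line; matched case-insensitively at token
# boundaries.  Each match must normalize to a dictionary surface.
lvef
lv\s?ef
lved{1,2}
lvesd
lvidd?
lvid\s?d
lvids
lvid\s?s
lvd\s?ed
lvd\s?es
lvpwd?
ivsd?
lvh
pasp
rap
ava
mva
e\s?/\s?e'?(?:\s+prime)?(?:\s+ratio)?
e\s+to\s+e\s+prime(?:\s+ratio)?
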
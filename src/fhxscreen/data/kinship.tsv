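label	degree	sides	sex
self	0	maternal|paternal
mother	1	maternal	female
father	1	paternal	male
sister	1	maternal|paternal	female
brother	1	maternal|paternal	male
daughter	1	maternal|paternal	female
son	1	maternal|paternal	male
maternal_grandmother	2	maternal	female
maternal_grandfather	2	maternal	male
paternal_grandmother	2	paternal	female
paternal_grandfather	2	paternal	male
maternal_aunt	2	maternal	female
maternal_uncle	2	maternal	male
paternal_aunt	2	paternal	female
paternal_uncle	2	paternal	male
maternal_half_sister	2	maternal	female
maternal_half_brother	2	maternal	male
paternal_half_sister	2	paternal	female
paternal_half_brother	2	paternal	male
niece	2	maternal|paternal	female
nephew	2	maternal|paternal	male
granddaughter	2	maternal|paternal	female
grandson	2	maternal|paternal	male
maternal_cousin	3	maternal
paternal_cousin	3	paternal
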
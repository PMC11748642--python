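name	mass_delta	target_residues	terminal_only	synthesizable	artifact_prone
oxidation	15.994915	M	False	False	True
sulphone	31.989829	M	False	True	False
acetylation	42.010565	K	False	True	False
nterm-acetylation	42.010565		True	True	True
deamidation	0.984016	NQ	False	True	False
phosphorylation	79.966331	STY	False	True	False
cysteinylation	119.004099	C	False	True	False
glutathionylation	305.068156	C	False	True	False
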
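neuron	node
ASEL	ASEL
ASER	ASER
AWCL	AWCL
AWCR	AWCR
RMDDL	RMD_DV
RMDDR	RMD_DV
RMDVL	RMD_DV
RMDVR	RMD_DV
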
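gene	cdna_start	cdna_end	pseudogene
PMS2	1145	2589	PMS2CL
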
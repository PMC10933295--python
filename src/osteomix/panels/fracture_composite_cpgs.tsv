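modality	feature_id
methylation	cg15320980
methylation	cg18249968
methylation	cg15508935
methylation	cg23088318
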
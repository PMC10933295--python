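modality	feature_id
methylation	cg22026953
methylation	cg18008345
methylation	cg21813369
methylation	cg11070274
methylation	cg00329101
methylation	cg23088318
methylation	cg15508935
methylation	cg09656629
methylation	cg15320980
methylation	cg00431894
methylation	cg18243574
microbiota	Klebsiella
microbiota	Streptococcus
microbiota	Veillonella
metabolite	Threonic acid
metabolite	5Z-Dodecenoic acid
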
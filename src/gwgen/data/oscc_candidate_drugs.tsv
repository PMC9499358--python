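# Candidate drugs per OSCC biomarker: signed L1000 regulation ability,
# PRISM sensitivity score and LD50 toxicity (log-scaled mol/kg).
drug	biomarker	regulation	sensitivity	toxicity
capsaicin	HES1	0.1690	-0.1217	4.202
gabazine	HES1	0.3716	-0.6103	3.079
phenolphthalein	HES1	-0.6116	-0.4833	5.297
tetramisole	HES1	0.1036	0.1136	4.111
gefitinib	HES1	0.2750	-0.5144	5.068
carvedilol	TCF	-0.0787	-0.0906	5.014
fipronil	TCF	-0.1207	-0.0939	5.534
metformin	TCF	0.0770	-0.0789	2.039
diethylcarbamazine	TCF	0.0501	-0.0848	2.008
dyphylline	TCF	0.1372	0.0356	2.022
sirolimus	NF-kB	-0.0866	-0.2058	3.486
terfenadine	NF-kB	-0.7665	-0.7406	5.437
metformin	NF-kB	-0.2607	-0.0789	2.039
gallic-acid	NF-kB	-1.0620	0.6208	3.262
gefitinib	NF-kB	-0.3428	-0.5144	5.068
niridazole	SP1	-0.6456	-0.1400	2.746
chlorambucil	SP1	-0.0559	-0.1424	3.249
bepridil	SP1	0.7249	0.2789	5.083
gallic-acid	SP1	-0.5239	0.6208	3.262
disopyramide	SP1	-0.3694	-0.1440	3.316
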
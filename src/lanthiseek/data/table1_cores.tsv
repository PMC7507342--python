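sample	core_peptide	modification	anti_m_luteus	source	nisp_adjusted
RL1	ITVRSKSLCTPGCITGPLRTCYLCFPTHVNC	(7)	N	Bacillus velezensis	yes
RL2	ITWKSESLCTPGCVTGVLQTCFLQTITCNCKISK	(9)	N	Bacillus subtilis/Bacillus licheniformis	yes
RL3	VTSKSLCTPGCITGILMCLTQNSCVSCNSCIKC	(9)	N	Bacillus thermoamylovorans	no
RL4	ITSKSLCTPGCVTGILMTCPVQTATCGCQITGK	6,7 (9)	N	Blautia coccoides	no
RL5	ITSKSLCTPGCITGILMCLTQNSCVSCNSCIRC	(9)	N	Parageobacillus thermantarcticus/Anoxybacillus ayderensis	no
RL6	ITSVSLCTPGCKTGALMGCNMKTASCGCHVHVSK	6-8 (8)	Y	Leuconostoc gelidum	no
RL7	ITSVSLCTPGCVTGVLMCPGNTISCNGHCSIHITG	(9)	N	Streptococcus pneumoniae	no
RL8	VTSKSLCTPGCKTGILQTCAIKSATCGCSIHIGK	6-8 (9)	Y	Bacillus cereus	no
RL9	VTSKSLCTPGCITGVLMCLTQNSCVSCNSCIKC	(9)	N	Aneurinibacillus sp. XH2	no
RL10	ITVKITSYSLCTPGCKTGALMGCTMKTASCGCHVHISK	6-9 (10)	N	Lactobacillus salivarius	yes
RL11	ITWKSESLCTPGCITGVLQTCFLQTITCNCHISK	(9)	N	Bacillus nakamurai	yes
RL12	ITSYSLCTPGCITGVLMGCHIQSIGCNVHVHVSK	(7)	N	Streptococcus salivarius	no
RL13	ITSKSLCTPGCKTGALMTCPIKTATCGCHFGN	6,7 (8)	Y	Streptococcus equinus	no
RL14	ITSKSLCTPGCVTGVLMGCALKTITCNCSVGIGKK	5,6 (8)	Y	Enterococcus rotai/Enterococcus moraviensis	no
RL15	ITSKSLCTPGCVTGLLMGCAGSSATCNCSVHVG	(9)	N	Pseudobutyrivibrio sp. UC1225/sp. 49	no
RL16	ITSKSLCTPGCVTGVLMGCNNKTATCNCSVHVG	(8)	N	Pseudobutyrivibrio sp. UC1225/sp. 49	no
RL17	ITQFKSISLCTPGCPTGILMGCHKCPSGSDTVYTK	(9)	N	Pseudobutyrivibrio sp. UC1225/sp. 49	yes
RL18	ITSPQITSVSLCTPGCQTGFLACFSQACNPTGGCKISK	(10)	N	Thermostaphylospora chromogena	no
bagelicin	VTSISLCTPGCKTGILMTCAIKTATCGCHF	6-8 (8)	Y	Streptococcus suis R61	no
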
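# Ammonia-oxidation pathway 2 (NO as redox shuttle to AMO): AMO receives its
# two electrons from NO rather than quinol, hydroxylamine is still oxidized by
# HAO, and nitrite reductase regenerates the NO pool.
# See pathway1.tsv for the reconstruction notes on the NIR and NADH lines.
id	name	equation	lb	ub	subsystem	genes
Trans_NH4	Ammonium transporter	nh4_e -> nh3_c + h_p	0	1000	ammonia oxidation
AMO_NO	Ammonia monooxygenase (NO-dependent)	nh3_c + o2_c + 2 no_c + h2o_c -> nh2oh_c + 2 hno2_c	0	1000	ammonia oxidation
HAO	Hydroxylamine oxidoreductase	nh2oh_c + h2o_c + 4 pcym_p -> hno2_c + 4 pcyme_p + 4 h_p	0	1000	ammonia oxidation
QH2_Synt	Quinone reductase (QRED)	2 pcyme_p + q_c + 2 h_p -> qh2_c + 2 pcym_p	0	1000	electron transport
NIR	Nitrite reductase (reconstructed)	hno2_c + pcyme_p + 0.5 h_p + 0.5 h_c -> no_c + h2o_c + pcym_p	0	1000	electron transport
N2O_spon	Abiotic N2O formation	no_c + nh2oh_c -> n2o_c + h2o_c + h_p	0	1000	ammonia oxidation
Cytbc1	Cytochrome bc1 (complex III)	qh2_c + h_c + 2 pcy_p -> q_c + 3 h_p + 2 pcye_p	0	1000	electron transport
Cytaa3	Cytochrome aa3 (complex IV)	2 pcye_p + 0.5 o2_c + 4 h_c -> 2 h_p + h2o_c + 2 pcy_p	0	1000	electron transport
ATP_Synt	F0F1 ATP synthase	4 h_p + adp_c + pi_c -> 3 h_c + atp_c + h2o_c	0	1000	energy
NADH_Synt	NADH dehydrogenase, reverse (reconstructed)	qh2_c + nad_c -> nadh_c + q_c + h_p	0	1000	energy
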
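site	sequence	category	kcat_km_mM_min	vphos_reported
992	DADEYLIPQ	minor	74.9	8.4
1045	FLQRYSSDP	minor
1068	PVPEYINQS	major	65.4	3.3
1086	QNPVYHNQP	major	12.1	0.3
1101	RDPHYQDPH
1114	GNPEYLNTV	minor	49.8	1.7
1148	DNPDYQQDF	major	71.2	2.8
1173	ENAEYLRVA	major	64.0	2.9
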
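species_id	cluster_index	cluster_type	p450_name
Sphbr2	2	terpene	CYP654C8
Sphbr2	2	terpene	CYP667F1
Sphbr2	11	fungal-RiPP	CYP51F1
Sphbr2	12	NRPS	CYP5109B1
Sphbr2	12	NRPS	CYP6836A1
Sphbr2	16	NRPS	CYP613S1
Trihyb1	14	terpene	CYP6637B2
Wilmi1	9	terpene	CYP51048A1
Wilmi1	11	terpene	CYP6637B2
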
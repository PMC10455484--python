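species_id	display_name	n_clusters
Ascim1	Ascobolus immersus	14
Morimp1	Morchella importuna	12
Sphbr2	Sphaerosporella brunnea	18
Tercla1	Terfezia claveryi	8
Tirniv1	Tirmania nivea	9
Trihyb1	Trichophaea hybrida	16
Tubbor1	Tuber borchii	8
Tubbr1	Tuber brumale	8
Tubin1	Tuber indicum	10
Tubma1	Tuber magnatum	10
Tubme1	Tuber melanosporum	8
Wilmi1	Wilcoxina mikolae CBS 423.85	21
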
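species_id	display_name	lifestyle	total_hits	p450s	no_hits	false_positives	fragments
Ascim1	Ascobolus immersus RN42	SAP	63	58	4	1	0
Ascni1	Ascodesmis nigricans CBS 389.68	SAP	31	28	2	0	1
Morco1	Morchella importuna CCBAS932	SAP	40	37	3	0	0
Morimp1	Morchella importuna SCYDJ1-A1	SAP	41	37	3	0	1
Pyrco1	Pyronema confluens CBS100304	SAP	55	44	1	2	8
Chove1	Choiromyces venosus 120613-1	ECM	52	33	1	1	17
Kalpfe1	Kalaharituber pfeilii F3	ECM	35	32	0	0	3
Sphbr2	Sphaerosporella brunnea Sb_GMNB300	ECM	49	47	0	0	2
Terbo2	Terfezia boudieri ATCC MYA-4762	ECM	24	19	1	2	2
Tercla1	Terfezia claveryi T7	ECM	19	17	0	0	2
Tirniv1	Tirmania nivea G3	ECM	21	19	0	0	2
Trihyb1	Trichophaea hybrida UTF0779	ECM	44	37	0	0	7
Tubae1	Tuber aestivum var. urcinatum	ECM	31	29	0	0	2
Tubbor1	Tuber borchii Tbo3840	ECM	74	55	0	0	19
Tubbr1	Tuber brumale	ECM	37	32	0	0	5
Tubin1	Tuber indicum	ECM	39	35	0	0	4
Tubma1	Tuber magnatum	ECM	32	27	0	1	4
Tubme1	Tuber melanosporum Mel28	ECM	35	30	0	0	5
Wilmi1	Wilcoxina mikolae CBS 423.85	ECM	57	52	1	0	4
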
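species_id	display_name	n_families	n_subfamilies
Ascim1	Ascobolus immersus RN42	36	49
Ascni1	Ascodesmis nigricans CBS 389.68	24	26
Chove1	Choiromyces venosus 120613-1	24	29
Kalpfe1	Kalaharituber pfeilii F3	20	22
Morco1	Morchella importuna CCBAS932	33	36
Morimp1	Morchella importuna SCYDJ1-A1	33	36
Pyrco1	Pyronema confluens CBS100304	37	43
Sphbr2	Sphaerosporella brunnea Sb_GMNB300	38	45
Terbo2	Terfezia boudieri ATCC MYA-4762	16	18
Tercla1	Terfezia claveryi T7	14	16
Tirniv1	Tirmania nivea G3	17	19
Trihyb1	Trichophaea hybrida UTF0779	31	36
Tubae1	Tuber aestivum var. urcinatum	24	26
Tubbor1	Tuber borchii Tbo3840	22	27
Tubbr1	Tuber brumale	24	27
Tubin1	Tuber indicum	24	28
Tubma1	Tuber magnatum	21	23
Tubme1	Tuber melanosporum Mel28	23	25
Wilmi1	Wilcoxina mikolae CBS 423.85	40	49
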
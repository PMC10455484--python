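family	members	n_subfamilies
CYP567	38	12
CYP6001	35	3
CYP52	34	13
CYP5959	31	1
CYP548	24	2
CYP51	20	1
CYP5093	19	3
CYP61	19	1
CYP539	18	1
CYP6135	18	1
CYP6136	15	4
CYP617	15	4
CYP663	14	2
CYP512	13	4
CYP5945	12	6
CYP6220	11	1
CYP51070	10	1
CYP573	9	2
CYP6271	9	1
CYP6713	8	6
CYP50043	7	1
CYP504	7	2
CYP51062	6	3
CYP530	6	1
CYP6188	6	1
CYP6498	6	1
CYP6592	6	1
CYP50194	5	2
CYP505	5	1
CYP675	5	2
CYP50026	4	2
CYP50127	4	3
CYP50251	4	2
CYP51074	4	3
CYP53	4	1
CYP6433	4	1
CYP6453	4	1
CYP6501	4	1
CYP6529	4	1
CYP6608	4	1
CYP6637	4	2
CYP6648	4	2
CYP6761	4	3
CYP6855	4	4
CYP50115	3	2
CYP50335	3	2
CYP5078	3	2
CYP51041	3	2
CYP51048	3	3
CYP51069	3	3
CYP51083	3	3
CYP51089	3	2
CYP51092	3	2
CYP5192	3	2
CYP5268	3	1
CYP532	3	2
CYP584	3	2
CYP6470	3	1
CYP6497	3	2
CYP6521	3	2
CYP6643	3	1
CYP6685	3	1
CYP671	3	1
CYP6742	3	2
CYP6902	3	2
CYP50030	2	1
CYP50042	2	2
CYP50241	2	1
CYP50308	2	1
CYP50320	2	1
CYP50357	2	1
CYP51042	2	2
CYP51044	2	1
CYP51045	2	1
CYP51046	2	1
CYP51052	2	2
CYP51057	2	1
CYP51073	2	1
CYP51075	2	2
CYP51079	2	2
CYP51085	2	2
CYP51093	2	1
CYP5142	2	1
CYP5242	2	1
CYP540	2	1
CYP578	2	1
CYP6002	2	1
CYP6480	2	1
CYP6535	2	1
CYP666	2	1
CYP6683	2	1
CYP6775	2	1
CYP6818	2	1
CYP6900	2	1
CYP6958	2	1
CYP5004	1	1
CYP50147	1	1
CYP50183	1	1
CYP503	1	1
CYP5095	1	1
CYP5104	1	1
CYP51040	1	1
CYP51043	1	1
CYP51047	1	1
CYP51049	1	1
CYP51050	1	1
CYP51053	1	1
CYP51054	1	1
CYP51055	1	1
CYP51056	1	1
CYP51058	1	1
CYP51059	1	1
CYP51060	1	1
CYP51061	1	1
CYP51063	1	1
CYP51064	1	1
CYP51065	1	1
CYP51066	1	1
CYP51068	1	1
CYP51071	1	1
CYP51072	1	1
CYP51076	1	1
CYP51077	1	1
CYP51078	1	1
CYP5108	1	1
CYP51080	1	1
CYP51081	1	1
CYP51082	1	1
CYP51084	1	1
CYP51086	1	1
CYP51087	1	1
CYP51088	1	1
CYP5109	1	1
CYP51090	1	1
CYP51091	1	1
CYP52486	1	1
CYP52487	1	1
CYP55	1	1
CYP566	1	1
CYP594	1	1
CYP596	1	1
CYP6006	1	1
CYP613	1	1
CYP65	1	1
CYP654	1	1
CYP665	1	1
CYP66608	1	1
CYP667	1	1
CYP676	1	1
CYP677	1	1
CYP6793	1	1
CYP682	1	1
CYP6836	1	1
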
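family_id	method	k_tested	detected
tc001	testcross	6	1
tc002	testcross	6	0
tc003	testcross	6	0
tc004	testcross	6	0
tc005	testcross	6	0
tc006	testcross	6	0
tc007	testcross	6	0
tc008	testcross	6	0
tc009	testcross	6	0
tc010	testcross	6	0
tc011	testcross	6	0
tc012	testcross	6	0
tc013	testcross	6	0
tc014	testcross	6	0
tc015	testcross	6	0
tc016	testcross	6	0
tc017	testcross	6	0
tc018	testcross	6	0
tc019	testcross	6	0
tc020	testcross	6	0
tc021	testcross	6	0
tc022	testcross	6	0
tc023	testcross	6	0
tc024	testcross	6	0
tc025	testcross	6	0
tc026	testcross	6	0
tc027	testcross	6	0
tc028	testcross	6	0
tc029	testcross	6	0
tc030	testcross	6	0
tc031	testcross	6	0
tc032	testcross	6	0
tc033	testcross	6	0
tc034	testcross	6	0
tc035	testcross	6	0
tc036	testcross	6	0
tc037	testcross	6	0
tc038	testcross	6	0
tc039	testcross	6	0
tc040	testcross	6	0
tc041	testcross	6	0
tc042	testcross	6	0
tc043	testcross	6	0
tc044	testcross	6	0
tc045	testcross	6	0
tc046	testcross	6	0
tc047	testcross	6	0
tc048	testcross	6	0
tc049	testcross	6	0
tc050	testcross	6	0
tc051	testcross	6	0
tc052	testcross	6	0
tc053	testcross	6	0
tc054	testcross	6	0
tc055	testcross	6	0
tc056	testcross	6	0
tc057	testcross	6	0
tc058	testcross	6	0
tc059	testcross	6	0
tc060	testcross	6	0
tc061	testcross	6	0
tc062	testcross	6	0
tc063	testcross	6	0
tc064	testcross	6	0
tc065	testcross	6	0
tc066	testcross	6	0
tc067	testcross	6	0
tc068	testcross	6	0
tc069	testcross	6	0
tc070	testcross	6	0
tc071	testcross	6	0
tc072	testcross	6	0
tc073	testcross	6	0
tc074	testcross	6	0
tc075	testcross	6	0
tc076	testcross	6	0
tc077	testcross	6	0
tc078	testcross	6	0
tc079	testcross	6	0
tc080	testcross	6	0
tc081	testcross	5	0
tc082	testcross	5	0
tc083	testcross	5	0
tc084	testcross	5	0
tc085	testcross	5	0
tc086	testcross	5	0
tc087	testcross	5	0
tc088	testcross	5	0
tc089	testcross	5	0
tc090	testcross	5	0
tc091	testcross	5	0
tc092	testcross	5	0
tc093	testcross	5	0
tc094	testcross	5	0
tc095	testcross	5	0
tc096	testcross	5	0
tc097	testcross	5	0
tc098	testcross	5	0
tc099	testcross	5	0
tc100	testcross	5	0
tc101	testcross	5	0
tc102	testcross	5	0
tc103	testcross	5	0
tc104	testcross	5	0
tc105	testcross	5	0
tc106	testcross	5	0
tc107	testcross	5	0
tc108	testcross	5	0
tc109	testcross	5	0
tc110	testcross	5	0
tc111	testcross	4	0
tc112	testcross	4	0
tc113	testcross	4	0
tc114	testcross	4	0
tc115	testcross	4	0
tc116	testcross	4	0
tc117	testcross	4	0
tc118	testcross	4	0
tc119	testcross	4	0
tc120	testcross	4	0
tc121	testcross	4	0
tc122	testcross	4	0
tc123	testcross	4	0
tc124	testcross	4	0
tc125	testcross	4	0
tc126	testcross	4	0
tc127	testcross	4	0
tc128	testcross	4	0
tc129	testcross	4	0
tc130	testcross	4	0
tc131	testcross	3	0
tc132	testcross	3	0
tc133	testcross	3	0
tc134	testcross	3	0
tc135	testcross	3	0
tc136	testcross	3	0
tc137	testcross	3	0
tc138	testcross	3	0
tc139	testcross	3	0
tc140	testcross	3	0
tc141	testcross	3	0
tc142	testcross	3	0
tc143	testcross	3	0
tc144	testcross	3	0
tc145	testcross	2	0
tc146	testcross	2	0
tc147	testcross	2	0
tc148	testcross	2	0
tc149	testcross	2	0
tc150	testcross	2	0
tc151	testcross	2	0
tc152	testcross	2	0
tc153	testcross	2	0
tc154	testcross	1	0
tc155	testcross	1	0
tc156	testcross	1	0
tc157	testcross	1	0
tc158	testcross	1	0
pcr001	pcr	0	1
pcr002	pcr	0	0
pcr003	pcr	0	0
pcr004	pcr	0	0
pcr005	pcr	0	0
pcr006	pcr	0	0
pcr007	pcr	0	0
pcr008	pcr	0	0
pcr009	pcr	0	0
pcr010	pcr	0	0
pcr011	pcr	0	0
pcr012	pcr	0	0
pcr013	pcr	0	0
pcr014	pcr	0	0
pcr015	pcr	0	0
pcr016	pcr	0	0
pcr017	pcr	0	0
pcr018	pcr	0	0
pcr019	pcr	0	0
pcr020	pcr	0	0
pcr021	pcr	0	0
pcr022	pcr	0	0
pcr023	pcr	0	0
pcr024	pcr	0	0
pcr025	pcr	0	0
pcr026	pcr	0	0
pcr027	pcr	0	0
pcr028	pcr	0	0
pcr029	pcr	0	0
pcr030	pcr	0	0
pcr031	pcr	0	0
pcr032	pcr	0	0
pcr033	pcr	0	0
pcr034	pcr	0	0
pcr035	pcr	0	0
pcr036	pcr	0	0
pcr037	pcr	0	0
pcr038	pcr	0	0
pcr039	pcr	0	0
pcr040	pcr	0	0
pcr041	pcr	0	0
pcr042	pcr	0	0
pcr043	pcr	0	0
pcr044	pcr	0	0
pcr045	pcr	0	0
pcr046	pcr	0	0
pcr047	pcr	0	0
pcr048	pcr	0	0
pcr049	pcr	0	0
pcr050	pcr	0	0
pcr051	pcr	0	0
pcr052	pcr	0	0
pcr053	pcr	0	0
pcr054	pcr	0	0
pcr055	pcr	0	0
pcr056	pcr	0	0
pcr057	pcr	0	0
pcr058	pcr	0	0
pcr059	pcr	0	0
pcr060	pcr	0	0
pcr061	pcr	0	0
pcr062	pcr	0	0
pcr063	pcr	0	0
pcr064	pcr	0	0
pcr065	pcr	0	0
pcr066	pcr	0	0
pcr067	pcr	0	0
pcr068	pcr	0	0
pcr069	pcr	0	0
pcr070	pcr	0	0
pcr071	pcr	0	0
pcr072	pcr	0	0
pcr073	pcr	0	0
pcr074	pcr	0	0
pcr075	pcr	0	0
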
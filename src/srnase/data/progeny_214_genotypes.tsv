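line_id	genotype
P001	SaSa
P002	SaSa
P003	SaSa
P004	SaSa
P005	SaSa
P006	SaSa
P007	SaSa
P008	SaSa
P009	SaSa
P010	SaSa
P011	SaSa
P012	SaSa
P013	SaSa
P014	SaSa
P015	SaSa
P016	SaSa
P017	SaSa
P018	SaSa
P019	SaSa
P020	SaSa
P021	SaSa
P022	SaSa
P023	SaSa
P024	SaSa
P025	SaSa
P026	SaSa
P027	SaSa
P028	SaSa
P029	SaSa
P030	SaSa
P031	SaSa
P032	SaSa
P033	SaSa
P034	SaSa
P035	SaSa
P036	SaSa
P037	SaSa
P038	SaSa
P039	SaSa
P040	SaSa
P041	SaSa
P042	SaSa
P043	SaSa
P044	SaSa
P045	SaSa
P046	SaSa
P047	SaSa
P048	SaSa
P049	SaSb
P050	SaSb
P051	SaSb
P052	SaSb
P053	SaSb
P054	SaSb
P055	SaSb
P056	SaSb
P057	SaSb
P058	SaSb
P059	SaSb
P060	SaSb
P061	SaSb
P062	SaSb
P063	SaSb
P064	SaSb
P065	SaSb
P066	SaSb
P067	SaSb
P068	SaSb
P069	SaSb
P070	SaSb
P071	SaSb
P072	SaSb
P073	SaSb
P074	SaSb
P075	SaSb
P076	SaSb
P077	SaSb
P078	SaSb
P079	SaSb
P080	SaSb
P081	SaSb
P082	SaSb
P083	SaSb
P084	SaSb
P085	SaSb
P086	SaSb
P087	SaSb
P088	SaSb
P089	SaSb
P090	SaSb
P091	SaSb
P092	SaSb
P093	SaSb
P094	SaSb
P095	SaSb
P096	SaSb
P097	SaSb
P098	SaSb
P099	SaSb
P100	SaSb
P101	SaSb
P102	SaSb
P103	SaSb
P104	SaSb
P105	SaSb
P106	SaSb
P107	SaSb
P108	SaSb
P109	SaSb
P110	SaSb
P111	SaSb
P112	SaSb
P113	SaSb
P114	SaSb
P115	SaSb
P116	SaSb
P117	SaSb
P118	SaSb
P119	SaSb
P120	SaSb
P121	SaSb
P122	SaSb
P123	SaSb
P124	SaSb
P125	SaSb
P126	SaSb
P127	SaSb
P128	SaSb
P129	SaSb
P130	SaSb
P131	SaSb
P132	SaSb
P133	SaSb
P134	SaSb
P135	SaSb
P136	SaSb
P137	SaSb
P138	SaSb
P139	SaSb
P140	SaSb
P141	SaSb
P142	SaSb
P143	SaSb
P144	SaSb
P145	SaSb
P146	SaSb
P147	SaSb
P148	SaSb
P149	SaSb
P150	SaSb
P151	SaSb
P152	SaSb
P153	SaSb
P154	SaSb
P155	SbSb
P156	SbSb
P157	SbSb
P158	SbSb
P159	SbSb
P160	SbSb
P161	SbSb
P162	SbSb
P163	SbSb
P164	SbSb
P165	SbSb
P166	SbSb
P167	SbSb
P168	SbSb
P169	SbSb
P170	SbSb
P171	SbSb
P172	SbSb
P173	SbSb
P174	SbSb
P175	SbSb
P176	SbSb
P177	SbSb
P178	SbSb
P179	SbSb
P180	SbSb
P181	SbSb
P182	SbSb
P183	SbSb
P184	SbSb
P185	SbSb
P186	SbSb
P187	SbSb
P188	SbSb
P189	SbSb
P190	SbSb
P191	SbSb
P192	SbSb
P193	SbSb
P194	SbSb
P195	SbSb
P196	SbSb
P197	SbSb
P198	SbSb
P199	SbSb
P200	SbSb
P201	SbSb
P202	SbSb
P203	SbSb
P204	SbSb
P205	SbSb
P206	SbSb
P207	SbSb
P208	SbSb
P209	SbSb
P210	SbSb
P211	SbSb
P212	SbSb
P213	SbSb
P214	SbSb
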
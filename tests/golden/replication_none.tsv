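snp_id	gene_id	n	beta	se	t	p_raw	tested	reason	p_adjusted	q
rs000210	G00065	22	-0.3045622302	0.08940594417	-3.406509859	0.002799016357	True		0.003591682246	0.05387523368
rs000219	G00068	22	0.3308920479	0.08398842631	3.939733871	0.0008099622356	True		0.001102196328	0.03306588984
rs000337	G00103	22	0.1141396782	0.05254578139	2.172194898	0.0420385797	True		0.04762021255	0.221848811
rs000082	G00026	22	0.2225452596	0.116905502	1.903633754	0.0714485721	True		0.0790609927	0.221848811
rs000449	G00143	22	-0.04726772692	0.06898026799	-0.6852354782	0.5010609866	True		0.5121574624	0.5311365367
rs000102	G00039	22	0.5066591086	0.3608464879	1.40408491	0.1756322919	True		0.1870274133	0.28054112
rs000128	G00043	22	-0.2892130304	0.1932454223	-1.496609994	0.1501099611	True		0.1608988216	0.2583967081
rs000222	G00070	22	0.05978817048	0.1690627096	0.3536449323	0.7273056343	True		0.7340634744	0.6291972637
rs000029	G00013	22	-0.1922661284	0.1059281514	-1.81506168	0.08454142344	True		0.09286598454	0.221848811
rs000086	G00028	22	0.1973009002	0.1327452063	1.486312807	0.1527911188	True		0.1636512485	0.2583967081
rs000480	G00155	22	0.2467390842	0.07908480852	3.119930222	0.005395273744	True		0.006713558131	0.06713558131
rs000104	G00035	22	-0.2068725797	0.1122371744	-1.843173448	0.0801754661	True		0.08827312899	0.221848811
rs000283	G00086	22	0.2490563266	0.09392151889	2.651749349	0.01530795743	True		0.01815139586	0.1195071539
rs000327	G00099	22	0.380465296	0.1900711984	2.001698833	0.05906846766	True		0.06590990809	0.221848811
rs000323	G00100	22	-0.1829722572	0.09662254076	-1.893680871	0.072825017	True		0.08051694201	0.221848811
rs000018	G00008	22	-0.2226807261	0.1240021288	-1.795781477	0.08765414685	True		0.09613448477	0.221848811
rs000078	G00025	22	-0.08274185473	0.119926951	-0.6899354484	0.4981631875	True		0.5093014204	0.5311365367
rs000159	G00052	22	0.07656576123	0.1325712224	0.5775443557	0.5700172713	True		0.5799981253	0.5612885084
rs000492	G00157	22	-0.08221046432	0.1278734797	-0.6429047251	0.5275885758	True		0.5382826451	0.5382826451
rs000209	G00064	22	0.008639586499	0.2565751325	0.03367273522	0.9734719172	True		0.9741553303	0.7491181085
rs000255	G00080	22	0.03702441655	0.1526891236	0.2424823436	0.8108757198	True		0.8156608195	0.6613466104
rs000036	G00012	22	-0.01556779921	0.08095881894	-0.1922928152	0.8494519165	True		0.8532870837	0.6736476976
rs000448	G00144	22	-0.163662872	0.1058575851	-1.546066556	0.137766097	True		0.1482015764	0.2583967081
rs000230	G00074	22	0.0001528484895	0.09978878915	0.001531720054	0.9987930401	True		0.9988241446	0.7491181085
rs000140	G00048	22	-0.1118137291	0.1301790508	-0.8589226024	0.4005609639	True		0.412811416	0.51601427
rs000107	G00037	22	0.06963174371	0.1434167917	0.4855201605	0.6325836816	True		0.6413783394	0.6012921932
rs000452	G00145	22	0.2125804488	0.1309331593	1.623579924	0.1201226251	True		0.1299740373	0.24370132
rs000145	G00050	22	-0.07499007324	0.1694025738	-0.4426737539	0.6627523085	True		0.6709261956	0.6099329051
rs000282	G00084	22	-0.3082781531	0.1182541161	-2.606912667	0.01687266987	True		0.01991785899	0.1195071539
rs000386	G00121	22	-0.1199161236	0.1746633335	-0.686555794	0.5002459668	True		0.5113542322	0.5311365367
rs000105	G00040	22	-0.02977392473	0.09959371638	-0.2989538478	0.7680595151	True		0.7738720205	0.6448933504
rs000437	G00139	22	-0.1005701045	0.279256819	-0.3601348211	0.7225215231	True		0.7293879485	0.6291972637
rs000022	G00009	22	0.1233665488	0.180586749	0.6831428635	0.5023542901	True		0.5134319855	0.5311365367
rs000243	G00077	22	-0.07133017486	0.0987170175	-0.7225722238	0.478307736	True		0.4897197473	0.5311365367
rs000271	G00082	22	-0.1272027883	0.07619128794	-1.669518809	0.1105932393	True		0.1200857235	0.24370132
rs000191	G00056	22	0.1815461521	0.1734630913	1.046598159	0.3077695989	True		0.3204034862	0.4179175907
rs000214	G00067	22	-0.1475235648	0.140827122	-1.047550803	0.3073409724	True		0.3199746983	0.4179175907
rs000364	G00111	22	0.1717100162	0.1037819857	1.654526217	0.1136301972	True		0.1232406392	0.24370132
rs000247	G00079	22	-0.1676081902	0.0915772367	-1.830238564	0.08215927686	True		0.09036128439	0.221848811
rs000085	G00027	22	-0.1221244273	0.1074023282	-1.137074301	0.2689476421	True		0.2814804018	0.4021148598
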
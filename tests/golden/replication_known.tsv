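snp_id	gene_id	n	beta	se	t	p_raw	tested	reason	p_adjusted	q
rs000210	G00065	22	-0.3170417124	0.08730735513	-3.631328791	0.002063683733	True		0.002063683733	0.030955256
rs000219	G00068	22	0.2733354977	0.1024505372	2.667975251	0.01622265452	True		0.01622265452	0.08111327259
rs000337	G00103	22	0.08261970099	0.05950410742	1.388470554	0.1829199641	True		0.1829199641	0.3429749326
rs000082	G00026	22	0.1755079672	0.1158069464	1.515521933	0.1480130643	True		0.1480130643	0.2960261286
rs000449	G00143	22	-0.06881434311	0.07550251148	-0.9114179351	0.3748186311	True		0.3748186311	0.4685232889
rs000102	G00039	22	0.1754745766	0.1466151472	1.19683798	0.2477941886	True		0.2477941886	0.4372838622
rs000128	G00043	22	-0.4954316703	0.0701223921	-7.065242006	1.897582094e-06	True		1.897582094e-06	5.692746283e-05
rs000222	G00070	22	0.125309158	0.1299815245	0.96405361	0.3485334167	True		0.3485334167	0.4546088044
rs000029	G00013	22	-0.264470631	0.08573235845	-3.084840261	0.006719225163	True		0.006719225163	0.06719225163
rs000086	G00028	22	0.248103564	0.08588117716	2.888916666	0.01019926101	True		0.01019926101	0.07649445757
rs000480	G00155	22	0.2321263647	0.08644563602	2.685229416	0.01564991221	True		0.01564991221	0.08111327259
rs000104	G00035	22	-0.22364626	0.1089475272	-2.052788768	0.05581537123	True		0.05581537123	0.1522237397
rs000283	G00086	22	0.2590245856	0.1132006788	2.288189332	0.03520672211	True		0.03520672211	0.1124967572
rs000327	G00099	22	0.2146258396	0.2197178198	0.9768249104	0.342352557	True		0.342352557	0.4546088044
rs000323	G00100	22	-0.186796607	0.1015187345	-1.840021036	0.08329221151	True		0.08329221151	0.1784833104
rs000018	G00008	22	-0.2720286322	0.1205550216	-2.256468695	0.03749891907	True		0.03749891907	0.1124967572
rs000078	G00025	22	-0.03476305035	0.09412675173	-0.3693216828	0.7164479367	True		0.7164479367	0.6640089867
rs000159	G00052	22	0.09364279357	0.1469512443	0.6372371599	0.5324592217	True		0.5324592217	0.6001064115
rs000492	G00157	22	-0.02017749638	0.1437077634	-0.1404064464	0.8899890702	True		0.8899890702	0.6777409645
rs000209	G00064	22	0.1054854427	0.1939950493	0.5437532713	0.5936712851	True		0.5936712851	0.6186145613
rs000255	G00080	22	0.06442706573	0.1518698592	0.4242254918	0.6767211778	True		0.6767211778	0.6640089867
rs000036	G00012	22	0.03567251859	0.09956794747	0.3582731139	0.7245491355	True		0.7245491355	0.6640089867
rs000448	G00144	22	-0.2475911905	0.1054412443	-2.34814367	0.03122617805	True		0.03122617805	0.1124967572
rs000230	G00074	22	0.01956082821	0.1037119903	0.188607201	0.8526339123	True		0.8526339123	0.6777409645
rs000140	G00048	22	-0.1214704533	0.154675122	-0.7853263776	0.443070309	True		0.443070309	0.5316843708
rs000107	G00037	22	-0.02560733528	0.1547946903	-0.1654277367	0.8705586401	True		0.8705586401	0.6777409645
rs000452	G00145	22	0.1639087485	0.147706523	1.10969201	0.2825829521	True		0.2825829521	0.4434089797
rs000145	G00050	22	-0.09817764504	0.1570157956	-0.6252724107	0.5400957704	True		0.5400957704	0.6001064115
rs000282	G00084	22	-0.2344247705	0.1212293851	-1.933728942	0.06997382694	True		0.06997382694	0.1749345673
rs000386	G00121	22	-0.02090655527	0.1701583313	-0.122865305	0.9036546194	True		0.9036546194	0.6777409645
rs000105	G00040	22	-0.1141007421	0.1160284065	-0.9833862722	0.3392069657	True		0.3392069657	0.4546088044
rs000437	G00139	22	-0.0698950423	0.2181252924	-0.3204352945	0.7525435183	True		0.7525435183	0.6640089867
rs000022	G00009	22	0.0722580802	0.1344727004	0.5373438621	0.5979940759	True		0.5979940759	0.6186145613
rs000243	G00077	22	-0.02918806293	0.1073885315	-0.2717986969	0.7890500802	True		0.7890500802	0.6763286402
rs000271	G00082	22	-0.103714184	0.09558651297	-1.085029475	0.2930565057	True		0.2930565057	0.4434089797
rs000191	G00056	22	-0.05866637892	0.1753760376	-0.3345176441	0.742080682	True		0.742080682	0.6640089867
rs000214	G00067	22	-0.1947728292	0.1036139606	-1.879793302	0.07738708283	True		0.07738708283	0.1784833104
rs000364	G00111	22	0.1037311981	0.0961253561	1.079124201	0.2956059865	True		0.2956059865	0.4434089797
rs000247	G00079	22	-0.2099484867	0.09074810051	-2.313530372	0.03346983064	True		0.03346983064	0.1124967572
rs000085	G00027	22	0.0220804947	0.09437711074	0.2339602741	0.8178101148	True		0.8178101148	0.6777409645
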
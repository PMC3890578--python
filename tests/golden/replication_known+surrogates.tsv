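snp_id	gene_id	n	beta	se	t	p_raw	tested	reason	p_adjusted	q
rs000210	G00065	22	-0.3295038233	0.173104471	-1.903496896	0.08345494586	True		0.09446491963	0.2034629038
rs000219	G00068	22	0.3360749513	0.1744626513	1.926343254	0.0802836099	True		0.09107583919	0.2034629038
rs000337	G00103	22	0.1382374183	0.07833780949	1.764632165	0.1053365921	True		0.1176737909	0.2241727329
rs000082	G00026	22	-0.02036119605	0.1472973027	-0.1382319681	0.892555116	True		0.8961765413	0.6457930523
rs000449	G00143	22	-0.1861853533	0.08741929622	-2.129796982	0.05659952123	True		0.06550974395	0.1708577963
rs000102	G00039	22	0.2345624648	0.104286034	2.249222219	0.04595252219	True		0.05383399506	0.1674835402
rs000128	G00043	22	-0.421676707	0.09118724411	-4.62429489	0.000735208491	True		0.001107656642	0.03101438597
rs000222	G00070	22	0.08452267224	0.104188677	0.8112462378	0.4344268709	True		0.45016438	0.5338831828
rs000029	G00013	22	-0.2814247599	0.07485401525	-3.759648149	0.003156590656	True		0.004344693011	0.0405504681
rs000086	G00028	22	0.201314879	0.08089832303	2.488492609	0.03011595688	True		0.03616681383	0.1459102165
rs000480	G00155	22	0.153076341	0.08739087179	1.751628492	0.107631978	True		0.1200925355	0.2241727329
rs000104	G00035	22	-0.1806679194	0.07940261781	-2.275339584	0.04389403971	True		0.05156007297	0.1674835402
rs000283	G00086	22	0.1734222021	0.1147493482	1.511313178	0.158891265	True		0.1734975109	0.2556805424
rs000327	G00099	22	0.512512313	0.1992383104	2.572358257	0.02594116381	True		0.03142947709	0.1459102165
rs000323	G00100	22	-0.1139979989	0.1207471439	-0.9441051377	0.3653911161	True		0.3818701553	0.5091602071
rs000018	G00008	22	-0.2996574135	0.1083377562	-2.765955509	0.01835930154	True		0.02270608681	0.1459102165
rs000078	G00025	22	-0.07309940662	0.1726952409	-0.4232855882	0.6802443834	True		0.6905134705	0.6041992866
rs000159	G00052	22	0.05326534751	0.1563610276	0.3406561618	0.7397796296	True		0.7482972677	0.6304563745
rs000492	G00157	22	-0.01536430978	0.1355046163	-0.1133858772	0.9117675594	True		0.9147470579	0.6457930523
rs000209	G00064	22	0.3128189194	0.1259652589	2.48337456	0.03039101626	True		0.03647755412	0.1459102165
rs000255	G00080	22	0.07366535399	0.1569620151	0.4693196246	0.6480063339	True		0.6591717752	0.5953809582
rs000036	G00012	22	-0.04395523602	0.13889866	-0.3164554361	0.7575810462	True		0.765554169	0.6304563745
rs000448	G00144	22	-0.01401975144	0.1098516602	-0.1276243928	0.90074947	True		0.904097559	0.6457930523
rs000230	G00074	22	-0.1330636151	0.1823222727	-0.7298264394	0.4807497902	True		0.4957486697	0.5338831828
rs000140	G00048	22	-0.1671323614	0.1081400888	-1.545517146	0.1504893246	True		0.1648135393	0.2556805424
rs000107	G00037	22	-0.1199206808	0.2266567969	-0.5290848652	0.6072579942	True		0.6194944704	0.578194839
rs000452	G00145	22	0.09978721338	0.136462536	0.731242554	0.4799185431	True		0.4949321602	0.5338831828
rs000145	G00050	22	-0.06674645793	0.1230289562	-0.5425264098	0.5982755432	True		0.6107378401	0.578194839
rs000282	G00084	22	-0.2197329154	0.1442046728	-1.523757248	0.1557886719	True		0.1702935454	0.2556805424
rs000386	G00121	22	0.2002271836	0.1642805522	1.218812458	0.2484084532	True		0.2648096338	0.3707334874
rs000105	G00040	22	-0.07505575552	0.09841472409	-0.7626476243	0.4617151061	True		0.4770383071	0.5338831828
rs000437	G00139	22	-0.4300214979	0.1138275621	-3.777832803	0.003058549435	True		0.004217935479	0.0405504681
rs000022	G00009	22	-0.03217386056	0.1179570284	-0.2727591649	0.7900908722	True		0.7970486236	0.6376388989
rs000243	G00077	22	0.01373183233	0.10111068	0.1358099097	0.89442504	True		0.897984154	0.6457930523
rs000271	G00082	22	-0.0473838873	0.07030548294	-0.6739714361	0.5142427852	True		0.5286067782	0.548184807
rs000191	G00056	22	0.01929397974	0.1874056824	0.1029530134	0.9198531985	True		0.9225615033	0.6457930523
rs000214	G00067	22	-0.2568051398	0.1214256204	-2.114917256	0.05807969949	True		0.06712270569	0.1708577963
rs000364	G00111	22	0.05404463223	0.08642471442	0.6253377011	0.5445042985	True		0.5582306449	0.5582306449
rs000247	G00079	22	-0.1707424584	0.0999142069	-1.708890695	0.1154968985	True		0.1283598912	0.2246298096
rs000085	G00027	22	0.0830288219	0.1108330075	0.7491344301	0.4694934529	True		0.4846874875	0.5338831828
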
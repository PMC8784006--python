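name	locus	species	chromosome	start	end	strand	type	type_corrected	flag
TaDHN1-A	TraesCS3A02G254600	Ta	3A	476563869	476564968	-	YSK2	.	.
TaDHN1-B	TraesCS3B02G286600	Ta	3B	458398889	458399630	-	YSK2	.	.
TaDHN1-D	TraesCS3D02G255500	Ta	3D	357146923	357147959	-	YSK2	.	.
TaDHN2-A	TraesCS3A02G396200	Ta	3A	643459970	643461316	-	YSK3	.	.
TaDHN2-B	TraesCS3B02G428200	Ta	3B	667112076	667113352	-	YSK3	.	.
TaDHN2-D	TraesCS3D02G390200	Ta	3D	505318572	505319988	-	YSK3	.	.
TaDHN3-A	TraesCS4A02G250900	Ta	4A	562289788	562291566	-	Y2SK3	.	.
TaDHN3-B	TraesCS4B02G064200	Ta	4B	57136426	57138194	-	Y2SK3	.	.
TaDHN3-D	TraesCS4D02G063100	Ta	4D	39233033	39234840	-	Y2SK3	.	.
TaDHN4-A1	TraesCS5A02G369800	Ta	5A	569677389	569678193	+	YSK2	.	.
TaDHN4-A2	TraesCS5A02G369900	Ta	5A	569682833	569683707	+	YSK2	.	.
TaDHN4-B1	TraesCS5B02G372100	Ta	5B	550320429	550321418	+	YSK2	.	.
TaDHN4-B2	TraesCS5B02G372200	Ta	5B	550337855	550338611	+	YSK2	.	.
TaDHN4-D1	TraesCS5D02G379200	Ta	5D	450373636	450374483	+	YSK2	.	.
TaDHN4-D2	TraesCS5D02G379300	Ta	5D	450379533	450380460	+	YSK2	.	.
TaDHN5-A1	TraesCS5A02G424700	Ta	5A	610078219	610079136	-	YSK1	.	truncated
TaDHN5-A2	TraesCS5A02G424800	Ta	5A	610184778	610185696	-	YSK2	.	.
TaDHN5-B1	TraesCS5B02G426700	Ta	5B	602483279	602484206	-	YSK2	.	.
TaDHN5-B2	TraesCS5B02G426800	Ta	5B	602648556	602649390	-	YSK2	.	.
TaDHN5-D1	TraesCS5D02G433200	Ta	5D	489012960	489013838	-	YSK2	.	.
TaDHN5-D2	TraesCS5D02G433300	Ta	5D	489166583	489167421	-	YSK2	.	.
TaDHN6-A	TraesCS6A02G059800	Ta	6A	31583535	31584464	-	YSK2	.	.
TaDHN6-B	TraesCSU02G086200	Ta	Un	76960851	76961538	+	YSK2	.	.
TaDHN6-D	TraesCSU02G122200	Ta	Un	104041218	104042344	-	YSK1	.	truncated
TaDHN7-A	TraesCS6A02G253300	Ta	6A	468473627	468475112	-	SK3	.	.
TaDHN7-B	TraesCS6B02G273400	Ta	6B	493352704	493354073	-	SK3	.	.
TaDHN7-D	TraesCS6D02G234700	Ta	6D	329080938	329082415	-	SK3	.	.
TaDHN8-A	TraesCS6A02G350100	Ta	6A	581982926	581983580	+	K3	.	truncated
TaDHN8-B	TraesCS6B02G383200	Ta	6B	658177094	658178907	+	K6	.	.
TaDHN8-D	TraesCS6D02G332500	Ta	6D	434811674	434812738	+	K3	.	truncated
TaDHN9-A	TraesCS6A02G350200	Ta	6A	582086438	582087160	+	K2	.	.
TaDHN9-D	TraesCS6D02G332600	Ta	6D	435012400	435012681	+	K2	.	.
TaDHN10-A	TraesCS6A02G350300	Ta	6A	582092081	582096138	+	K14	.	.
TaDHN10-B	TraesCS6B02G695200LC	Ta	6B	658234035	658241687	+	K8	.	truncated
TaDHN10-D	TraesCS6D02G332700	Ta	6D	435072895	435075633	+	K12	.	.
TaDHN11-A	TraesCS6A02G350500	Ta	6A	582264726	582266027	+	YSK2	.	.
TaDHN11-B	TraesCS6B02G383500	Ta	6B	658402976	658404180	+	YSK2	.	.
TaDHN11-D	TraesCS6D02G332900	Ta	6D	435351033	435352218	+	YSK2	.	.
TaDHN12-A1	TraesCS6A02G350600	Ta	6A	582511276	582512221	+	YSK2	.	.
TaDHN12-A2	TraesCS6A02G350700	Ta	6A	582516436	582517359	+	YSK2	.	.
TaDHN12-A3	TraesCS6A02G350800	Ta	6A	582630751	582631295	-	SK2	YSK2	misannotated
TaDHN12-A4	TraesCS6A02G350900	Ta	6A	582638141	582638862	-	YSK1	.	misannotated
TaDHN12-B1	TraesCS6B02G695700LC	Ta	6B	658477430	658478020	+	YSK2	.	.
TaDHN12-B2	TraesCS6B02G695800LC	Ta	6B	658496215	658496805	+	YSK2	.	.
TaDHN12-B3	TraesCS6B02G695900LC	Ta	6B	658515366	658515956	+	YSK2	.	.
TaDHN12-B4	TraesCS6B02G383600	Ta	6B	658530539	658531483	+	YSK2	.	.
TaDHN12-B5	TraesCS6B02G383800	Ta	6B	658577562	658578499	-	YSK2	.	.
TaDHN12-D1	TraesCS6D02G333000	Ta	6D	435711668	435712623	+	YSK2	.	.
TaDHN12-D2	TraesCS6D02G333100	Ta	6D	435749803	435750719	+	YSK2	.	.
TaDHN12-D3	TraesCS6D02G333200	Ta	6D	435763700	435764598	+	YSK2	.	.
TaDHN12-D4	TraesCS6D02G333300	Ta	6D	435831506	435832386	-	YSK2	.	.
TaDHN12-D5	TraesCS6D02G333600	Ta	6D	435962275	435963310	-	YSK2	.	.
TaDHN13-A	TraesCS7A02G560000	Ta	7A	731882428	731883023	+	K3	.	.
TaDHN13-B	TraesCS7B02G484900	Ta	7B	741668510	741668887	+	K3	.	.
TaDHN13-D	TraesCS7D02G549900	Ta	7D	634439606	634440272	-	K2	.	.
TdDHN1-A	TRIDC3AG038190	Td	3A	483446623	483451982	-	YSK2	.	.
TdDHN1-B	TRIDC3BG042940	Td	3B	468417850	468427038	-	YSK2	.	.
TdDHN2-A	TRIDC3AG056410	Td	3A	639664417	639665447	-	YSK2	.	truncated
TdDHN2-B	TRIDC3BG063150	Td	3B	677652490	677653501	-	YSK2	.	truncated
TdDHN3-A	TRIDC4AG039320	Td	4A	555522541	555523348	-	SK3	.	truncated
TdDHN3-B	TRIDC4BG009930	Td	4B	55083350	55084815	-	Y2SK3	.	truncated
TdDHN4-A1	TRIDC5AG054100	Td	5A	564921473	564922000	+	YSK2	.	.
TdDHN4-A2	TRIDC5AG054110	Td	5A	564926944	564927492	+	YSK2	.	.
TdDHN4-B1	TRIDC5BG058060	Td	5B	556085190	556085719	+	YSK2	.	.
TdDHN4-B2	TRIDC5BG058080	Td	5B	556101420	556101927	+	YSK2	.	.
TdDHN5-A1	TRIDC5AG061380	Td	5A	605402094	605402742	-	SK1	.	truncated
TdDHN5-A2	TRIDC5AG061420	Td	5A	605513222	605513988	-	YSK2	.	misannotated
TdDHN5-B	TRIDC5BG065560	Td	5B	608742508	608743380	-	YSK2	.	.
TdDHN6-A	TRIDC6AG007480	Td	6A	31000232	31000891	-	YSK2	.	.
TdDHN6-B	TRIDC6BG010780	Td	6B	55591718	55592361	-	YSK2	.	.
TdDHN7-A	TRIDC6AG039020	Td	6A	470140072	470141622	-	SK3	.	.
TdDHN7-B	TRIDC6BG045690	Td	6B	486136098	486141800	+	SK3	.	.
TdDHN8-A	TRIDC6AG052540	Td	6A	582467279	582468478	+	K4	.	truncated
TdDHN8-B	TRIDC6BG061300	Td	6B	642747123	642748606	+	K7	.	misannotated
TdDHN9-A	TRIDC6AG052550	Td	6A	582534354	582534931	+	K2	.	.
TdDHN9-B	TRIDC6BG061310	Td	6B	642748977	642749569	+	K2	.	misannotated
TdDHN10-A	TRIDC6AG052570	Td	6A	582541438	582543392	+	K8	.	truncated
TdDHN11-A	TRIDC6AG052590	Td	6A	582698877	582699685	+	YSK2	.	truncated
TdDHN11-B	TRIDC6BG061340	Td	6B	643041875	643042827	+	YSK2	.	.
TdDHN12-A1	TRIDC6AG052630	Td	6A	582893775	582898592	+	YSK2	.	.
TdDHN12-A2	TRIDC6AG052640	Td	6A	582992994	582993790	-	YSK2	.	.
TdDHN12-A3	TRIDC6AG052650	Td	6A	583001187	583001807	-	YSK2	.	.
TdDHN12-B1	TRIDC6BG061350	Td	6B	643116359	643132143	+	YSK2	.	.
TdDHN12-B2	TRIDC6BG061380	Td	6B	643190550	643191397	-	YSK2	.	.
TdDHN13-A	TRIDC7AG077740	Td	7A	723743247	723743983	-	K3	.	.
TdDHN13-B	TRIDC7BG076250	Td	7B	750614280	750614913	+	K3	.	.
TuDHN1	TuG1812G0300003021.01	Tu	3A	477045519	477046650	-	YSK2	.	.
TuDHN3	TuG1812G0400000583.01	Tu	4A	41901253	41903075	-	Y2SK3	.	.
TuDHN4-1	TuG1812G0500003981.01	Tu	5A	535938718	535939515	+	YSK2	.	.
TuDHN4-2	TuG1812G0500003982.01	Tu	5A	535944152	535945001	+	YSK2	.	.
TuDHN5-1	TuG1812G0500004492.01	Tu	5A	574218374	574219129	-	YSK1	.	truncated
TuDHN5-2	TuG1812S0001634800.01	Tu	Un	1	593	-	YSK1	.	truncated
TuDHN6	TuG1812G0600000621.01	Tu	6A	31890359	31891122	-	YSK2	.	.
TuDHN7	TuG1812G0600002817.01	Tu	6A	439323348	439324718	-	SK3	.	.
TuDHN8	TuG1812G0600003768.01	Tu	6A	539540401	539541995	+	K6	.	.
TuDHN9	TuG1812G0600003769.01	Tu	6A	539598064	539599229	+	K2	.	.
TuDHN11	TuG1812G0600003775.01	Tu	6A	539946480	539947767	+	YSK2	.	.
TuDHN12-1	TuG1812S0003423700.01	Tu	Un	1979	2944	+	YSK1	.	misannotated
TuDHN12-2	TuG1812S0003424100.01	Tu	Un	5679	6605	+	YSK2	.	.
TuDHN12-3	TuG1812G0600003779.01	Tu	6A	540160098	540161020	-	YSK2	.	.
TuDHN13	TuG1812G0700005988.01	Tu	7A	712117702	712118431	+	K3	.	.
AetDHN1	AET3Gv20620600	Aet	3D	364603011	364610005	-	YSK2	.	.
AetDHN2	AET3Gv20881700	Aet	3D	513201759	513203320	-	SK2	.	truncated
AetDHN3	AET4Gv20132600	Aet	4D	41638766	41640754	-	Y2SK3	.	.
AetDHN4-1	AET5Gv20866700	Aet	5D	458683120	458684124	+	YSK2	.	.
AetDHN4-2	AET5Gv20866800	Aet	5D	458689123	458689989	+	YSK2	.	.
AetDHN5	AET5Gv20990000	Aet	5D	498787518	499029693	-	YSK2	.	.
AetDHN6	AET6Gv20153700	Aet	6D	34801689	34803209	-	K1	.	truncated
AetDHN7	AET6Gv20653900	Aet	6D	352066646	352068329	-	SK3	.	.
AetDHN8	AET6Gv20864100	Aet	6D	458864577	458866768	+	K6	.	.
AetDHN9	AET6Gv20864400	Aet	6D	459070823	459071706	+	K2	.	.
AetDHN10	AET6Gv20864500	Aet	6D	459131190	459134316	+	K9	.	truncated
AetDHN11	AET6Gv20864900	Aet	6D	459422062	459423545	+	YSK1	.	misannotated
AetDHN12-1	AET6Gv20865700	Aet	6D	459787474	459841184	+	YSK2	.	.
AetDHN12-2	AET6Gv20866000	Aet	6D	459889128	459890166	-	YSK2	.	.
AetDHN12-3	AET6Gv20866400	Aet	6D	460020381	460021566	-	YSK2	.	.
AetDHN13	AET7Gv21347200	Aet	7D	641274370	641275124	+	K2	.	.
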
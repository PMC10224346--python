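species	mt1_intron1	mt1_intron2	mt2_intron1	mt2_intron2	mt3_intron1	mt3_intron2	mt4_intron1	mt4_intron2
Balaenoptera acutorostrata	611	351	295		175	854	1642	527
Balaenoptera bonaerensis	611	351	295		175	854	1646	527
Balaenoptera musculus	575(c)	737(c)	295	209	175	856	1666	527
Delphinapterus leucas	601	352	295	216	173	854
Eschrichtius robustus	611	351	295	219	175	857	1671	527
Eubalaena japonica			295		175	855	1662	527
Globicephala melas	611(a)-578(b)	350(a)-710(b)	295	216	173	853	1171	526
Inia geoffrensis	611	344	291	215	175	849	1368	527
Kogia breviceps	577	351	295	221	181	854
Lagenorhynchus obliquidens	611	350	295	216	173	851	1308	526
Lipotes vexillifer	608(a)-721(b)-578(c)	350(a)-753(b)-708(c)	295	214	175	853	1436	527
Megaptera novaengliae	611	351	295	205	175	854	1608	526
Mesoplodon bidens			294	215	175	861	1395	526
Monodon monoceros	612	355	295	216	173	854	1395	527
Neophocaena asiaeorientalis	610	350	295	217	173	850	1391	527
Orcinus orca	611	350	295	216	173	853	1309	526
Phocoena phocoena	610	350	295	217	173	849	1393	527
Phocoena sinus	601	352	295	217	173	849	1390	527
Physeter macrocephalus	611(a)-713(b)-716(c)	353(a)-359(b)-359(c)	295	216	176	857
Platanista minor	594	356	297	224	176	803	1399	529
Pontoporia blainvillei	611		295	215	175	861	1357	520
Sousa chinensis	611	351	294	216	173	852	1308	527
Tursiops aduncus	611	350	295	216	173	852	1309	527
Tursiops truncatus	611(a)-612(b)	350(a)-714(b)	295	216	173	1098	1309	527
Ziphius cavirostris	608	351			175	861	1393	526
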
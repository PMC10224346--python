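species	family	mitochondrion	mt_cluster_contigs	intron_free_mt	mt_with_intron	mt_mrna
Balaena mysticetus	Balaenidae	NC_005268				Mt1: SRR17645797; Mt2: AF022117
Balaenoptera acutorostrata	Balaenopteridae	NC_005271	Mt3-Mt2: ATDI01082660-661	Mt1: ATDI01132427, ATDI01131740, ATDI01081017; Mt2: ATDI01041776	Mt1: ATDI01082662; Mt4: ATDI01082657	Mt1: XM_007167588, XR_003622960, XR_003622964, XR_003622677, XM_007193604, XM_007193603, XM_007193605, XM_007193602, XM_007167587, XM_007167582, XM_007198029, XM_007178847, XM_007167583, XM_007164196, XM_007175023; Mt2: XM_007167584; Mt4: XM_028162920
Balaenoptera bonaerensis	Balaenopteridae	NC_006926	Mt3-Mt2: BAUQ01093692	Mt1: BAUQ01195848, BAUQ01613210; Mt2: BAUQ01307512	Mt1: BAUQ01180559; Mt4: BAUQ01234274
Balaenoptera musculus	Balaenopteridae	MF409242	Mt4-Mt3: VNFD01000017	Mt1: VNFD01005770	Mt1: VNFD01001442; Mt2: VNFC01000015; Mt3: VNFC01000015
Delphinapterus leucas	Monodontidae	NC_034236	Mt3-Mt2-Mt1: NQVZ01021645	Mt1: NQVZ01003203		Mt1: XM_022555910, XR_002642604; Mt2: XM_022555911; Mt3: GGBT01018098; Mt4: XM_022555909
Eschrichtius robustus	Eschrichtiidae	NC_005270	Mt4-Mt3-Mt2-Mt1: RJWN010001895	Mt1: RJWN010023894, RJWN010012658, NIPP01004159, NIPP01000460, RJWN010001847, NIPP01050325, RJWN010001516, NIPP01000414
Eubalaena japonica	Balaenidae	NC_006931	Mt4-Mt3-Mt2: RJWP010002310	Mt1: RJWP010029515, RJWP010014455, RJWP011049311, RJWP010044123, RJWP010003859, RJWP010517844, RJWP010045258
Globicephala melas	Delphinidae	NC_019441	Mt3-Mt2: SWEB01012070; Mt1-Mt1: SWEB01015162	Mt1: personal data	Mt1: personal data; Mt2: personal data; Mt3: personal data; Mt4: personal data	Mt4: XM_030847937
Inia geoffrensis	Iniidae	NC_005276	Mt4-Mt3-Mt2-Mt1: RJWO010009779	Mt1: RJWO010024955, RJWO010005555
Kogia breviceps	Kogiidae	NC_005272	Mt3-Mt2: RJWL010036575	Mt1: RJWL010001100	Mt1: RJWL010167408
Lagenorhynchus obliquidens	Delphinidae	NC_035426	Mt3-Mt2-Mt1: RCWK01007239	Mt1: RCWK01003005	Mt4: RCWK01007238	Mt1: XM_027119875, XM_027092179, XR_003432150, XR_003433512, XR_003429008; Mt2: XM_027119873; Mt4: XM_027119872
Lipotes vexillifer	Lipotidae	NC_007629	Mt4-Mt3: AUPI01085919; Mt4-Mt3-Mt2-Mt1-Mt1: NW_006786802; Mt2-Mt1-Mt1-Mt1: AUPI01085920	Mt1: AUPI01016291, AUPI01032811	Mt2: AUPI01085920	Mt1: XM_007450307, XM_007459446, XM_007459445, XM_007459251; Mt2: XM_007459444; Mt4: XM_007459443
Megaptera novaengliae	Balaenopteridae	NC_006927	Mt4-Mt3-Mt2-Mt1: RYZJ01000704	Mt1: RYZJ01002277
Mesoplodon bidens	Ziphiidae	NC_042218	Mt3-Mt2-Mt1: PVJJ010038290	Mt1: PVJJ010001248, PVJJ010035753, PVJJ010000716	Mt4: PVJJ010048532
Monodon monoceros	Monodontidae	NC_005279	Mt4-Mt3-Mt2-Mt1: SIHG01006952; Mt3-Mt2-Mt1: PVJE01024091, PVJF01025398	Mt1: PVJF01009326, PVJE01004367, SIHG01006957, RWIC01000029		Mt1: XM_029210741, XM_022566857, XR_003793663, XM_029213332, XM_029213320, XM_029213311, XR_003792376, XM_029243937; Mt2: XM_029210730; Mt4: XM_029207165
Neophocaena asiaeorientalis	Phocoenidae	NC_026456	Mt3-Mt2: MKKW01002943	Mt1: XR_003002470, MKKW01009685, MKKW01050072	Mt1: MKKW01002942, NW_020172079; Mt2, Mt4: NW_020172079	Mt1: XM_024751546, XM_024752871; Mt2: XM_024751535; Mt4: XM_024751560
Orcinus orca	Delphinidae	NC_023889	Mt3-Mt2: ANOL02076608; Mt1-Mt1: ANOL02076611; Mt4-Mt3-Mt2: NW_004438720	Mt1: ANOL02015359, ANOL02053476, ANOL02005809; Mt2: ANOL02033101	Mt4: ANOL02076604	Mt1: XR_001119644, XR_001120057, XM_004286377; Mt2: XM_004272467, XM_004286376; Mt3: XM_004286375; Mt4: XM_004286374
Phocoena phocoena	Phocoenidae	NC_005280	Mt3-Mt2-Mt1: RJWQ010020171; Mt2-Mt1: PKGA01134162	Mt1: RJWQ010000213, PKGA01141836, RJWQ010001208, PKGA01000712	Mt4: RJWQ010008745
Phocoena sinus	Phocoenidae	MZ772969	Mt4-Mt3-Mt2-Mt1: VOSU01000010
Physeter catodon	Physeteridae	KU891394	Mt3-Mt2: PGGR02120841; Mt1-Mt1-Mt1: PGGR02120842; Mt3-Mt2-Mt1: AWZP01019177; Mt3-Mt2: UEMC01002060	Mt1: AWZP01108577, AWZP01061491, UEMC01000019, PGGR02098163, AWZP01094651, AWZP01036149; Mt2: AWZP01013965	Mt2: personal data; Mt3: personal data	Mt1: XM_028487398, XM_028487397, XR_002892573, XM_024124849, XR_002890606, XR_002890985, XM_007111896, XM_007106395; Mt2: XR_002891953, XM_024124902, XR_002891953, XM_007104604
Platanista minor	Platanistidae	NC_005275	Mt1-Mt1: RJWK010077258	Mt1: RJWK010030898, RJWK010019970	Mt1: RJWK010077258; Mt2: RJWK010120550; Mt3: RJWK010071068; Mt4: RJWK010018570
Pontoporia blainvillei	Pontoporiidae	NC_005277	Mt2-Mt1: RJWI010022586	Mt1: RJWI010118407	Mt1: RJWI010124881; Mt3: RJWI010018702; Mt4: RJWI010009362
Sousa chinensis	Delphinidae	NC_012057	Mt4-Mt3-Mt2-Mt1: QWLN02017480	Mt1: QWLN02012546, QWLN02014060
Tursiops aduncus	Delphinidae	KF570360	Mt4-Mt3-Mt2-Mt1: NCQN01002597	Mt1: NCQN01000091, NCQN01000487
Tursiops truncatus	Delphinidae	EU557093	Mt4-Mt3-Mt2-Mt1: NW_004202941, QUXD02065780; Mt4-Mt3-Mt2: ABRN02426572	Mt1: ABRN02374863, ABRN02315981, ABRN02301451, QUXD02004646, QUXD02000953, QMGA01000002, MRVK01000157, QUXD02061382, QUXD02003404, QMGA01000469, MRVK01000730	Mt2: QUXD02065780, ABRN02426572	Mt1: XM_019951660, XR_002175011, XR_002178769, XR_002172975, XM_004322331; Mt2: XM_004331916, XM_004322332; Mt3: XM004322333; Mt4: XM004322334
Ziphius cavirostris	Ziphiidae	KC776698	Mt2-Mt1: RJWS010029178	Mt1: RJWS010650073, RJWS011128550, RJWS010020051	Mt3: RJWS010262321; Mt4: RJWS010091044
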
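species	igr_mt4_mt3	igr_mt3_mt2	igr_mt2_mt1a	igr_mt1a_mt1b	igr_mt1b_mt1c
Balaenoptera acutorostrata		7129
Balaenoptera bonaerensis		7137
Balaenoptera musculus	21933
Delphinapterus leucas		7173	5015
Eschrichtius robustus	21903	7521	4739	3141
Eubalaena japonica	22674	7171
Globicephala melas		7202		3068
Inia geoffrensis	19583	7232	5310	3084
Kogia breviceps		7195
Lagenorhynchus obliquidens		7184	5026
Lipotes vexillifer	20328	7897	5309	3214	3926
Megaptera novaengliae	±22163	7175	4740	3083
Mesoplodon bidens		7196	4994
Monodon monoceros	27526	7159	5005
Neophocaena asiaeorientalis		7201		3092
Orcinus orca	±36109	7194		3055
Phocoena phocoena		7198	5137	3091
Phocoena sinus	27958	7196	5090
Physeter catodon		7206	4448	2729	3088
Platanista minor			5083	3048
Pontoporia blainvillei			2064
Sousa chinensis	32782	7177	5016
Tursiops aduncus	±34939	7182	5027
Tursiops truncatus	23064	7186–7219	6269	3151
Ziphius cavirostris			4955
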
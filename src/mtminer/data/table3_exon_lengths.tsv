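species	mt1_exon1	mt1_exon2	mt1_exon3	mt2_exon1	mt2_exon2	mt2_exon3	mt3_exon1	mt3_exon2	mt3_exon3	mt4_exon1	mt4_exon2	mt4_exon3
Balaenoptera acutorostrata	28	66	92	28	66	92	31	66	107	31	66	92
Balaenoptera bonaerensis	28	66	92	28	66		31	66	107	31	66	92
Balaenoptera musculus	28	66	92	28	66	92	31	66	107	31	66	92
Delphinapterus leucas	28	66	92	28	66	92	31	66	107
Eschrichtius robustus	28	66	92	28	66	92	31	66	107	31	66	92
Eubalaena japonica				28	66		31	66	107	31	66	92
Globicephala melas	28	66	92	28	66	92	31	66	107	31	66	92
Inia geoffrensis	28	66	92	28	66	92	31	66	107	31	66	92
Kogia breviceps	28	66	92	28	81		31	66	107
Lagenorhynchus obliquidens	28	66	92	28	66	92	31	66	107	31	66	92
Lipotes vexillifer	28	66	92	28	66	92	31	66	107	31	66	92
Megaptera novaengliae	28	66	92	28	66	92	31	66	107	31	66	92
Mesoplodon bidens	28			28	66	92	31	66	104	31	66	92
Monodon monoceros	28	66	92	28	66	92	31	66	107	31	66	92
Neophocaena asiaeorientalis	28	66	92	28	66	92	31	66	107	31	66	92
Orcinus orca	28	66	92	28	66	92	31	66	107	31	66	92
Phocoena phocoena	28	66	92	28	66	92	31	66	107	31	66	92
Phocoena sinus	31	66	92	28	66	92	31	66	107	31	66	92
Physeter catodon	28	66	92	28	66	92	31	66	104
Platanista minor	28	66	92	28	66	92	31	66	107	31	66	92
Pontoporia blainvillei	28	66		28	66	92	31	66	107	31	66	92
Sousa chinensis	28	66	92	28	66	92	31	66	107	31	66	92
Tursiops aduncus	28	66	92	28	66	92	31	66	107	31	66	92
Tursiops truncatus	28	66	92	28	66	92	31	66	107	31	66	92
Ziphius cavirostris	28	66	92	28		92	31	66	104	31	66	92
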
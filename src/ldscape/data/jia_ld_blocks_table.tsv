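chrom	start	end	snps	neutrophil_h3k4me1	neutrophil_h3k27ac	cd4_h3k4me1	cd4_h3k27ac
chr1	206940310	206947167	rs1800896	Y	N	Y	Y
chr1	25197155	25203390	rs4648881	Y	N	Y	N
chr11	36336263	36371757	rs4755450,rs7127214	N	N	N	N
chr12	111884608	111932800	rs3184504	Y	Y	Y	Y
chr12	112486818	112906415	rs17696736	Y	Y	Y	Y
chr13	40299842	40368601	rs7993214,rs9532434	N	N	Y	N
chr13	43056036	43066523	rs34132030	N	N	N	N
chr16	11400900	11435990	rs66718203	Y	Y	Y	N
chr18	12821903	12880206	rs7234029	Y	Y	Y	Y
chr2	100806514	100837567	rs10194635,rs6740838,rs1160542	Y	N	Y	Y
chr2	191900449	191935804	rs3821236	Y	Y	Y	Y
chr2	191943742	191970120	rs7574865	N	N	Y	N
chr22	24234493	24237862	rs755622	Y	Y	Y	Y
chr3	119125202	119243934	rs4688013,rs4688011	Y	Y	Y	Y
chr3	46253650	46350716	rs79893749	Y	Y	Y	Y
chr4	123141054	123548068	rs17388568	Y	Y	Y	Y
chr6	112359543	112448654	rs2280153	Y	Y	Y	Y
chr6	137959235	138006504	rs6920220	N	N	Y	N
chr6	31492453	31543031	rs1800629	N	Y	Y	Y
chr7	22774437	22811384	rs6946509,rs7808122	N	N	N	N
chr7	28152193	28243473	rs10280937,rs73300638	Y	Y	Y	Y
chr9	123636121	123723351	rs10818488	Y	Y	Y	Y
chr9	123640500	123706382	rs2900180	Y	Y	Y	Y
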
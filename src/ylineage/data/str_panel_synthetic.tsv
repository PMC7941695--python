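# Synthetic Y-STR locus table: standard locus names and motif compositions
# with SYNTHETIC coordinates (not genome-derived); for testing and examples.
name	start_hg19	end_hg19	start_hg38	end_hg38	motifs	named
DYS19	2650001	2650060	2651001	2651060	TAGA:15	1
DYS385a	2660001	2660044	2661001	2661044	GAAA:11	1
DYS385b	2670001	2670056	2671001	2671056	GAAA:14	1
DYS389I	2680001	2680048	2681001	2681048	TCTG:3,TCTA:9	1
DYS389II	2690001	2690068	2691001	2691068	TCTG:5,TCTA:12	1
DYS390	2700001	2700096	2701001	2701096	TCTG:8,TCTA:16	1
DYS391	2710001	2710040	2711001	2711040	TCTA:10	1
DYS392	2720001	2720039	2721001	2721039	TAT:13	1
DYS393	2730001	2730052	2731001	2731052	AGAT:13	1
DYS437	2740001	2740056	2741001	2741056	TCTA:9,TCTG:5	1
DYS438	2750001	2750050	2751001	2751050	TTTTC:10	1
DYS439	2760001	2760048	2761001	2761048	AGAT:12	1
DYS448	2770001	2770114	2771001	2771114	AGAGAT:19	1
DYS456	2780001	2780060	2781001	2781060	AGAT:15	1
DYS458	2790001	2790068	2791001	2791068	GAAA:17	1
DYS635	2800001	2800084	2801001	2801084	AGGA:2,AGAT:19	1
YGATAH4	2810001	2810048	2811001	2811048	TAGA:12	1
DYS481	2820001	2820066	2821001	2821066	CTT:22	1
DYS533	2830001	2830048	2831001	2831048	ATCT:12	1
DYS549	2840001	2840048	2841001	2841048	GATA:12	1
DYS570	2850001	2850068	2851001	2851068	TTTC:17	1
DYS576	2860001	2860072	2861001	2861072	AAAG:18	1
DYS643	2870001	2870050	2871001	2871050	CTTTT:10	1
DYS388	2880001	2880036	2881001	2881036	ATT:12	1
DYS426	2890001	2890033	2891001	2891033	GTT:11	1
DYS460	2900001	2900040	2901001	2901040	ATAG:10	1
DYS461	2910001	2910048	2911001	2911048	TAGA:12	1
Y-STR-U1	2920001	2920018	2921001	2921018	AAT:6	0
Y-STR-U2	2930001	2930020	2931001	2931020	ACGT:5	0
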
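# SYNTHETIC Y-STR allele frequency reference for Bayesian haplogroup
# prediction: hand-built toy counts, not derived from any published data set.
# Schema for user references: haplogroup, locus, allele (repeat number), count.
haplogroup	locus	allele	count
O2	DYS19	15	40
O2	DYS19	16	10
O2	DYS391	10	45
O2	DYS391	11	5
O2	DYS393	12	30
O2	DYS393	13	20
R1a	DYS19	16	35
R1a	DYS19	17	15
R1a	DYS391	11	40
R1a	DYS391	10	10
R1a	DYS393	13	35
R1a	DYS393	14	15
E1b	DYS19	13	30
E1b	DYS19	14	20
E1b	DYS391	9	25
E1b	DYS391	10	25
E1b	DYS393	13	25
E1b	DYS393	14	25
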
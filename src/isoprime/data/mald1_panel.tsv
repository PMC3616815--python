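gene_id	primer_name_f	seq_f	snp_cons_f	snp_gene_f	snp_allele_f	primer_name_r	seq_r	snp_cons_r	snp_gene_r	snp_allele_r	start	amplicon_length	primer_conc	ta	tm_amplicon	dct_slope
Mal d 1.01	qMd1.01/02F	GATTGAAGGAGATGCTTTGACA	5	0	0	qMd1.01R	GTAATGACTGATGCTCTTGATGG	0	1	1	258	103	100	63	80.5	-0.079
Mal d 1.02	qMd1.01/02F	GATTGAAGGAGATGCTTTGACA	4	0	0	qMd1.02R	TTGGTGTGGTAGTGGCTGATA	1	1	0	258	111	100	62	81.0	-0.206
Mal d 1.03A	qMd1.03AF	ATCTGAGTTCACCTCCGTCATT	1	2	0	qMd1.03AR	ACTGCTTGTGGTGGAATCTTT	0	1	1	21	96	70	63	81.0	-0.057
Mal d 1.03B	qMd1.03BF	TGTTTTCACATACGAATCCGAA	1	1	0	qMd1.03BR	TGATCTTCTTAATGGTTCCTACGC	1	1	1	6	167	100	63	83.5	-0.570
Mal d 1.03C	qMd1.03CF	CTCCGAAACAATTGAGAAAATCTG	3	0	1	qMd1.03CR	GCTGGTGCTCTTGATGATGC	1	1	0	276	79	100	63	80.5	-0.120
Mal d 1.03D	qMd1.03D/EF	ATACGAATCCGAGTTCACCTCT	1	0	0	qMd1.03DR	ATCTTCTTAATGGTTCCAACTCCT	1	1	0	15	156	70	62	83.0	0.005
Mal d 1.03E	qMd1.03D/EF	ATACGAATCCGAGTTCACCTCT	1	0	2	qMd1.03ER	TTCACCGAAGTTGATCTTCTTAATA	1	1	0	15	169	70	62	83.0	-0.116
Mal d 1.03F	qMd1.03FF	CACAGAATTGACGGGGTG	2	2	0	qMd1.03FR	CCGGAAGCGACCAACTTA	2	1	1	208	119	70	63	81.0	-0.122
Mal d 1.03G	qMd1.03GF	ATTATCAAGAGCACCAGTCACTACT	2	2	0	qMd1.03GR	TCCAAGAGGTAGTTCTCAATCAA	1	0	0	337	122	70	62	81.0	-0.254
Mal d 1.03H	qMd1.03HF	AAAATCTGCTACGAGACTAAGTTGA	3	2	0	qMd1.03HR	TGGTGCTCCAAGAGGTAGTTT	1	1	0	277	173	100	61	83.5	-0.431
Mal d 1.03I	qMd1.03IF	CCCCAAGATTGCACCACAT	0	1	0	qMd1.03IR	GCCACCAACTTAGTCTCGTAACAA	2	1	0	93	228	100	61	81.5	-0.230
Mal d 1.03J	qMd1.03JF	GCATCACCCACTACCACACA	2	1	0	qMd1.03JR	CGAGCTGTAGGAGTCTTGGTT	3	3	0	347	134	70	61	82.0	-0.105
Mal d 1.03K	qMd1.03KF	CATCAGCCACTACCACACAAA	2	1	0	qMd1.03KR	TGTATGCATCCTGGTGCTCT	2	1	1	348	128	100	61	81.5	-0.431
Mal d 1.04	qMd1.04F	GGGTATGTTAAGCAAAGGGTCA	5	2	0	qMd1.04R	TGATCTCAACATCACCCTTAGC	1	1	0	196	193	100	61	80.5	-0.103
Mal d 1.05	qMd1.05F	ATCAAACCACTAGTCACTGCCAT	4	1	1	qMd1.05R	GGTTGGCCACAAGGTAGGTT	6	1	0	343	124	70	63	82.5	-0.141
Mal d 1.06A	qMd1.06AF	CTATAGCTATAGCTTGATTGAAGGG	5	1	0	qMd1.06AR	TTCCAACCTTAACATGTTCTTCT	3	0	1	243	167	100	61	80.5	-0.203
Mal d 1.06B	qMd1.06BF	AAACCGAATACGCATCCATT	3	3	1	qMd1.06BR	ACAGTTTTGACTGCTTGTGGAG	6	0	0	20	106	100	61	81.5	-0.012
Mal d 1.06C	qMald1.06CF	GCTCCACAAGCAGTCAAAACT	5	0	0	qMald1.06CR	TCAACCTTGTGCTTCACATAACTA	3	2	0	103	116	70	63	80.5	-0.250
Mal d 1.06D	qMd1.06DF	CCCTCCTGCTAGGTTGTATT	2	2	0	qMd1.06DR	TCCCTCGAGAATTTCAACAG	6	0	0	42	100	70	61	80.5	-0.005
Mal d 1.07	qMd1.07F	CAACTTTGTGTACCAGTACAGTGTC	2	2	0	qMd1.07R	TAGTGGCTGATGCTCTTGATAAC	2	1	0	234	126	100	61	81.5	-0.201
Mal d 1.08	qMd1.08F	TCTTCGGTGAAGGTAGCACAA	0	2	0	qMd1.08R	ACCCTTAGTGTGGTAGTGGCAT	1	2	0	173	200	100	61	81.5	-0.390
Mal d 1.09	qMd1.09F	TTTTCACATACGAATCCGAGTC	0	1	0	qMd1.09R	GGATCTCAACGCTCTTCACA	2	1	0	8	126	100	61	84.0	-0.265
Mal d 1.10.	qMald1.10F	CAAGGCTTTCATCCACGAC	5	2	1	qMald1.10R	GATTCTGTGCTTTACAAACCCT	4	3	0	60	157	100	61	83.0	-0.158
Mal d 1.11A	qMald1.11AF	GGAGGATGCATCTGTCATTTG	11	1	0	qMald1.11AR	CCATGAGATAGGCTTCCAAAACT	8	2	0	343	130	100	62	79.5	-0.018
Mal d 1.11B	qMd1.11BF	CAGCACATACAAAGCCAAAGAC	8	1	0	qMd1.11BR	TTTATGCGCGAGGGTGTG	6	1	0	363	125	100	61	81.0	-0.106
Mal d 1.12	qMd1.12F	GCTTACACTTTGGTTGAAGGAGAAC	4	3	0	qMd1.12R	CCTGCCAGCTTTTATTTCTTCC	5	4	0	247	171	100	62	76.0	-0.227
Mal d 1.13A	qMd1.13AF	GTGTTGGAACCATCAAGAAGATTAG	2	2	0	qMd1.13AR	ACATCTCCTTCAATCAAACTGTAAT	1	1	0	149	124	100	61	78.0	-0.216
Mal d 1.13B	qMd1.13BF	CGAAGATAACTTTGTCTACAACCAT	2	1	0	qMd1.13BR	GCTCTTCCTTGATCTCAACATCTT	1	1	0	258	137	70	61	81.5	0.003
Mal d 1.13C	qMd1.13CF	GAATTCGCCTCAGTCTCCA	5	1	0	qMd1.13CR	GTGCTTCACATAGCTGTATTCACTT	3	1	0	25	186	70	61	82.0	0.087
Mal d 1.13D	qMd1.13DF	TGTTGGAACCATCAAGAAGATAAGT	2	1	0	qMd1.13DR	GACATCTCCTTCAATCAAACTGTAG	2	1	0	150	124	100	61	78.5	-0.163
Mal d 1.14	qMd1.14F	GGTGAAGGGAGTGAATACAACTATA	6	1	0	qMd1.14R	TGGTAATGGCTAATGTTCTTGATAC	2	2	2	178	185	100	61	79.0	-0.470
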
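chrom	start_bp	end_bp	length_cM	ratio
chr9	38293483	72605261	8.15	39
chr8	10428647	13469693	7.96	38
chr21	16344186	19375168	6.91	22
chr10	44555093	53240188	7.58	22
chr22	16051881	25095451	20.82	22
chr2	85304243	99558013	6.53	21
chr1	118434520	153401108	9.95	19
chr15	20060673	25145260	10.46	15
chr17	77186666	78417478	5.66	11
chr15	27115823	30295750	9.29	9
chr17	59518083	64970531	6.23	9
chr2	132695025	141442636	9.16	7
chr16	19393068	24031556	6.18	6
chr2	192352906	198110229	5.04	4
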
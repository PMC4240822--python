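gene	chrom	strand	exons	cds_start_cdna	cds_seq
CRYGD	chr2	+	208988800-208988835;208988985-208989113;208989300-208989659	1	ATGCTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAACCATCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTAA
GJA8	chr1	+	147379500-147379649;147380083-147381384	151	ATGCTTAAAGGTTCCATCCTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCATACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAAGGTTCCATCGTGCCGACAGCTGAACTTAAATAA
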
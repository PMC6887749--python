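motif_id	consensus	evalue	sites	width
1	VRGVSGGERKRVSIGNEJIINPSJLFLDEPTSGLDSTTALR	4.9 x 10^-1822	60	41
2	GFVTQDDVLFPHLTVEETLVFAALLRLPKTLSKEQKEKRVEEVISELGLE	1.1 x 10^-1875	60	50
3	EKTJLNGITGSVRPGEILALLGPSGSGKTTLLBALAGRLTQ	1.2 x 10^-1524	60	41
4	GKTVVTSIHQPSSRLFHLFDKLJLLSKGSLLYFGKASEAMV	1.5 x 10^-1397	60	41
5	WGFYPCFTALFTFPQERAMLTKERAAGMY	8.3 x 10^-1056	59	29
6	VKKIPVFIIWIRYLSFVYYTYRLLLKVQY	3.2 x 10^-924	58	29
7	WWZQFSILFQRGJKERRHEYFNWLRITQV	3.9 x 10^-814	41	29
8	QGLGLAIGATLMDLKRATTLASVTVLTFM	4.9 x 10^-674	46	29
9	RLSAYFLARTVVDLPLDLILPVAFLVITYWMAGLRPSAETF	2.3 x 10^-1088	58	41
10	GCSPLISMNPAEFLLDLANGN	5.6 x 10^-528	54	21
11	NGKPSPAVVHEYLVEAYETRVADEEKKKJMVPLPLDDELKLKVSISKREW	4.1 x 10^-705	21	50
12	KVSGSITYNGQTYSKFVKRRT	2.1 x 10^-485	59	21
13	ALJLGLLWWQSDSNN	1.9 x 10^-350	58	15
14	NNBPSPNSMVPTFANPFWIEMAVLAKRSMKNARRMPELFGI	3.9 x 10^-318	15	41
15	FGYRLLAYLALRRMK	5.3 x 10^-276	54	15
16	KPKFQTLPTLPJTLKFTDVTYKVILKGMR	1.8 x 10^-520	48	29
17	DEVPSGMALSRASSASLAFSFLFSGFTIP	4.9 x 10^-498	40	29
18	SSRELFRASPSRESLLMKRNSFIYKFKSAQL	1.0 x 10^-390	26	31
19	TGRTIVCTIHQPNIDIFEAFDELJLLKTGGRIIYSGPLGQHSSRVIEYFZ	2.9 x 10^-479	14	50
20	GISGGQKKRLTTAEMJIGPTKALFMDEITNGLDSSTAFQIVNSLQQLVHI	5.0 x 10^-469	14	50
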
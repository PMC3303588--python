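Gene name	Link	Link in background	Links to seed	Links in subnetwork	z-score
HLA-DQA2	3	11429	2	60	15.852
DARC	4	11429	2	60	13.692
LCK	67	11429	6	60	9.548
PRTN3	9	11429	2	60	9.007
APCS	10	11429	2	60	8.522
FN1	62	11429	5	60	8.215
IGFBP7	11	11429	2	60	8.103
PTPN13	12	11429	2	60	7.737
CASP1	18	11429	2	60	6.215
A2M	24	11429	2	60	5.293
DCN	25	11429	2	60	5.171
NCL	30	11429	2	60	4.655
C3	31	11429	2	60	4.566
JAK2	116	11429	4	60	4.356
PTPRC	35	11429	2	60	4.248
THBS1	37	11429	2	60	4.108
ARRB1	44	11429	2	60	3.690
TRADD	63	11429	2	60	2.910
PIK3R1	133	11429	3	60	2.761
FYN	153	11429	3	60	2.457
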
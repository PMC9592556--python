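res	N	H	CA	CB	C	HA
ALA	123.8	8.24	52.5	19.1	177.8	4.32
ARG	120.5	8.23	56.0	30.9	176.3	4.34
ASN	118.7	8.40	52.8	38.9	175.2	4.74
ASP	120.4	8.34	54.2	41.1	176.3	4.64
CYS	118.8	8.32	58.2	28.0	174.6	4.55
GLN	119.8	8.32	55.7	29.4	176.0	4.34
GLU	120.2	8.42	56.6	29.9	176.6	4.35
GLY	108.8	8.33	45.1	.	174.9	3.96
HIS	118.2	8.42	55.0	29.0	174.1	4.73
ILE	119.9	8.00	61.1	38.8	176.4	4.17
LEU	121.8	8.16	55.1	42.4	177.6	4.38
LYS	120.4	8.29	56.2	33.1	176.6	4.32
MET	119.6	8.28	55.4	32.9	176.3	4.48
PHE	120.3	8.30	57.7	39.6	175.8	4.62
PRO	135.0	.	63.3	31.7	177.3	4.42
SER	115.7	8.31	58.3	63.8	174.6	4.47
THR	113.6	8.15	61.8	69.8	174.7	4.35
TRP	121.3	8.25	57.5	29.6	176.1	4.66
TYR	120.3	8.12	57.9	38.8	175.9	4.55
VAL	119.2	8.03	62.2	32.9	176.3	4.12
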
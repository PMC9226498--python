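aa	CA	CB	C	H	N	HA
A	52.5	19.1	177.8	8.24	123.8	4.32
R	56.0	30.9	176.3	8.23	120.5	4.34
N	52.8	37.9	175.2	8.40	118.7	4.74
D	54.2	41.1	176.3	8.34	120.4	4.64
C	58.2	28.0	174.6	8.32	118.8	4.55
Q	56.6	29.4	176.0	8.32	119.8	4.34
E	56.6	29.9	176.6	8.42	120.2	4.35
G	45.1	NA	174.9	8.33	108.8	3.96
H	55.0	29.0	174.1	8.42	118.2	4.73
I	61.1	38.8	176.4	8.00	119.9	4.17
L	55.1	42.4	177.6	8.16	121.8	4.32
K	56.2	33.1	176.6	8.29	120.4	4.32
M	55.4	32.9	176.3	8.28	119.6	4.48
F	57.7	39.6	175.8	8.30	120.3	4.62
P	63.3	31.7	177.3	NA	NA	4.42
S	58.3	63.8	174.6	8.31	115.7	4.47
T	61.8	69.8	174.7	8.15	113.6	4.35
W	57.5	29.6	176.1	8.25	121.3	4.66
Y	57.9	38.8	175.9	8.12	120.3	4.55
V	62.2	32.9	176.3	8.03	119.2	4.12
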
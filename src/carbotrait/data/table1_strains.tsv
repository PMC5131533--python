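strain	branch	origin	starter
S28	A	France red wine	1
S23	A	England white wine	0
S11	A	France white wine	0
AWRI_B429	A	Italy	1
CiNe	A	NA	1
IOEB_0608	A	France red wine	0
IOEB_9517	A	France	0
IOEB_L65.2	A	Lebanon red wine	0
AWRI_B419	A	France	1
VF	A	France	1
IOEB_S436	A	NA	1
S15	A	France red wine	0
S161	A	red wine	0
IOEB_S277	A	France	1
IOEB_L18.3	A	Lebanon red wine	0
IOEB_B10	A	NA	0
S19	A	France red wine	0
IOEB_1491	A	France red wine	0
AWRI_B129	A	France	0
IOEB_L40.4	A	Lebanon red wine	0
IOEB_S450	A	France	1
PSU-1	A	USA red wine	1
S14	A	France red wine	0
B16	A	France Champagne	1
IOEB_0205	A	France Champagne	0
AWRI_B548	A	France Champagne	1
IOEB_0607	A	France red wine	0
S25	A	France	0
IOEB_L26.1	A	Lebanon red wine	0
S13	B	France red wine	0
S12	B	France white wine	0
IOEB_0501	B	France red wine	0
IOEB_0502	B	France red wine	0
ATCC_BAA-1163	B	France red wine	0
IOEB_9803	B	France	0
IOEB_9805	B	France	0
IOEB_8417	B	France	0
IOEB_9304	B	France cider	0
IOEB_C28	B	France cider	0
IOEB_C23	B	France cider	0
IOEB_C52	C	France cider	0
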
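strain	ptsEI	treP	treC	treC1	malA
S28	I	I	I	I	P
S23	I	I	I	I	P
S11	I	I	I	I	P
AWRI_B429	I	I	I	I	P
CiNe	I	I	I	I	P
IOEB_0608	I	I	I	I	P
IOEB_9517	I	I	I	I	P
IOEB_L65.2	I	I	I	I	P
AWRI_B419	I	I	P	I	P
VF	I	I	I	I	P
IOEB_S436	I	I	I	I	P
S15	I	I	I	I	P
S161	I	I	I	I	P
IOEB_S277	I	I	I	I	P
IOEB_L18.3	I	I	I	I	P
IOEB_B10	I	I	I	I	P
S19	I	I	I	I	P
IOEB_1491	I	I	I	I	P
AWRI_B129	I	I	I	I	P
IOEB_L40.4	I	I	I	I	P
IOEB_S450	I	I	I	I	P
PSU-1	I	I	I	I	P
S14	I	I	I	I	P
B16	I	I	I	I	P
IOEB_0205	I	I	I	I	P
AWRI_B548	I	I	I	I	P
IOEB_0607	S	I	I	I	P
S25	I	I	I	I	P
IOEB_L26.1	I	I	I	I	P
S13	I	I	P	I	I
S12	I	I	I	I	I
IOEB_0501	I	I	I	I	I
IOEB_0502	I	I	I	I	P
ATCC_BAA-1163	I	I	P	I	P
IOEB_9803	I	I	I	I	I
IOEB_9805	I	I	I	I	I
IOEB_8417	I	I	I	I	P
IOEB_9304	I	I	I	I	I
IOEB_C28	I	I	I	I	P
IOEB_C23	I	I	I	I	I
IOEB_C52	I	I	I	I	I
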
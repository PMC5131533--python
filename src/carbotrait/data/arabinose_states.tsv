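strain	araA	araB	araD	araD1	araC	araT	epi
S28	I	I	I	A	P	I	I
S23	I	I	I	A	I	I	P
S11	I	I	I	A	I	I	P
AWRI_B429	P	I	I	A	I	I	I
CiNe	I	I	I	A	I	I	I
IOEB_0608	I	I	I	A	I	I	I
IOEB_9517	I	I	I	A	I	I	I
IOEB_L65.2	I	I	I	A	I	I	I
AWRI_B419	I	I	P	I	I	I	I
VF	I	I	I	A	I	I	I
IOEB_S436	I	I	I	A	I	I	I
S15	I	I	I	A	I	I	P
S161	I	I	I	A	I	I	I
IOEB_S277	I	I	I	A	I	I	I
IOEB_L18.3	I	I	I	A	I	I	I
IOEB_B10	I	I	I	A	I	I	I
S19	I	I	I	A	I	I	I
IOEB_1491	I	I	I	A	I	I	I
AWRI_B129	I	I	I	A	I	I	I
IOEB_L40.4	I	I	I	A	I	I	P
IOEB_S450	I	P	I	A	I	I	I
PSU-1	I	I	I	A	I	I	I
S14	I	I	I	A	I	I	I
B16	I	I	I	A	I	I	I
IOEB_0205	I	I	I	A	I	I	I
AWRI_B548	I	I	I	A	I	I	I
IOEB_0607	I	I	P	A	I	I	I
S25	I	I	I	A	I	I	I
IOEB_L26.1	I	I	I	A	I	I	I
S13	I	I	I	A	I	I	P
S12	I	I	I	A	I	I	I
IOEB_0501	I	I	I	A	P	I	I
IOEB_0502	I	I	I	A	I	I	I
ATCC_BAA-1163	P	P	I	A	I	I	I
IOEB_9803	I	I	I	A	I	I	I
IOEB_9805	I	I	I	A	P	I	I
IOEB_8417	I	I	I	A	I	I	I
IOEB_9304	I	I	I	A	I	A	I
IOEB_C28	I	I	I	A	I	A	I
IOEB_C23	I	I	I	A	I	I	I
IOEB_C52	I	I	I	A	I	A	I
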
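strain	ribT	mfs9C23
S28	I	A
S23	I	A
S11	I	A
AWRI_B429	I	A
CiNe	I	A
IOEB_0608	I	A
IOEB_9517	I	A
IOEB_L65.2	I	A
AWRI_B419	I	A
VF	I	A
IOEB_S436	I	A
S15	I	A
S161	I	A
IOEB_S277	I	A
IOEB_L18.3	I	A
IOEB_B10	P	A
S19	P	A
IOEB_1491	P	A
AWRI_B129	I	A
IOEB_L40.4	I	A
IOEB_S450	I	A
PSU-1	I	A
S14	I	A
B16	I	A
IOEB_0205	I	A
AWRI_B548	I	A
IOEB_0607	I	A
S25	P	A
IOEB_L26.1	I	A
S13	I	A
S12	I	A
IOEB_0501	I	A
IOEB_0502	I	A
ATCC_BAA-1163	I	A
IOEB_9803	I	A
IOEB_9805	I	A
IOEB_8417	I	A
IOEB_9304	I	A
IOEB_C28	I	A
IOEB_C23	A	I
IOEB_C52	I	A
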
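strain	malA	malE
S28	P	I
S23	P	I
S11	P	I
AWRI_B429	P	I
CiNe	P	I
IOEB_0608	P	I
IOEB_9517	P	I
IOEB_L65.2	P	I
AWRI_B419	P	I
VF	P	I
IOEB_S436	P	I
S15	P	I
S161	P	I
IOEB_S277	P	I
IOEB_L18.3	P	I
IOEB_B10	P	I
S19	P	I
IOEB_1491	P	I
AWRI_B129	P	I
IOEB_L40.4	P	I
IOEB_S450	P	I
PSU-1	P	I
S14	P	I
B16	P	I
IOEB_0205	P	I
AWRI_B548	P	I
IOEB_0607	P	I
S25	P	I
IOEB_L26.1	P	I
S13	I	I
S12	I	I
IOEB_0501	I	I
IOEB_0502	P	I
ATCC_BAA-1163	P	I
IOEB_9803	I	I
IOEB_9805	I	I
IOEB_8417	P	I
IOEB_9304	I	I
IOEB_C28	P	I
IOEB_C23	I	I
IOEB_C52	I	I
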
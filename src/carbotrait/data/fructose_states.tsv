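strain	manC	fruA	fruB	fruC	fruD
S28	P	A	A	A	A
S23	P	A	A	A	A
S11	P	A	A	A	A
AWRI_B429	P	A	A	A	A
CiNe	P	A	A	A	A
IOEB_0608	P	A	A	A	A
IOEB_9517	P	A	A	A	A
IOEB_L65.2	P	A	A	A	A
AWRI_B419	P	A	A	A	A
VF	P	A	A	A	A
IOEB_S436	P	A	A	A	A
S15	P	A	A	A	A
S161	P	A	A	A	A
IOEB_S277	P	A	A	A	A
IOEB_L18.3	P	A	A	A	A
IOEB_B10	I	A	A	A	A
S19	P	I	A	A	A
IOEB_1491	P	I	A	A	A
AWRI_B129	P	A	A	A	A
IOEB_L40.4	P	A	A	A	A
IOEB_S450	P	A	A	A	A
PSU-1	P	A	A	A	A
S14	P	A	A	A	A
B16	P	A	A	A	A
IOEB_0205	P	A	A	A	A
AWRI_B548	P	A	A	A	A
IOEB_0607	P	A	A	A	A
S25	P	A	A	A	A
IOEB_L26.1	P	A	A	A	A
S13	I	A	A	A	A
S12	I	I	A	A	A
IOEB_0501	I	A	A	A	A
IOEB_0502	I	A	A	A	A
ATCC_BAA-1163	P	I	A	A	A
IOEB_9803	I	A	A	A	A
IOEB_9805	I	A	A	A	A
IOEB_8417	I	A	A	A	A
IOEB_9304	I	A	A	A	A
IOEB_C28	I	A	A	A	A
IOEB_C23	P	I	A	A	A
IOEB_C52	P	I	A	A	A
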
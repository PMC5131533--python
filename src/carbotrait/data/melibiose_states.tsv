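strain	galA
S28	P
S23	P
S11	I
AWRI_B429	P
CiNe	I
IOEB_0608	I
IOEB_9517	P
IOEB_L65.2	P
AWRI_B419	I
VF	I
IOEB_S436	I
S15	I
S161	I
IOEB_S277	I
IOEB_L18.3	I
IOEB_B10	I
S19	I
IOEB_1491	I
AWRI_B129	I
IOEB_L40.4	I
IOEB_S450	I
PSU-1	I
S14	P
B16	P
IOEB_0205	P
AWRI_B548	P
IOEB_0607	P
S25	P
IOEB_L26.1	P
S13	I
S12	I
IOEB_0501	I
IOEB_0502	I
ATCC_BAA-1163	I
IOEB_9803	I
IOEB_9805	I
IOEB_8417	I
IOEB_9304	I
IOEB_C28	I
IOEB_C23	I
IOEB_C52	I
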
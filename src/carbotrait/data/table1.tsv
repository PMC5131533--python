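strain	glucose	trehalose	cellobiose	ribose	mannose	melibiose	arabinose	fructose	sucrose	maltose	galactose	xylose	raffinose	lactose	sorbose	rhamnose	sorbitol	mannitol
S28	1	1	1	1	1		1											
S23	1	1	1	1	1		1											
S11	1	1	1	1	1	1	1	1										
AWRI_B429	1	1	1	1	1													
CiNe	1	1	1	1	1	1												
IOEB_0608	1	1	1	1	1	1												
IOEB_9517	1	1	1	1	1													
IOEB_L65.2	1	1	1	1	1													
AWRI_B419	1	1	1	1	1	1	1											
VF	1	1	1	1	1	1	1											
IOEB_S436	1	1	1	1	1	1	1											
S15	1	1	1	1	1	1	1				1							
S161	1	1	1	1	1	1	1						1					
IOEB_S277	1	1	1	1	1	1	1											
IOEB_L18.3	1	1	1	1	1	1												
IOEB_B10	1	1	1		1	1		1										
S19	1	1	1		1	1		1										
IOEB_1491	1	1	1		1	1		1										
AWRI_B129	1	1	1	1	1	1		1										
IOEB_L40.4	1	1	1	1	1	1	1	1										
IOEB_S450	1	1	1	1	1	1												
PSU-1	1	1	1	1	1	1	1	1										
S14	1	1	1	1	1		1											
B16	1	1	1	1														
IOEB_0205	1	1	1	1														
AWRI_B548	1	1	1	1														
IOEB_0607	1		1	1		1												
S25	1	1	1			1												
IOEB_L26.1	1	1	1	1	1	1						1						
S13	1	1		1	1	1	1	1										
S12	1	1		1	1	1	1	1	1	1								
IOEB_0501	1	1	1	1	1	1	1	1	1	1	1		1					
IOEB_0502	1	1	1	1	1	1	1	1	1	1	1	1						
ATCC_BAA-1163	1	1	1	1	1	1		1	1									
IOEB_9803	1	1	1	1	1	1	1	1		1	1							
IOEB_9805	1	1	1	1	1	1	1	1	1	1								
IOEB_8417	1	1	1	1	1	1	1	1	1									
IOEB_9304	1	1	1	1	1	1	1	1		1								
IOEB_C28	1	1	1	1	1	1	1	1	1									
IOEB_C23	1	1	1	1	1	1	1	1	1	1								
IOEB_C52	1	1	1	1	1	1	1	1	1	1		1						
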
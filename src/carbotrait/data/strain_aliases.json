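{
 "ATCC BAA-1163": "ATCC_BAA-1163",
 "ATCC_BAA1163": "ATCC_BAA-1163",
 "AWRIB-429": "AWRI_B429",
 "AWRIB_129": "AWRI_B129",
 "AWRIB_419": "AWRI_B419",
 "AWRIB_429": "AWRI_B429",
 "AWRIB_548": "AWRI_B548",
 "B10": "IOEB_B10",
 "C23": "IOEB_C23",
 "C28": "IOEB_C28",
 "C52": "IOEB_C52",
 "CINE": "CiNe",
 "Cine": "CiNe",
 "IOEB 0501": "IOEB_0501",
 "IOEB 9803": "IOEB_9803",
 "IOEB_40.4": "IOEB_L40.4",
 "IOEB_L18_3": "IOEB_L18.3",
 "IOEB_L26-1": "IOEB_L26.1",
 "IOEB_L26_1": "IOEB_L26.1",
 "IOEB_L40_4": "IOEB_L40.4",
 "IOEB_L65_2": "IOEB_L65.2",
 "IOEB_S436a": "IOEB_S436",
 "PSU1": "PSU-1",
 "PSU_1": "PSU-1",
 "S450": "IOEB_S450"
}
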
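{
 "sugar": "fructose",
 "name": "PTS-mannose permease ManC (fructose-6-P route) or any pts-fru operon (fructose-1-P route)",
 "routes": [
  [
   [
    "manC"
   ]
  ],
  [
   [
    "fruA",
    "fruB",
    "fruC",
    "fruD"
   ]
  ]
 ]
}
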
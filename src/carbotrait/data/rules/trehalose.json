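{
 "sugar": "trehalose",
 "name": "PTS uptake plus phosphotrehalase, with treC1 complementation",
 "routes": [
  [
   [
    "ptsEI"
   ],
   [
    "treP"
   ],
   [
    "treC",
    "treC1"
   ]
  ]
 ]
}
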
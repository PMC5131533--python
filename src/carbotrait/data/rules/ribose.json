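{
 "sugar": "ribose",
 "name": "ribose permease ribT, or the strain-specific mfs9C23 permease",
 "routes": [
  [
   [
    "ribT"
   ]
  ],
  [
   [
    "mfs9C23"
   ]
  ]
 ]
}
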
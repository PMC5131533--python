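{
 "sugar": "maltose",
 "name": "maltose phosphorylase MalA plus the malEFG ABC transporter",
 "routes": [
  [
   [
    "malA"
   ],
   [
    "malE"
   ]
  ]
 ]
}
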
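{
 "sugar": "arabinose",
 "name": "arabinose isomerase/ribulokinase/ribulose-5-P-4-isomerase triad with araD1 complementation",
 "routes": [
  [
   [
    "araA"
   ],
   [
    "araB"
   ],
   [
    "araD",
    "araD1"
   ]
  ]
 ]
}
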
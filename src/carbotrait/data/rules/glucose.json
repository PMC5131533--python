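{
 "sugar": "glucose",
 "name": "PTS-mannose uptake, or MFS permease plus hexokinase (illustrative: no negative strain exists to test it)",
 "routes": [
  [
   [
    "manA",
    "manB",
    "manC"
   ]
  ],
  [
   [
    "mfs0136",
    "mfs0819",
    "mfs1574"
   ],
   [
    "nagC",
    "nagC1",
    "nagC2"
   ]
  ]
 ]
}
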
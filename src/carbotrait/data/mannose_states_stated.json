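{
 "note": "manB carries a singular IIC-subunit mutation in the five mannose-negative strains; manI is conserved in all strains.",
 "stated_cells": [
  [
   "ATCC_BAA-1163",
   "manA"
  ],
  [
   "AWRI_B548",
   "manB"
  ],
  [
   "B16",
   "manB"
  ],
  [
   "IOEB_0205",
   "manB"
  ],
  [
   "IOEB_0607",
   "manB"
  ],
  [
   "S25",
   "manB"
  ]
 ]
}
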
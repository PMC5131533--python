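{
 "note": "manC defaults to PSEUDOGENE outside the ten strains with a functional copy (the truncated/absent split of the remainder is not strain-resolved); which of the four pts-fru operons each carrier strain holds is not strain-resolved either, so the functional copy is placed in fruA.",
 "stated_cells": [
  [
   "ATCC_BAA-1163",
   "fruA"
  ],
  [
   "IOEB_0501",
   "manC"
  ],
  [
   "IOEB_0502",
   "manC"
  ],
  [
   "IOEB_1491",
   "fruA"
  ],
  [
   "IOEB_8417",
   "manC"
  ],
  [
   "IOEB_9304",
   "manC"
  ],
  [
   "IOEB_9803",
   "manC"
  ],
  [
   "IOEB_9805",
   "manC"
  ],
  [
   "IOEB_B10",
   "manC"
  ],
  [
   "IOEB_C23",
   "fruA"
  ],
  [
   "IOEB_C28",
   "manC"
  ],
  [
   "IOEB_C52",
   "fruA"
  ],
  [
   "S12",
   "fruA"
  ],
  [
   "S12",
   "manC"
  ],
  [
   "S13",
   "manC"
  ],
  [
   "S19",
   "fruA"
  ]
 ]
}
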
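{
 "note": "ptsEI = general PTS enzyme I (singular near the active site in IOEB_0607); treP = PTS permease of the treA locus; malA functional only in the eight listed B/C strains.",
 "stated_cells": [
  [
   "ATCC_BAA-1163",
   "malA"
  ],
  [
   "ATCC_BAA-1163",
   "treC"
  ],
  [
   "AWRI_B129",
   "malA"
  ],
  [
   "AWRI_B419",
   "malA"
  ],
  [
   "AWRI_B419",
   "treC"
  ],
  [
   "AWRI_B429",
   "malA"
  ],
  [
   "AWRI_B548",
   "malA"
  ],
  [
   "B16",
   "malA"
  ],
  [
   "CiNe",
   "malA"
  ],
  [
   "IOEB_0205",
   "malA"
  ],
  [
   "IOEB_0502",
   "malA"
  ],
  [
   "IOEB_0607",
   "malA"
  ],
  [
   "IOEB_0607",
   "ptsEI"
  ],
  [
   "IOEB_0608",
   "malA"
  ],
  [
   "IOEB_1491",
   "malA"
  ],
  [
   "IOEB_8417",
   "malA"
  ],
  [
   "IOEB_9517",
   "malA"
  ],
  [
   "IOEB_B10",
   "malA"
  ],
  [
   "IOEB_C28",
   "malA"
  ],
  [
   "IOEB_L18.3",
   "malA"
  ],
  [
   "IOEB_L26.1",
   "malA"
  ],
  [
   "IOEB_L40.4",
   "malA"
  ],
  [
   "IOEB_L65.2",
   "malA"
  ],
  [
   "IOEB_S277",
   "malA"
  ],
  [
   "IOEB_S436",
   "malA"
  ],
  [
   "IOEB_S450",
   "malA"
  ],
  [
   "PSU-1",
   "malA"
  ],
  [
   "S11",
   "malA"
  ],
  [
   "S13",
   "treC"
  ],
  [
   "S14",
   "malA"
  ],
  [
   "S15",
   "malA"
  ],
  [
   "S161",
   "malA"
  ],
  [
   "S19",
   "malA"
  ],
  [
   "S23",
   "malA"
  ],
  [
   "S25",
   "malA"
  ],
  [
   "S28",
   "malA"
  ],
  [
   "VF",
   "malA"
  ]
 ]
}
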
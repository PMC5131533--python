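{
 "note": "malA (maltose/trehalose phosphorylase locus) functional in eight B/C strains and truncated elsewhere, including the maltose-positive IOEB_0502; malE (ABC transporter) is not strain-resolved and defaults INTACT, so the packaged rule reproduces the two documented discordances.",
 "stated_cells": [
  [
   "ATCC_BAA-1163",
   "malA"
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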
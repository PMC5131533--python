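{
 "note": "galA is a pseudogene in 12 strains: the nine panel negatives plus three panel positives (names assumed; the prose 4-positive/8-negative pseudogene split totals 33 positives, one more than the panel column total of 32).",
 "stated_cells": [
  [
   "AWRI_B429",
   "galA"
  ],
  [
   "AWRI_B548",
   "galA"
  ],
  [
   "B16",
   "galA"
  ],
  [
   "IOEB_0205",
   "galA"
  ],
  [
   "IOEB_0607",
   "galA"
  ],
  [
   "IOEB_9517",
   "galA"
  ],
  [
   "IOEB_L26.1",
   "galA"
  ],
  [
   "IOEB_L65.2",
   "galA"
  ],
  [
   "S14",
   "galA"
  ],
  [
   "S23",
   "galA"
  ],
  [
   "S25",
   "galA"
  ],
  [
   "S28",
   "galA"
  ]
 ]
}
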
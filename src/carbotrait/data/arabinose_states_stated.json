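{
 "note": "araD1 defaults to ABSENT (second-cluster isoform carried by a minority of strains); all other unstated cells default INTACT.",
 "stated_cells": [
  [
   "ATCC_BAA-1163",
   "araA"
  ],
  [
   "ATCC_BAA-1163",
   "araB"
  ],
  [
   "AWRI_B419",
   "araD"
  ],
  [
   "AWRI_B419",
   "araD1"
  ],
  [
   "AWRI_B429",
   "araA"
  ],
  [
   "IOEB_0501",
   "araC"
  ],
  [
   "IOEB_0607",
   "araD"
  ],
  [
   "IOEB_9304",
   "araT"
  ],
  [
   "IOEB_9805",
   "araC"
  ],
  [
   "IOEB_C28",
   "araT"
  ],
  [
   "IOEB_C52",
   "araT"
  ],
  [
   "IOEB_L40.4",
   "epi"
  ],
  [
   "IOEB_S450",
   "araB"
  ],
  [
   "S11",
   "epi"
  ],
  [
   "S13",
   "epi"
  ],
  [
   "S15",
   "epi"
  ],
  [
   "S23",
   "epi"
  ],
  [
   "S28",
   "araC"
  ]
 ]
}
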
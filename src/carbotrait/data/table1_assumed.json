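{
 "note": "Cells not pinned by prose statements or uniquely forced by the printed row/strain totals; chosen once to satisfy all marginals. All totals, percentages, bins and branch means are invariant to these choices.",
 "cells": [
  [
   "S11",
   "melibiose"
  ],
  [
   "CiNe",
   "melibiose"
  ],
  [
   "IOEB_0608",
   "melibiose"
  ],
  [
   "AWRI_B419",
   "melibiose"
  ],
  [
   "VF",
   "melibiose"
  ],
  [
   "IOEB_S436",
   "melibiose"
  ],
  [
   "S15",
   "melibiose"
  ],
  [
   "S161",
   "melibiose"
  ],
  [
   "IOEB_S277",
   "melibiose"
  ],
  [
   "IOEB_L18.3",
   "melibiose"
  ],
  [
   "IOEB_B10",
   "melibiose"
  ],
  [
   "S19",
   "melibiose"
  ],
  [
   "IOEB_1491",
   "melibiose"
  ],
  [
   "AWRI_B129",
   "melibiose"
  ],
  [
   "IOEB_L40.4",
   "melibiose"
  ],
  [
   "IOEB_S450",
   "melibiose"
  ],
  [
   "PSU-1",
   "melibiose"
  ],
  [
   "S14",
   "melibiose"
  ],
  [
   "IOEB_0607",
   "melibiose"
  ],
  [
   "S25",
   "melibiose"
  ],
  [
   "IOEB_L26.1",
   "melibiose"
  ],
  [
   "VF",
   "arabinose"
  ],
  [
   "IOEB_S436",
   "arabinose"
  ],
  [
   "S161",
   "arabinose"
  ],
  [
   "IOEB_S277",
   "arabinose"
  ],
  [
   "PSU-1",
   "arabinose"
  ],
  [
   "S14",
   "arabinose"
  ],
  [
   "S12",
   "arabinose"
  ],
  [
   "IOEB_8417",
   "arabinose"
  ],
  [
   "IOEB_9803",
   "arabinose"
  ],
  [
   "IOEB_C23",
   "arabinose"
  ],
  [
   "IOEB_0502",
   "arabinose"
  ],
  [
   "S12",
   "sucrose"
  ],
  [
   "ATCC_BAA-1163",
   "sucrose"
  ],
  [
   "IOEB_9805",
   "sucrose"
  ],
  [
   "IOEB_8417",
   "sucrose"
  ],
  [
   "IOEB_C23",
   "sucrose"
  ],
  [
   "S12",
   "maltose"
  ],
  [
   "IOEB_9803",
   "maltose"
  ],
  [
   "IOEB_9805",
   "maltose"
  ],
  [
   "IOEB_9304",
   "maltose"
  ],
  [
   "IOEB_C23",
   "maltose"
  ],
  [
   "S15",
   "galactose"
  ],
  [
   "IOEB_0501",
   "galactose"
  ],
  [
   "IOEB_0502",
   "galactose"
  ],
  [
   "IOEB_9803",
   "galactose"
  ],
  [
   "S161",
   "raffinose"
  ],
  [
   "IOEB_0501",
   "raffinose"
  ]
 ]
}
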
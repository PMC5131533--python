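{
 "note": "mfs9C23 is a strain-specific permease, ABSENT by default.",
 "stated_cells": [
  [
   "IOEB_1491",
   "ribT"
  ],
  [
   "IOEB_B10",
   "ribT"
  ],
  [
   "IOEB_C23",
   "mfs9C23"
  ],
  [
   "IOEB_C23",
   "ribT"
  ],
  [
   "S19",
   "ribT"
  ],
  [
   "S25",
   "ribT"
  ]
 ]
}
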
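{
 "chain": {
  "reactions": [
   "Ein",
   "r1",
   "Eout"
  ],
  "expas": [
   [
    1,
    1,
    1
   ]
  ]
 },
 "diamond": {
  "reactions": [
   "Ein",
   "r1",
   "r2",
   "Eout"
  ],
  "expas": [
   [
    1,
    0,
    1,
    1
   ],
   [
    1,
    1,
    0,
    1
   ]
  ]
 },
 "cycle": {
  "reactions": [
   "c1",
   "c2"
  ],
  "expas": [
   [
    1,
    1
   ]
  ]
 },
 "chain_cycle": {
  "reactions": [
   "Ein",
   "r1",
   "Eout",
   "c1",
   "c2"
  ],
  "expas": [
   [
    0,
    0,
    0,
    1,
    1
   ],
   [
    1,
    1,
    1,
    0,
    0
   ]
  ]
 },
 "reversible_pair": {
  "reactions": [
   "Ein",
   "r1_fwd",
   "r1_bwd",
   "Eout"
  ],
  "expas": [
   [
    1,
    1,
    0,
    1
   ]
  ]
 },
 "parallel_chains": {
  "reactions": [
   "Ein",
   "split",
   "r1a",
   "r1b",
   "r2",
   "Eout_B",
   "Eout_D"
  ],
  "expas": [
   [
    1,
    1,
    0,
    1,
    1,
    1,
    1
   ],
   [
    1,
    1,
    1,
    0,
    1,
    1,
    1
   ]
  ]
 }
}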
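{
 "LUT": {
  "residue_name": "LUT",
  "description": "lutein, C40H56O2 xanthophyll; beta-ionone ring (unprimed) and epsilon-ionone ring (primed), hydroxyls O3/O3'",
  "heavy_atoms": [
   "C1",
   "C2",
   "C3",
   "C4",
   "C5",
   "C6",
   "C7",
   "C8",
   "C9",
   "C10",
   "C11",
   "C12",
   "C13",
   "C14",
   "C15",
   "C16",
   "C17",
   "C18",
   "C19",
   "C20",
   "C1'",
   "C2'",
   "C3'",
   "C4'",
   "C5'",
   "C6'",
   "C7'",
   "C8'",
   "C9'",
   "C10'",
   "C11'",
   "C12'",
   "C13'",
   "C14'",
   "C15'",
   "C16'",
   "C17'",
   "C18'",
   "C19'",
   "C20'",
   "O3",
   "O3'"
  ],
  "hydroxyl_oxygens": {
   "beta": "O3",
   "epsilon": "O3'"
  },
  "rings": {
   "beta": [
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C16",
    "C17",
    "C18"
   ],
   "epsilon": [
    "C1'",
    "C2'",
    "C3'",
    "C4'",
    "C5'",
    "C6'",
    "C16'",
    "C17'",
    "C18'"
   ]
  },
  "inversion_pairs": [
   [
    "C1",
    "C1'"
   ],
   [
    "C2",
    "C2'"
   ],
   [
    "C3",
    "C3'"
   ],
   [
    "C4",
    "C4'"
   ],
   [
    "C5",
    "C5'"
   ],
   [
    "C6",
    "C6'"
   ],
   [
    "C7",
    "C7'"
   ],
   [
    "C8",
    "C8'"
   ],
   [
    "C9",
    "C9'"
   ],
   [
    "C10",
    "C10'"
   ],
   [
    "C11",
    "C11'"
   ],
   [
    "C12",
    "C12'"
   ],
   [
    "C13",
    "C13'"
   ],
   [
    "C14",
    "C14'"
   ],
   [
    "C15",
    "C15'"
   ],
   [
    "C16",
    "C16'"
   ],
   [
    "C17",
    "C17'"
   ],
   [
    "C18",
    "C18'"
   ],
   [
    "C19",
    "C19'"
   ],
   [
    "C20",
    "C20'"
   ],
   [
    "O3",
    "O3'"
   ]
  ]
 }
}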
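{
 "nodes": [
  "stress",
  "TRP",
  "SSRI",
  "TPH2",
  "HTP5",
  "AADC",
  "HT5_DRN",
  "MAOA",
  "HIAA5",
  "SLC18A2",
  "VESICLE",
  "SNARE",
  "HT5_SYN",
  "HTT",
  "HT1A_PRE",
  "KCH_PRE",
  "K_PRE",
  "HT1A_POST",
  "KCH_POST",
  "K_POST",
  "NFKB",
  "CREB",
  "BDNF",
  "TRKB",
  "CRH",
  "VPA",
  "ACTH",
  "CORT",
  "GRMR_PG",
  "GRMR_PVN",
  "GRMR_DRN",
  "GRMR_SSC",
  "GI_PRE",
  "GBG_PRE",
  "AC",
  "CAMP",
  "PKA",
  "GI_POST",
  "GBG_POST",
  "AC_POST",
  "CAMP_POST"
 ],
 "inputs": [
  [
   0
  ],
  [
   1
  ],
  [
   2
  ],
  [
   23,
   30,
   16
  ],
  [
   1,
   3
  ],
  [
   23
  ],
  [
   4,
   5
  ],
  [
   23
  ],
  [
   6,
   7
  ],
  [
   23
  ],
  [
   6,
   9
  ],
  [
   10
  ],
  [
   11,
   12,
   13
  ],
  [
   23,
   2,
   16
  ],
  [
   12,
   23,
   2
  ],
  [
   14
  ],
  [
   15
  ],
  [
   12,
   20
  ],
  [
   17
  ],
  [
   18
  ],
  [
   31
  ],
  [
   16
  ],
  [
   21
  ],
  [
   22
  ],
  [
   0,
   29
  ],
  [
   0,
   29
  ],
  [
   24,
   25,
   28
  ],
  [
   26
  ],
  [
   27
  ],
  [
   27
  ],
  [
   27
  ],
  [
   27
  ],
  [
   14
  ],
  [
   32
  ],
  [
   23
  ],
  [
   34
  ],
  [
   35
  ],
  [
   17
  ],
  [
   37
  ],
  [
   37
  ],
  [
   39
  ]
 ],
 "truth_tables": [
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1,
   0,
   0,
   0,
   0,
   0,
   0
  ],
  [
   0,
   0,
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   0,
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   0,
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   0,
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1,
   1,
   1,
   0,
   0,
   0,
   0
  ],
  [
   0,
   1,
   0,
   0,
   0,
   0,
   0,
   0
  ],
  [
   0,
   1,
   0,
   0,
   0,
   0,
   0,
   0
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   0,
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   1,
   0
  ],
  [
   1,
   0
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1,
   0,
   0
  ],
  [
   0,
   1,
   0,
   0
  ],
  [
   0,
   0,
   0,
   1,
   0,
   0,
   0,
   0
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ],
  [
   0,
   1
  ]
 ],
 "clamped": [
  "SSRI",
  "TRP",
  "stress"
 ]
}
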
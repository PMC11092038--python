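# The 27 accessions (25 distinct cultivars; Avalon appears under three IT
# numbers) with their corrected Glu-B1 genotype.  Bx14 entries are
# disambiguated into 14(-)/14(+) via the promoter-indel column.
cultivars:
  - {no: 1,  cultivar: Avalon,      origin: UK,        it_no: IT176822, bx: "Glu-1Bx6",     by: "Glu-1By8*"}
  - {no: 2,  cultivar: Avalon,      origin: UK,        it_no: IT115944, bx: "Glu-1Bx6",     by: "Glu-1By8*"}
  - {no: 3,  cultivar: Avalon,      origin: UK,        it_no: IT014649, bx: "Glu-1Bx6",     by: "Glu-1By8*"}
  - {no: 4,  cultivar: Keumkang,    origin: Korea,     it_no: IT213100, bx: "Glu-1Bx7",     by: "Glu-1By8"}
  - {no: 5,  cultivar: Hanback,     origin: Korea,     it_no: IT311644, bx: "Glu-1Bx7",     by: "Glu-1By8"}
  - {no: 6,  cultivar: Alchan,      origin: Korea,     it_no: IT175574, bx: "Glu-1Bx7",     by: "Glu-1By8"}
  - {no: 7,  cultivar: Gobun,       origin: Korea,     it_no: IT214681, bx: "Glu-1Bx7*",    by: "Glu-1By9"}
  - {no: 8,  cultivar: Eunpa,       origin: Korea,     it_no: IT175521, bx: "Glu-1Bx7*",    by: "Glu-1By9"}
  - {no: 9,  cultivar: Anbaek,      origin: Korea,     it_no: IT213245, bx: "Glu-1Bx7*",    by: "Glu-1By9"}
  - {no: 10, cultivar: Cheyenne,    origin: USA,       it_no: IT011154, bx: "Glu-1Bx7*",    by: "Glu-1By9"}
  - {no: 11, cultivar: Klein Cacique, origin: Argentina, it_no: IT234987, bx: "Glu-1Bx7*",  by: "Glu-1By8"}
  - {no: 12, cultivar: Chisolm,     origin: USA,       it_no: IT230956, bx: "Glu-1Bx7OE",   by: "Glu-1By8*"}
  - {no: 13, cultivar: MT8191,      origin: USA,       it_no: IT230937, bx: "Glu-1Bx7OE",   by: "Glu-1By8*"}
  - {no: 14, cultivar: KS85WGRC01,  origin: USA,       it_no: IT230965, bx: "Glu-1Bx7OE",   by: "Glu-1By8*"}
  - {no: 15, cultivar: Jeokjoong,   origin: Korea,     it_no: IT246750, bx: "Glu-1Bx13",    by: "Glu-1By16"}
  - {no: 16, cultivar: Baekjoong,   origin: Korea,     it_no: IT227093, bx: "Glu-1Bx13",    by: "Glu-1By16"}
  - {no: 17, cultivar: Joeun,       origin: Korea,     it_no: IT213101, bx: "Glu-1Bx13",    by: "Glu-1By16"}
  - {no: 18, cultivar: Troll,       origin: Germany,   it_no: IT206475, bx: "Glu-1Bx14(-)", by: "Glu-1By15"}
  - {no: 19, cultivar: Hanno,       origin: Germany,   it_no: IT206477, bx: "Glu-1Bx14(-)", by: "Glu-1By15"}
  - {no: 20, cultivar: Imbros,      origin: Germany,   it_no: IT206478, bx: "Glu-1Bx14(-)", by: "Glu-1By15"}
  - {no: 21, cultivar: Joongmo2008, origin: Korea,     it_no: IT269492, bx: "Glu-1Bx17",    by: "Glu-1By18"}
  - {no: 22, cultivar: Suwon92,     origin: Korea,     it_no: IT246989, bx: "Glu-1Bx17",    by: "Glu-1By18"}
  - {no: 23, cultivar: Suwon105,    origin: Korea,     it_no: IT246973, bx: "Glu-1Bx17",    by: "Glu-1By18"}
  - {no: 24, cultivar: Suwon15,     origin: Korea,     it_no: IT246979, bx: "Glu-1Bx20",    by: "Glu-1By20"}
  - {no: 25, cultivar: Suwon28,     origin: Korea,     it_no: IT246969, bx: "Glu-1Bx20",    by: "Glu-1By20"}
  - {no: 26, cultivar: Suwon42,     origin: Korea,     it_no: IT246970, bx: "Glu-1Bx20",    by: "Glu-1By20"}
  - {no: 27, cultivar: RANEE,       origin: UNK,       it_no: IT176783, bx: "Glu-1Bx14(+)", by: "Glu-1By15"}
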
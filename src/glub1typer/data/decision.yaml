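# Decision matrix: expected marker outcome per allele and primer set.
#
# Outcome encoding in rows:
#   presence markers:  pos | neg                (product present / absent)
#   size markers:      a size-class label, one of the marker's classes
#   count markers:     a band-count class label
# A ":weak" suffix marks outcomes the gels score as weak bands (a tolerated
# internal primer mismatch); intensity participates in matching only for the
# markers flagged intensity_matters.
#
# Size-class values are the modelled product lengths in bp.  Lengths printed
# in the source tables/figures (520/563/705/748, 365/419, 457, 501, 254, 527,
# 543, 558) are used verbatim; the remainder are fixture-defined and
# documented in docs/methods.md.
markers:
  PS1:  {locus: Bx, mode: presence, positive_size: 457}
  PS2:  {locus: Bx, mode: size, classes: {"520": 520, "563": 563, "705": 705, "748": 748}}
  PS3:  {locus: Bx, mode: presence, positive_size: 448}
  PS4:  {locus: Bx, mode: presence, positive_size: 600}
  PS7:  {locus: Bx, mode: size, classes: {"full": 518, "del18": 500}}
  PS8:  {locus: Bx, mode: size, classes: {"del108": 534, "full": 642, "ins45": 687}}
  PS10: {locus: Bx, mode: presence, positive_size: 457}
  PS11: {locus: Bx, mode: size, classes: {"365": 365, "419": 419}}
  PS12: {locus: Bx, mode: presence, positive_size: 254}
  PS13: {locus: Bx, mode: presence, positive_size: 501}
  PS14: {locus: Bx, mode: size, classes: {"full": 518, "del18": 500}}
  PS15: {locus: By, mode: presence, positive_size: 527}
  PS16: {locus: By, mode: presence, positive_size: 527, intensity_matters: true}
  PS17: {locus: By, mode: presence, positive_size: 543}
  PS18: {locus: By, mode: size, classes: {"del45": 853, "full": 898, "larger": 988},
         intensity_matters: true}
  PS19: {locus: By, mode: size, classes: {"del45": 488, "full": 533, "larger": 623},
         intensity_matters: true}
  PS22: {locus: By, mode: count,
         classes: {"one_band": [400], "two_bands": [300, 500], "three_bands": [300, 500, 700]}}
  PS23: {locus: By, mode: presence, positive_size: 558}

rows:
  Glu-1Bx6:
    {PS1: neg, PS2: "520", PS3: neg, PS4: neg, PS7: full, PS8: ins45,
     PS10: pos, PS11: "419", PS12: neg, PS13: neg, PS14: full}
  Glu-1Bx7:
    {PS1: pos, PS2: "520", PS3: neg, PS4: neg, PS7: full, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: neg, PS14: full}
  Glu-1Bx7*:
    {PS1: pos, PS2: "520", PS3: neg, PS4: neg, PS7: del18, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: neg, PS14: full}
  Glu-1Bx7OE:
    {PS1: pos, PS2: "563", PS3: pos, PS4: pos, PS7: full, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: neg, PS14: full}
  Glu-1Bx13:
    {PS1: neg, PS2: "520", PS3: neg, PS4: neg, PS7: full, PS8: full,
     PS10: neg, PS11: "365", PS12: pos, PS13: neg, PS14: full}
  Glu-1Bx14(-):
    {PS1: pos, PS2: "520", PS3: neg, PS4: neg, PS7: full, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: neg, PS14: del18}
  Glu-1Bx14(+):
    {PS1: neg, PS2: "705", PS3: neg, PS4: neg, PS7: full, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: pos, PS14: full}
  Glu-1Bx17:
    {PS1: pos, PS2: "520", PS3: neg, PS4: neg, PS7: del18, PS8: del108,
     PS10: neg, PS11: "419", PS12: neg, PS13: neg, PS14: full}
  Glu-1Bx20:
    {PS1: neg, PS2: "705", PS3: neg, PS4: neg, PS7: full, PS8: full,
     PS10: neg, PS11: "419", PS12: neg, PS13: pos, PS14: full}
  Glu-1By8:
    {PS15: pos, PS16: neg, PS17: neg, PS18: full, PS19: full,
     PS22: two_bands, PS23: neg}
  Glu-1By8*:
    {PS15: neg, PS16: pos, PS17: neg, PS18: full, PS19: full,
     PS22: two_bands, PS23: neg}
  Glu-1By9:
    {PS15: neg, PS16: pos, PS17: neg, PS18: del45, PS19: del45,
     PS22: two_bands, PS23: neg}
  Glu-1By15:
    {PS15: neg, PS16: "pos:weak", PS17: neg, PS18: "larger:weak",
     PS19: "larger:weak", PS22: one_band, PS23: neg}
  Glu-1By16:
    {PS15: neg, PS16: pos, PS17: neg, PS18: full, PS19: full,
     PS22: three_bands, PS23: pos}
  Glu-1By18:
    {PS15: neg, PS16: pos, PS17: pos, PS18: full, PS19: full,
     PS22: two_bands, PS23: neg}
  Glu-1By20:
    {PS15: neg, PS16: "pos:weak", PS17: neg, PS18: "larger:weak",
     PS19: "larger:weak", PS22: one_band, PS23: neg}
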
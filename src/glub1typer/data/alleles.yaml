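# Reference registry of Glu-1Bx and Glu-1By alleles.
#
# promoter_features / cds_features name the structural polymorphisms that
# the marker panel exploits:
#   promoter: ins43 (43 bp insertion), ins185 (185 bp insertion),
#             dup54 (tandem 54 bp "cereal box" duplication; present in
#             every Bx promoter except Glu-1Bx13)
#   CDS:      del18 (18 bp hexapeptide-motif deletion), del108, ins15,
#             ins45 (extra 45 bp seen as a larger cauBx642 product in Bx6),
#             del45 (By9), dup_locus (the x-type gene duplication that
#             defines Glu-1Bx7OE)
#
# in_decision_table marks alleles for which the published marker panel
# defines a full expected outcome row; the remainder (Bx14*, Bx17*, Bx23,
# Bx23*, By15*) appear only in the sequence-comparison registry/phylogeny.
alleles:
  - name: Glu-1Bx6
    locus: Bx
    accession: KX454509.1
    promoter_features: [dup54]
    cds_features: [ins15, ins45]
    in_decision_table: true
    notes: "dominantly detected by MHBx6 (457 bp); 45 bp larger cauBx642 product"
  - name: Glu-1Bx7
    locus: Bx
    accession: BK006773.1
    promoter_features: [dup54]
    cds_features: []
    in_decision_table: true
    notes: ""
  - name: Glu-1Bx7*
    locus: Bx
    accession: X13927.3
    promoter_features: [dup54]
    cds_features: [del18]
    in_decision_table: true
    notes: "18 bp deletion of one hexapeptide motif in the repeat domain"
  - name: Glu-1Bx7OE
    locus: Bx
    accession: unavailable
    promoter_features: [ins43, dup54]
    cds_features: [dup_locus]
    in_decision_table: true
    notes: "over-expression allele: 43 bp promoter insertion plus gene duplication; CDS matches Glu-1Bx7"
  - name: Glu-1Bx13
    locus: Bx
    accession: EF540764.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "promoter lacks the 54 bp cereal-box duplication"
  - name: Glu-1Bx14(-)
    locus: Bx
    accession: KF733216.1
    promoter_features: [dup54]
    cds_features: [del18]
    in_decision_table: true
    notes: "18 bp CDS deletion relative to Glu-1Bx14(+), assayed by MHBx14(-)"
  - name: Glu-1Bx14(+)
    locus: Bx
    accession: AY367771.1
    promoter_features: [ins185, dup54]
    cds_features: []
    in_decision_table: true
    notes: "near-identical to Glu-1Bx20; the pair is a documented ambiguity class"
  - name: Glu-1Bx14*
    locus: Bx
    accession: KJ579439.1
    promoter_features: []
    cds_features: []
    in_decision_table: false
    notes: "phylogeny only; sister to Glu-1Bx23*"
  - name: Glu-1Bx17
    locus: Bx
    accession: KC254854.1
    promoter_features: [dup54]
    cds_features: [del18, del108]
    in_decision_table: true
    notes: ""
  - name: Glu-1Bx17*
    locus: Bx
    accession: KF547469.1
    promoter_features: []
    cds_features: []
    in_decision_table: false
    notes: "no published marker outcomes"
  - name: Glu-1Bx20
    locus: Bx
    accession: AJ437000.2
    promoter_features: [ins185, dup54]
    cds_features: [ins15]
    in_decision_table: true
    notes: "near-identical to Glu-1Bx14(+); the pair is a documented ambiguity class"
  - name: Glu-1Bx23
    locus: Bx
    accession: AY553933.1
    promoter_features: []
    cds_features: []
    in_decision_table: false
    notes: "no published marker outcomes"
  - name: Glu-1Bx23*
    locus: Bx
    accession: KF995273.1
    promoter_features: []
    cds_features: []
    in_decision_table: false
    notes: "no published marker outcomes"
  - name: Glu-1By8
    locus: By
    accession: JN255519.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "only allele amplified by ZSBy8 (PS15); null for the By8-negative SNP marker"
  - name: Glu-1By8*
    locus: By
    accession: unavailable
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "sequence not in public databases; called by elimination"
  - name: Glu-1By9
    locus: By
    accession: X61026.1
    promoter_features: []
    cds_features: [del45]
    in_decision_table: true
    notes: "45 bp CDS deletion"
  - name: Glu-1By15
    locus: By
    accession: EU137874.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "near-identical to Glu-1By20; the pair is a documented ambiguity class"
  - name: Glu-1By15*
    locus: By
    accession: KJ579440.1
    promoter_features: []
    cds_features: []
    in_decision_table: false
    notes: "no published marker outcomes"
  - name: Glu-1By16
    locus: By
    accession: EF540765.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "three-band ZSBy9 pattern; dominant 558 bp MHBy16 product"
  - name: Glu-1By18
    locus: By
    accession: KF430649.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "dominant 543 bp MHBy18 product"
  - name: Glu-1By20
    locus: By
    accession: KU886033.1
    promoter_features: []
    cds_features: []
    in_decision_table: true
    notes: "near-identical to Glu-1By15; the pair is a documented ambiguity class"
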
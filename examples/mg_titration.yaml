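times: [30, 60, 120, 240, 420]
replicates: 3
noise_sigma: 0.01
conditions:
  - {variant: WT, substrate: "C•G", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 0.2}
  - {variant: WT, substrate: "C•G", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 0.5}
  - {variant: WT, substrate: "C•G", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 1.0}
  - {variant: WT, substrate: "C•G", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 2.0}
  - {variant: WT, substrate: "C•G", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 5.0}
  - {variant: WT, substrate: "8oxoG•A", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 0.2}
  - {variant: WT, substrate: "8oxoG•A", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 0.5}
  - {variant: WT, substrate: "8oxoG•A", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 1.0}
  - {variant: WT, substrate: "8oxoG•A", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 2.0}
  - {variant: WT, substrate: "8oxoG•A", enzyme_nM: 1, dna_nM: 1000, atp_mM: 0.2, mg_free_mM: 5.0}
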
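# Default ATM-p53 DDR RT-MLPA panel: 10 classification genes in four
# response clusters plus 4 irradiation-independent housekeeping genes.
# Cluster I: p53/ATM targets induced by irradiation when the axis is intact.
# Clusters II-IV: genes whose post-irradiation regulation separates
# TP53-defective from ATM-defective cells (II+III up, IV down in
# TP53-defective relative to ATM-defective).
panel_version: "R016-X2-like/1"
genes:
  - gene_id: FAS
    cluster: I
    probes: [FAS_p1, FAS_p2]
  - gene_id: Bax
    cluster: I
    probes: [Bax_p1, Bax_p2]
  - gene_id: BBC3
    cluster: I
    probes: [BBC3_p1, BBC3_p2]
  - gene_id: CDKN1A
    cluster: I
    probes: [CDKN1A_p1, CDKN1A_p2]
  - gene_id: PCNA
    cluster: I
    probes: [PCNA_p1, PCNA_p2]
  - gene_id: FDXR
    cluster: I
    probes: [FDXR_p1, FDXR_p2]
  - gene_id: NME1
    cluster: II
    probes: [NME1_p1, NME1_p2]
  - gene_id: MYC
    cluster: III
    probes: [MYC_p1, MYC_p2]
  - gene_id: PYCR1
    cluster: III
    probes: [PYCR1_p1, PYCR1_p2]
  - gene_id: ACSM3
    cluster: IV
    probes: [ACSM3_p1, ACSM3_p2]
housekeeping:
  - gene_id: Diablo
    probes: [Diablo_p1]
  - gene_id: Aif
    probes: [Aif_p1]
  - gene_id: Gusb
    probes: [Gusb_p1]
  - gene_id: Parn
    probes: [Parn_p1]
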
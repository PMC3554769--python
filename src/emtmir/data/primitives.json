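{
  "_provenance": {
    "control_factors": "estimated: expressed as multiples of the healthy steady state; MYC->miR-9 Hill saturation set large (10x MYC) so the quartic amplifier reproduces the tissue-scale miR-9 overexpression factor",
    "ecad_steady_nM": "total E-Cadherin concentration, Chaplain 2011",
    "egf_egfr_binding": "EGFR cascade model constants, Brown et al. 2004",
    "half_lives": "Luscher & Eisenman (MYC); Sethi & Lukiw (miR-9, brain tissue); Iliopoulos et al. (let-7 after TAM); Fujita et al. (E-Cadherin); Akool et al. (MMP-9 mRNA)",
    "hela_total_volume": "Fujioka et al. 2006 (HeLa cell volume)",
    "kinetics_molecular": "Brown et al. 2004 EGFR cascade, per-molecule units",
    "mmp_mrna": "MMP-9 mRNA copies per lung tissue mass, Safranek et al. 2009; lung tissue density, Hopkins 2007",
    "molecule_counts": "Brown et al. 2004 (cascade species); Rudolph et al. 1999 (nuclear MYC); Lim et al. 2003 (let-7 copies/HeLa cell); miR-9 normal-lung copy number taken as 1/cell (very small)",
    "nucleus_volume": "HeLa nuclear volume, same source family"
  },
  "avogadro": 6.022e+23,
  "control_factors": {
    "k_ecad_on_mmp_over_ecad": 1.0,
    "k_let7_on_ras_over_let7": 20.0,
    "k_mir9_on_ecad_over_mir9": 10.0,
    "k_myc_on_let7_over_myc": 1.0,
    "k_myc_on_mir9_over_myc": 10.0
  },
  "cytoplasm_volume": 1.9e-12,
  "ecad_steady_nM": 100.0,
  "egf_count": 10000.0,
  "egfr_total_count": 80000.0,
  "half_lives": {
    "ecad": 300.0,
    "let7": 240.0,
    "mir9": 60.0,
    "mmp": 720.0,
    "myc": 30.0
  },
  "hela_total_volume": 2.6e-12,
  "kinetics_molecular": {
    "kd_erk": 0.002,
    "kd_ras": 0.005,
    "kd_sos": 0.0004,
    "kf_erk": 0.0018,
    "kf_ras": 0.0022,
    "kf_sos": 0.00025,
    "km_act_erk": 600000.0,
    "km_act_ras": 100000.0,
    "km_act_sos": 100000.0,
    "km_deact_erk": 150000.0,
    "km_deact_ras": 25000.0,
    "km_deact_sos": 25000.0
  },
  "koff": 1.0,
  "kon": 0.0001,
  "lung_tissue_density": 1050.0,
  "membrane_shell_thickness": 1e-08,
  "mir9_overexpression_factor": 30.0,
  "mmp_copies_per_gram_tissue": 600000000.0,
  "molecule_counts": {
    "erk": 600000.0,
    "let7": 10000.0,
    "mek": 600000.0,
    "mir9": 1.0,
    "myc_nucleus": 60000.0,
    "p90rsk": 100000.0,
    "pp2a": 100000.0,
    "ras": 100000.0,
    "ras_gap": 12000.0,
    "sos": 100000.0
  },
  "nucleus_volume": 7e-13
}
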
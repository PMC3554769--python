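{
  "deg_ecad": 0.0023104906018664843,
  "deg_erk": 200.0,
  "deg_let7": 0.0028881132523331052,
  "deg_mir9": 0.011552453009332421,
  "deg_mmp": 0.0009627044174443685,
  "deg_myc": 0.023104906018664842,
  "deg_ras": 60.0,
  "deg_sos": 0.07627866666666669,
  "egfr_complex": 7264.173642881435,
  "erk_total": 524.3930150850389,
  "hill_order_mir9": 4,
  "k_ecad_on_mmp": 100.0,
  "k_let7_on_ras": 174.79767169501298,
  "k_mir9_on_ecad": 0.00873988358475065,
  "k_myc_on_let7": 142.3352469516534,
  "k_myc_on_mir9": 1423.352469516534,
  "km_erk_act": 524.3930150850389,
  "km_erk_deact": 131.09825377125972,
  "km_ras_act": 87.39883584750649,
  "km_ras_deact": 21.849708961876622,
  "km_sos_act": 87.39883584750649,
  "km_sos_deact": 21.849708961876622,
  "prod_ecad": 0.029079788505279543,
  "prod_erk": 12.357144000000003,
  "prod_let7": 0.05048354720993383,
  "prod_mir9": 0.10097719112930963,
  "prod_mmp": 1.0071467668381803e-06,
  "prod_myc": 0.03107419050096348,
  "prod_ras": 2.5171960000000007,
  "prod_sos": 0.001376619074875716,
  "ras_total": 87.39883584750649,
  "sos_total": 87.39883584750649,
  "steady_state": {
    "ecad": 100.0,
    "erk": 105.83196057382206,
    "let7": 8.739883584750649,
    "mir9": 0.0008739883584750649,
    "mmp": 0.001046164065094653,
    "myc": 142.3352469516534,
    "ras": 16.286959074668122,
    "sos": 23.825238288780007
  },
  "units": {
    "concentration": "nM",
    "time": "min"
  }
}
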
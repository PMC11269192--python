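{
  "grid": {"cycle_length_days": 21, "horizon_years": 5, "days_per_month": 30.0},
  "assumptions": {"bsa_m2": 1.73, "rmb_per_usd": 7.238, "wtp_per_qaly": 35519.39},
  "treated": "utidelone_capecitabine",
  "comparator": "capecitabine",
  "use_category_overrides": true,
  "arms": {
    "utidelone_capecitabine": {
      "premedicated_infusion_days": 5,
      "regimen": [
        {"drug": "utidelone", "dose_per_m2": 30, "administrations_per_day": 1, "days_per_cycle": 5, "route": "intravenous"},
        {"drug": "capecitabine", "dose_per_m2": 1000, "administrations_per_day": 2, "days_per_cycle": 14, "route": "oral"}
      ]
    },
    "capecitabine": {
      "premedicated_infusion_days": 0,
      "regimen": [
        {"drug": "capecitabine", "dose_per_m2": 1250, "administrations_per_day": 2, "days_per_cycle": 14, "route": "oral"}
      ]
    }
  },
  "pack_specs": {
    "utidelone": {"pack_content_mg": 50, "price_param": "cost.utidelone_per_pack", "units_per_pack": 1, "rounding_level": "day", "rounding_mode": "nearest", "pack_rounding": "up"},
    "capecitabine": {"pack_content_mg": 500, "price_param": "cost.capecitabine_per_pack", "units_per_pack": 12, "rounding_level": "administration", "rounding_mode": "nearest", "pack_rounding": "up"}
  },
  "parameters": [
    {"name": "curve.utidelone_capecitabine.os.scale", "value": 15.224, "lower": null, "upper": null, "distribution": "loglogistic", "category": "curve"},
    {"name": "curve.utidelone_capecitabine.os.shape", "value": 2.826, "lower": null, "upper": null, "distribution": "loglogistic", "category": "curve_shape"},
    {"name": "curve.capecitabine.os.scale", "value": 12.534, "lower": null, "upper": null, "distribution": "loglogistic", "category": "curve"},
    {"name": "curve.capecitabine.os.shape", "value": 2.933, "lower": null, "upper": null, "distribution": "loglogistic", "category": "curve_shape"},
    {"name": "curve.utidelone_capecitabine.pfs.scale", "value": 0.0345, "lower": null, "upper": null, "distribution": "weibull", "category": "curve"},
    {"name": "curve.utidelone_capecitabine.pfs.shape", "value": 1.51337, "lower": null, "upper": null, "distribution": "weibull", "category": "curve_shape"},
    {"name": "curve.capecitabine.pfs.scale", "value": 0.072, "lower": null, "upper": null, "distribution": "weibull", "category": "curve"},
    {"name": "curve.capecitabine.pfs.shape", "value": 1.3696, "lower": null, "upper": null, "distribution": "weibull", "category": "curve_shape"},

    {"name": "cost.utidelone_per_pack", "value": 408.94, "lower": 327.15, "upper": 490.72, "distribution": "gamma", "category": "cost"},
    {"name": "cost.capecitabine_per_pack", "value": 36.51, "lower": 29.21, "upper": 43.81, "distribution": "gamma", "category": "cost"},
    {"name": "cost.cimetidine", "value": 3.38, "lower": 2.70, "upper": 4.05, "distribution": "gamma", "category": "cost"},
    {"name": "cost.diphenhydramine", "value": 4.69, "lower": 3.76, "upper": 5.63, "distribution": "gamma", "category": "cost"},
    {"name": "cost.dexamethasone", "value": 0.99, "lower": 0.79, "upper": 1.19, "distribution": "gamma", "category": "cost"},
    {"name": "cost.hospitalization", "value": 17.27, "lower": 13.82, "upper": 20.72, "distribution": "gamma", "category": "cost"},
    {"name": "cost.infusion", "value": 1.64, "lower": 1.31, "upper": 1.96, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ecg", "value": 3.73, "lower": 2.98, "upper": 4.48, "distribution": "gamma", "category": "cost"},
    {"name": "cost.hematology", "value": 3.45, "lower": 2.76, "upper": 4.14, "distribution": "gamma", "category": "cost"},
    {"name": "cost.serum_chemistry", "value": 24.87, "lower": 19.89, "upper": 29.84, "distribution": "gamma", "category": "cost"},
    {"name": "cost.urinalysis", "value": 4.14, "lower": 3.32, "upper": 4.97, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ct", "value": 296.96, "lower": 237.56, "upper": 356.35, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.anemia", "value": 275.30, "lower": 220.24, "upper": 330.36, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.neutropenia", "value": 483.54, "lower": 386.83, "upper": 580.25, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.diarrhoea", "value": 10.36, "lower": 8.29, "upper": 12.43, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.peripheral_neuropathy", "value": 621.69, "lower": 497.35, "upper": 746.03, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.palmar_plantar_erythrodysesthesia", "value": 93.25, "lower": 74.60, "upper": 111.90, "distribution": "gamma", "category": "cost"},
    {"name": "cost.ae.leucopenia", "value": 483.54, "lower": 386.83, "upper": 580.25, "distribution": "gamma", "category": "cost"},
    {"name": "cost.end_of_life", "value": 1036.15, "lower": 828.92, "upper": 1243.39, "distribution": "gamma", "category": "cost"},

    {"name": "cost.ae_total.utidelone_capecitabine", "value": 855.63, "lower": 684.50, "upper": 1026.76, "distribution": "gamma", "category": "override"},
    {"name": "cost.ae_total.capecitabine", "value": 477.81, "lower": 382.25, "upper": 573.37, "distribution": "gamma", "category": "override"},
    {"name": "cost.pd_total.utidelone_capecitabine", "value": 496.50, "lower": 397.20, "upper": 595.80, "distribution": "gamma", "category": "override"},
    {"name": "cost.pd_total.capecitabine", "value": 439.50, "lower": 351.60, "upper": 527.40, "distribution": "gamma", "category": "override"},

    {"name": "inc.utidelone_capecitabine.anemia", "value": 0.034, "lower": 0.027, "upper": 0.04, "distribution": "beta", "category": "incidence"},
    {"name": "inc.utidelone_capecitabine.neutropenia", "value": 0.116, "lower": 0.093, "upper": 0.14, "distribution": "beta", "category": "incidence"},
    {"name": "inc.utidelone_capecitabine.diarrhoea", "value": 0.071, "lower": 0.057, "upper": 0.09, "distribution": "beta", "category": "incidence"},
    {"name": "inc.utidelone_capecitabine.peripheral_neuropathy", "value": 0.217, "lower": 0.174, "upper": 0.26, "distribution": "beta", "category": "incidence"},
    {"name": "inc.utidelone_capecitabine.palmar_plantar_erythrodysesthesia", "value": 0.067, "lower": 0.054, "upper": 0.08, "distribution": "beta", "category": "incidence"},
    {"name": "inc.utidelone_capecitabine.leucopenia", "value": 0.052, "lower": 0.042, "upper": 0.06, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.anemia", "value": 0.031, "lower": 0.025, "upper": 0.04, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.neutropenia", "value": 0.092, "lower": 0.074, "upper": 0.11, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.diarrhoea", "value": 0.023, "lower": 0.018, "upper": 0.03, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.peripheral_neuropathy", "value": 0.008, "lower": 0.006, "upper": 0.01, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.palmar_plantar_erythrodysesthesia", "value": 0.077, "lower": 0.062, "upper": 0.09, "distribution": "beta", "category": "incidence"},
    {"name": "inc.capecitabine.leucopenia", "value": 0.054, "lower": 0.043, "upper": 0.06, "distribution": "beta", "category": "incidence"},

    {"name": "utility.pf", "value": 0.85, "lower": 0.68, "upper": 1.02, "distribution": "beta", "category": "utility"},
    {"name": "utility.pd", "value": 0.69, "lower": 0.55, "upper": 0.83, "distribution": "beta", "category": "utility"},
    {"name": "utility.ae_disutility", "value": -0.28, "lower": -0.34, "upper": -0.22, "distribution": "beta", "category": "utility"},

    {"name": "discount.annual", "value": 0.05, "lower": 0.0, "upper": 0.08, "distribution": "beta", "category": "discount"}
  ]
}
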
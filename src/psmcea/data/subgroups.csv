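label,hr,ci_low,ci_high
age_ge60,0.70,0.37,1.34
age_lt60,0.65,0.51,0.83
prior_chemo_gt2,0.60,0.42,0.85
prior_chemo_le2,0.70,0.52,0.94
visceral_metastases_yes,0.69,0.53,0.89
visceral_metastases_no,0.58,0.35,0.96
lymph_node_metastases_yes,0.69,0.52,0.92
lymph_node_metastases_no,0.63,0.43,0.91
metastatic_sites_gt2,0.69,0.50,0.95
metastatic_sites_le2,0.65,0.47,0.90
ecog_0,0.56,0.37,0.85
ecog_ge1,0.76,0.58,1.00
prior_capecitabine_yes,0.67,0.36,1.24
prior_capecitabine_no,0.68,0.53,0.87
her2neg_orpos_prpos,0.42,0.27,0.64
her2neg_orneg_prneg,0.77,0.48,1.24
her2neg,0.52,0.38,0.70
her2pos,0.82,0.52,1.29
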
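# Synthetic cohort: 90 high- and 37 low-social-anxiety observers with a
# group x negative-affect effect on the generating PSE.
n_hsa: 90
n_lsa: 37
na_mean_hsa: 13.81
na_sd_hsa: 3.38
na_mean_lsa: 11.68
na_sd_lsa: 2.02
b0: 3.0            # LSA PSE at mean NA (morph-%)
b_sa: 2.5          # HSA main effect
b_na: 0.3          # NA main effect (per NA point, centered)
b_int: 1.2         # group x NA interaction
pse_residual_sd: 11.0
omission_rate: 0.07
na_missing_rate: 0.04
seed: 1
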
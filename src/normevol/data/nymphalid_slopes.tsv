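species	cu1_slope	provenance
Papilio_polytes	-0.020	synthetic magnitude, sign negative per reared results
Danaus_chrysippus	0.000	synthetic, non-plastic species
Idea_leuconoe	0.001	synthetic, non-plastic species
Cethosia_cyane	-0.001	synthetic, non-plastic species
Vindula_dejone	0.002	synthetic, non-plastic species
Vanessa_cardui	-0.015	synthetic magnitude, sign negative (nymphaline)
Doleschallia_bisaltide	-0.020	synthetic magnitude, sign negative (nymphaline)
Junonia_coenia	-0.012	synthetic magnitude, sign negative (nymphaline)
Junonia_almana	-0.018	synthetic magnitude, sign negative (nymphaline)
Junonia_atlites	-0.010	synthetic magnitude, sign negative (nymphaline)
Junonia_iphita	-0.014	synthetic magnitude, sign negative (nymphaline)
Morpho_peleides	0.003	synthetic, non-plastic species
Melanitis_leda	0.020	synthetic magnitude, sign positive (satyrine, 6 C corrected)
Heteropsis_iboina	0.015	synthetic magnitude, sign positive (satyrine, 6 C corrected)
Bicyclus_anynana	0.025	synthetic magnitude, sign positive (satyrine)
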
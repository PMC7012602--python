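species	size_plasticity	titer_20e	ecr_eyespot	sensitivity_20e	reared	provenance
Papilio_polytes	1	1	0	?	1	size: papilionid outgroup showed a slight size decrease (negative); EcR absent from simple spot centers; titers higher at high T
Danaus_chrysippus	0	1	0	?	1	size: one of five reared species with no significant temperature effect (synthetic assignment); no central wing spots so EcR absent
Idea_leuconoe	0	0	0	?	1	size: non-plastic (synthetic assignment); EcR absent from simple spots; titer difference coded non-significant (synthetic)
Cethosia_cyane	0	1	1	?	1	size: non-plastic (synthetic assignment); eyespot-bearing heliconiine, EcR present
Vindula_dejone	0	1	1	?	1	size: non-plastic (synthetic assignment); EcR present in eyespot centers; injections showed no 20E sensitivity
Vanessa_cardui	1	1	1	?	1	size: nymphaline, small negative response; EcR present
Doleschallia_bisaltide	1	1	1	?	1	size: nymphaline, negative response; EcR present; injections showed no 20E sensitivity
Junonia_coenia	1	1	0	?	1	size: nymphaline, negative response; EcR absent from eyespots at the wandering stage
Junonia_almana	1	1	0	?	1	size: nymphaline, negative response; EcR absent from eyespots at the wandering stage
Junonia_atlites	1	0	1	?	1	size: nymphaline, negative response; titer difference coded non-significant (synthetic); EcR present
Junonia_iphita	1	1	1	?	1	size: nymphaline, negative response; EcR present
Morpho_peleides	0	0	1	?	1	size: non-plastic (synthetic assignment); EcR present; titer difference coded non-significant (synthetic)
Melanitis_leda	2	?	?	?	0	literature-derived satyrine (reared 21/27 C, slope corrected for 6 C); eyespot size increases with temperature; hormone/EcR unscored
Heteropsis_iboina	2	?	?	?	0	literature-derived satyrine (reared 21/27 C, slope corrected for 6 C); eyespot size increases with temperature; hormone/EcR unscored
Bicyclus_anynana	2	1	1	1	1	only reared species with a positive size reaction norm; EcR present; eyespots sensitive to 20E and CucB injections
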
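# Genus-level chronogram for the 13 reared species (12 nymphalids + 1
# papilionid outgroup) plus two literature-derived satyrines, pruned from the
# published nymphalid backbone topology. Branch lengths are ages in Myr from
# an ultrametric calibration anchored on the ~85 Myr origin of eyespots at
# the MRCA of the eyespot-bearing clade; all calibrations are synthetic
# placeholders and user-replaceable (see docs/methods.md).
(Papilio_polytes:110,((Danaus_chrysippus:60,Idea_leuconoe:60):34,(((Cethosia_cyane:35,Vindula_dejone:35):47,(Vanessa_cardui:65,(Doleschallia_bisaltide:45,(Junonia_coenia:25,(Junonia_almana:18,(Junonia_atlites:12,Junonia_iphita:12):6):7):20):20):17):3,(Morpho_peleides:75,(Melanitis_leda:55,(Heteropsis_iboina:40,Bicyclus_anynana:40):15):20):10):9):16);
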
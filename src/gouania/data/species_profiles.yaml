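# Categorical key-character states and vertebral ranges per species, as stated
# in the species Diagnoses. Used to assemble reference profiles and to equip
# simulated specimens with species-consistent categorical characters.
"G. adriatica":
  dorsal_head_profile: straight
  jaw_angle_extent: between_posterior_nostril_and_anterior_eye
  neuromast_groove: deep
  opercular_edge: pointed_upper_rounded_lower
  vertebrae: [35, 35]
"G. orientalis":
  dorsal_head_profile: straight
  jaw_angle_extent: to_anterior_eye_or_beyond
  neuromast_groove: deep
  opercular_edge: two_equal_tips
  vertebrae: [35, 36]
"G. hofrichteri":
  dorsal_head_profile: concave
  jaw_angle_extent: between_posterior_nostril_and_anterior_eye
  neuromast_groove: shallow
  opercular_edge: pointed_upper_rounded_lower
  vertebrae: [38, 40]
"G. pigra":
  dorsal_head_profile: concave
  jaw_angle_extent: to_anterior_nostril
  neuromast_groove: deep
  opercular_edge: two_tips_upper_longer_or_equal
  vertebrae: [39, 40]
"G. willdenowi":
  dorsal_head_profile: straight
  jaw_angle_extent: between_posterior_nostril_and_anterior_eye
  neuromast_groove: deep
  opercular_edge: two_equal_tips
  vertebrae: [37, 38]
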
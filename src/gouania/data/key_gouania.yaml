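# Dichotomous identification key for the five Gouania species.
# Each couplet has two contrasting leads (a/b); each lead is a conjunction of
# character predicates plus a branch target (another couplet or a species leaf).
# Geography notes are metadata only and never used as identification evidence.
root: "1"
couplets:
  - id: "1"
    a:
      predicates:
        - {character: dorsal_head_profile, op: eq, value: concave}
        - {character: caudal_fin_length_pct_sl, op: in_interval, lo: 11.1, hi: 13.0}
        - {character: pectoral_fin_length_pct_sl, op: in_interval, lo: 5.4, hi: 7.5}
      next: {couplet: "2"}
      note: "slender species of Gouania"
    b:
      predicates:
        - {character: dorsal_head_profile, op: eq, value: straight}
        - {character: caudal_fin_length_pct_sl, op: in_interval, lo: 13.5, hi: 17.5}
        - {character: pectoral_fin_length_pct_sl, op: in_interval, lo: 8.2, hi: 11.3}
      next: {couplet: "3"}
      note: "stout species of Gouania"
  - id: "2"
    a:
      predicates:
        - {character: jaw_angle_extent, op: eq, value: to_anterior_nostril}
        - {character: neuromast_groove, op: eq, value: deep}
      next: {species: "G. pigra"}
      note: "Adriatic Sea"
    b:
      predicates:
        - {character: jaw_angle_extent, op: eq, value: between_posterior_nostril_and_anterior_eye}
        - {character: neuromast_groove, op: eq, value: shallow}
      next: {species: "G. hofrichteri"}
      note: "Aegean Sea, rare in the south Adriatic Sea (single record from Peljesac)"
  - id: "3"
    a:
      predicates:
        - {character: opercular_edge, op: eq, value: pointed_upper_rounded_lower}
      next: {species: "G. adriatica"}
      note: "Adriatic Sea, northern Ionian Sea (Corfu)"
    b:
      predicates:
        - {character: opercular_edge, op: eq, value: two_equal_tips}
      next: {couplet: "4"}
  - id: "4"
    a:
      predicates:
        - {character: vertebrae_count, op: in_interval, lo: 37, hi: 38}
      next: {species: "G. willdenowi"}
      note: "West Mediterranean to Messina"
    b:
      predicates:
        - {character: vertebrae_count, op: in_interval, lo: 35, hi: 36}
      next: {species: "G. orientalis"}
      note: "southern Ionian Sea and Aegean Sea"
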
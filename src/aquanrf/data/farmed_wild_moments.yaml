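# Two-group farmed-versus-wild finfish contrast config, transcribing the
# published habitat-stratified nutrient moments (132 farmed, 117 wild).
# The wild zinc SD is printed as "209" in the source; transcribed as 2.09.
# Sodium and saturated-fat moments are not published; plausible values are
# supplied.  Species labels cycle through the demersal vocabulary; the
# habitat contrast does not depend on species identity.
seed: 20241031
groups:
  - label: farmed_finfish
    taxon_group: demersal
    n: 132
    habitat: {farmed: 1.0}
    state: {raw: 1.0}
    salinity: {freshwater: 0.6, saltwater: 0.4}
    nutrients:
      protein: {mean: 21.30, sd: 2.79}
      iron: {mean: 0.52, sd: 0.31}
      zinc: {mean: 0.60, sd: 0.30}
      calcium: {mean: 22.31, sd: 19.10, family: lognormal}
      potassium: {mean: 350.48, sd: 66.59}
      magnesium: {mean: 26.97, sd: 3.73}
      selenium: {mean: 24.51, sd: 9.83}
      folate: {mean: 9.28, sd: 3.15}
      vitamin_b12: {mean: 2.94, sd: 1.48}
      vitamin_a: {mean: 10.47, sd: 5.36}
      vitamin_d: {mean: 6.50, sd: 6.61, family: lognormal}
      omega3: {mean: 0.88, sd: 0.99, family: lognormal}
      total_fat: {mean: 6.90, sd: 4.96, family: lognormal}
      saturated_fat: {mean: 1.6, sd: 1.0}
      sodium: {mean: 70.0, sd: 30.0}
  - label: wild_finfish
    taxon_group: demersal
    n: 117
    habitat: {wild: 1.0}
    state: {raw: 1.0}
    salinity: {saltwater: 0.7, freshwater: 0.3}
    nutrients:
      protein: {mean: 21.80, sd: 2.67}
      iron: {mean: 0.68, sd: 0.77, family: lognormal}
      zinc: {mean: 1.19, sd: 2.09, family: lognormal}
      calcium: {mean: 26.55, sd: 17.12, family: lognormal}
      potassium: {mean: 389.60, sd: 70.49}
      magnesium: {mean: 30.52, sd: 4.77}
      selenium: {mean: 34.62, sd: 14.27}
      folate: {mean: 9.55, sd: 3.31}
      vitamin_b12: {mean: 4.34, sd: 3.85, family: lognormal}
      vitamin_a: {mean: 8.38, sd: 9.37, family: lognormal}
      vitamin_d: {mean: 7.33, sd: 9.82, family: lognormal}
      omega3: {mean: 0.72, sd: 0.87, family: lognormal}
      total_fat: {mean: 3.24, sd: 3.57, family: lognormal}
      saturated_fat: {mean: 0.7, sd: 0.5}
      sodium: {mean: 75.0, sd: 30.0}
prices: []
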
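{
  "name": "urambo",
  "n_informants": 55,
  "description": "Respiratory-ailment medicinal plant survey, Urambo District, mid-western Tanzania: 42 species, 28 families, 55 traditional health practitioners.",
  "count_inversion": "Raw use reports were never published. Integer counts were reconstructed from the printed indices with N = 55: FC = round(RFC*55), U = round(UV*55), fc = round(FIV*55/100), and verified to re-round to every printed index value.",
  "fiv_rounding": "The printed FIV column follows a two-stage rounding chain (percentage half-up to one decimal, then to an integer), so fc/N*100 = 25.4545 prints as 26. Reproduced cells use that chain. RFC/UV use single-stage half-up at 3 decimals.",
  "synthetic_components": [
    "informants.csv: 55 synthetic rows; marginal counts per attribute equal the published profile exactly, the joint assignment is an arbitrary seeded permutation (the survey publishes only margins).",
    "use_reports.csv: header-only; no raw reports exist to transcribe.",
    "preparation_codes/administration_codes in plants.csv: controlled-vocabulary codes derived from the free-text preparation notes, for use by the synthetic generator."
  ],
  "adjustments": [
    "Ailment entries 'cold' (Chenopodium opulifolium, Citrus limon, Zingiber officinale) and 'throat infection' (Zingiber officinale) omitted from plants.csv: no total label-to-category map over the verbatim ailment column reproduces the published per-category species counts (colds 9, flu 8, sore throat 3) with them present.",
    "Part code printed as bare 'S' for Syzygium aromaticum encoded as 'flower' (the abbreviation key defines S only as the shrub life form; Se is seed). The clove of commerce is the flower bud."
  ],
  "discrepancies": {
    "PPV[root]": "parts column gives 16 root species (38.1%); the survey text prints 35.7% (15/42).",
    "PPV[flower]": "parts column with S->flower gives 3 flower species (7.1%); the text prints 4.8% (2/42).",
    "sum_U_vs_sum_Nur": "per-species use reports sum to 667 but per-category reports sum to 733; both tables kept as printed (independent inversions).",
    "fiv_text_vs_table": "survey text prints Musaceae 5% and Solanaceae 7% where the table prints 6 and 9; the fixture follows the table.",
    "source_cultivated_rounding": "8/42 cultivated-only species = 19.05%, printed as 19.1%."
  },
  "excluded_regression_cells": []
}
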
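{
  "name": "microphthalmid_morphology",
  "description": "Discrete morphological character matrix for microphthalmid polychaetes and outgroups: 38 taxa scored for 48 unordered characters; '-' marks inapplicable cells (treated as equivocal).",
  "n_taxa": 38,
  "n_chars": 48,
  "outgroup": [
    "N. punctata",
    "O. flexuosus",
    "S. phuketensis"
  ],
  "label_corrections": {
    "M. indefstigstus": "M. indefatigatus",
    "H. pecularis": "H. peculiaris",
    "M. riser": "M. riseri",
    "M. monilicormis": "M. monilicornis",
    "H. indoceanica": "H. indooceanica",
    "M. pseudoaberrans": "M. pseudaberrans",
    "M. ancistrosyllisformis": "M. ancistrosylliformis",
    "S. camposi n. sp.": "S. camposi"
  },
  "label_corrections_note": "Published matrix rows carry evident typographic variants of the species list spellings; keys are the as-printed labels, values the normalized labels used here."
}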
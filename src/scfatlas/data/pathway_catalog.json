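{
  "description": "Butyrate/propionate pathway catalog for gut Clostridia. Routes converge at crotonyl-CoA (butyrate) or propionyl-CoA (propionate); terminal branches finish the acid; crossfeed pathways cover acetate/lactate utilisation. Block inventories of B2, B4 (beyond ato) and P1 follow the standard fermentation ladders and are editable catalog content.",
  "blocks": {
    "thl": {"name": "thiolase (acetyl-CoA acetyltransferase)", "ec": "2.3.1.9"},
    "hbd": {"name": "3-hydroxybutyryl-CoA dehydrogenase", "ec": "1.1.1.157"},
    "cro": {"name": "crotonase (3-hydroxybutyryl-CoA dehydratase)", "ec": "4.2.1.55"},
    "hbd4": {"name": "4-hydroxybutyrate dehydrogenase", "ec": "1.1.1.61"},
    "cat2": {"name": "4-hydroxybutyrate CoA-transferase", "ec": "2.8.3.-"},
    "abfd": {"name": "4-hydroxybutyryl-CoA dehydratase", "ec": "4.2.1.120"},
    "oxoglutarate_reductase": {"name": "2-oxoglutarate reductase", "ec": "1.1.1.399"},
    "gct": {"name": "glutaconate CoA-transferase", "ec": "2.8.3.12"},
    "hgd": {"name": "2-hydroxyglutaryl-CoA dehydratase", "ec": "4.2.1.-"},
    "gcd": {"name": "glutaconyl-CoA decarboxylase", "ec": "7.2.4.5"},
    "kamA": {"name": "lysine 2,3-aminomutase", "ec": "5.4.3.2"},
    "kamDE": {"name": "beta-lysine 5,6-aminomutase", "ec": "5.4.3.3"},
    "kdd": {"name": "3,5-diaminohexanoate dehydrogenase", "ec": "1.4.1.11"},
    "kce": {"name": "3-keto-5-aminohexanoate cleavage enzyme", "ec": "2.3.1.247"},
    "kal": {"name": "3-aminobutyryl-CoA ammonia-lyase", "ec": "4.3.1.14"},
    "ato": {"name": "acetoacetate CoA-transferase (ato)", "ec": "2.8.3.9"},
    "sct": {"name": "succinyl-CoA:acetate CoA-transferase", "ec": "2.8.3.18"},
    "mcm": {"name": "methylmalonyl-CoA mutase", "ec": "5.4.99.2"},
    "mce": {"name": "methylmalonyl-CoA epimerase", "ec": "5.1.99.1"},
    "mmc_carboxytransferase": {"name": "methylmalonyl-CoA carboxytransferase", "ec": "2.1.3.1"},
    "lct": {"name": "propionate:lactoyl-CoA transferase", "ec": "2.8.3.1"},
    "lcdA": {"name": "lactoyl-CoA dehydratase (lcdA)", "ec": "4.2.1.54"},
    "acr": {"name": "acryloyl-CoA reductase", "ec": "1.3.1.95"},
    "pduCDE": {"name": "propanediol dehydratase", "ec": "4.2.1.28"},
    "pduP": {"name": "propanal dehydrogenase (CoA-acylating)", "ec": "1.2.1.87"},
    "bcd": {"name": "butyryl-CoA dehydrogenase (with ETF)", "ec": "1.3.8.1"},
    "but": {"name": "butyryl-CoA:acetate CoA-transferase (but)", "ec": "2.8.3.8"},
    "ptb": {"name": "phosphate butyryltransferase", "ec": "2.3.1.19"},
    "buk": {"name": "butyrate kinase (buk)", "ec": "2.7.2.7"},
    "ptp": {"name": "phosphate propionyltransferase", "ec": "2.3.1.222"},
    "pk": {"name": "propionate kinase", "ec": "2.7.2.15"},
    "pct": {"name": "propionyl-CoA:lactate/acetate CoA-transferase", "ec": "2.8.3.1"},
    "ack": {"name": "acetate kinase", "ec": "2.7.2.1"},
    "pta": {"name": "phosphate acetyltransferase", "ec": "2.3.1.8"},
    "acs": {"name": "AMP-forming acetyl-CoA synthetase", "ec": "6.2.1.1"},
    "ldh": {"name": "D/L-lactate dehydrogenase", "ec": "1.1.1.27"},
    "pfor": {"name": "pyruvate:ferredoxin oxidoreductase", "ec": "1.2.7.1"}
  },
  "pathways": [
    {"pathway_id": "B1_acetylCoA", "name": "acetyl-CoA (thiolase) route", "role": "route", "product": "crotonyl-CoA", "blocks": ["thl", "hbd", "cro"]},
    {"pathway_id": "B2_succinate_semialdehyde", "name": "succinate semialdehyde route", "role": "route", "product": "crotonyl-CoA", "blocks": ["hbd4", "cat2", "abfd"]},
    {"pathway_id": "B3_glutarate", "name": "glutarate route", "role": "route", "product": "crotonyl-CoA", "blocks": ["oxoglutarate_reductase", "gct", "hgd", "gcd"]},
    {"pathway_id": "B4_lysine", "name": "lysine fermentation route", "role": "route", "product": "crotonyl-CoA", "blocks": ["kamA", "kamDE", "kdd", "kce", "kal", "ato"]},
    {"pathway_id": "P1_succinate", "name": "succinate route", "role": "route", "product": "propionyl-CoA", "blocks": ["sct", "mcm", "mce", "mmc_carboxytransferase"]},
    {"pathway_id": "P2_acrylate", "name": "acrylate route", "role": "route", "product": "propionyl-CoA", "blocks": ["lct", "lcdA", "acr"]},
    {"pathway_id": "P3_propanediol", "name": "propanediol route", "role": "route", "product": "propionyl-CoA", "blocks": ["pduCDE", "pduP"]},
    {"pathway_id": "TB_bcd", "name": "crotonyl-CoA to butyryl-CoA (bcd)", "role": "terminal", "product": "butyryl-CoA", "blocks": ["bcd"]},
    {"pathway_id": "TB_but", "name": "but branch (butyryl-CoA:acetate CoA-transferase)", "role": "terminal", "product": "butyrate", "blocks": ["but"]},
    {"pathway_id": "TB_buk", "name": "buk branch (phosphate butyryltransferase + butyrate kinase)", "role": "terminal", "product": "butyrate", "blocks": ["ptb", "buk"]},
    {"pathway_id": "TP_pta_pk", "name": "phosphate propionyltransferase + propionate kinase branch", "role": "terminal", "product": "propionate", "blocks": ["ptp", "pk"]},
    {"pathway_id": "TP_ct", "name": "propionyl-CoA:lactate/acetate transferase branch", "role": "terminal", "product": "propionate", "blocks": ["pct"]},
    {"pathway_id": "XF_acetate_akpta", "name": "acetate utilisation (acetate kinase + phosphate acetyltransferase)", "role": "crossfeed", "product": "acetyl-CoA", "blocks": ["ack", "pta"]},
    {"pathway_id": "XF_acetate_acs", "name": "acetate utilisation (AMP-forming acetyl-CoA synthetase)", "role": "crossfeed", "product": "acetyl-CoA", "blocks": ["acs"]},
    {"pathway_id": "XF_lactate", "name": "lactate utilisation (D/L-LDH + pyruvate:ferredoxin oxidoreductase)", "role": "crossfeed", "product": "acetyl-CoA", "blocks": ["ldh", "pfor"]}
  ]
}
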
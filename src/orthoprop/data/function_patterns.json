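{
  "comment": "Editable pattern lists for the product function-name classifier. 'unknown' entries match as whole-word prefixes anywhere in the name (case-insensitive). 'vague' entries match only when the entire name is the term, optionally preceded by generic qualifiers and an optional plural 's'.",
  "unknown": [
    "hypothetical protein",
    "hypothetical",
    "orf",
    "uncharacterized",
    "uncharacterised",
    "unknown function",
    "unknown protein",
    "duf",
    "upf",
    "domain-containing protein",
    "putative protein",
    "predicted protein",
    "conserved protein",
    "protein of unknown function",
    "ycf"
  ],
  "vague": [
    "transporter",
    "transport protein",
    "transport system",
    "oxidoreductase",
    "regulatory protein",
    "regulator",
    "transcriptional regulator",
    "response regulator",
    "permease",
    "membrane protein",
    "inner membrane protein",
    "outer membrane protein",
    "hydrolase",
    "kinase",
    "phosphatase",
    "transferase",
    "acyltransferase",
    "methyltransferase",
    "glycosyltransferase",
    "isomerase",
    "epimerase",
    "lyase",
    "ligase",
    "dehydrogenase",
    "reductase",
    "oxidase",
    "synthase",
    "synthetase",
    "protease",
    "peptidase",
    "metalloprotease",
    "metalloproteinase",
    "esterase",
    "nuclease",
    "helicase",
    "atpase",
    "gtpase",
    "binding protein",
    "dna-binding protein",
    "rna-binding protein",
    "lipoprotein",
    "efflux pump",
    "enzyme",
    "receptor",
    "chaperone",
    "cytochrome"
  ],
  "qualifiers": [
    "putative",
    "probable",
    "possible",
    "predicted",
    "conserved",
    "mfs",
    "abc",
    "abc-type",
    "mfs-type",
    "major facilitator superfamily",
    "major facilitator family",
    "family",
    "superfamily",
    "type",
    "class",
    "group",
    "inner membrane",
    "outer membrane",
    "membrane",
    "periplasmic",
    "cytoplasmic",
    "general",
    "broad-specificity",
    "broad specificity",
    "small",
    "large",
    "molecular",
    "metal-dependent",
    "zinc-dependent",
    "atp-dependent",
    "nad-dependent",
    "nadp-dependent",
    "lysr family",
    "lysr-type",
    "arac family",
    "tetr family",
    "helix-turn-helix",
    "two-component",
    "two-component system",
    "drug",
    "multidrug",
    "sugar",
    "amino acid",
    "c4-dicarboxylate",
    "cation",
    "anion",
    "divalent"
  ]
}
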
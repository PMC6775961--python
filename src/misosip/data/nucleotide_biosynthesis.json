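{
  "name": "methanogen-nucleotide-biosynthesis",
  "description": "Carbon atom fates from methanol (methyl-H4SPT) and DIC into ribose-5-phosphate (reverse gluconeogenesis + reverse ribulose monophosphate route) and the pyrimidine and purine bases. Atom order within each compound follows chemical numbering noted per reaction.",
  "sources": ["MEOH", "DIC"],
  "compounds": [
    {"name": "methyl-H4SPT", "n_carbons": 1},
    {"name": "formyl-H4SPT", "n_carbons": 1},
    {"name": "acetyl-CoA", "n_carbons": 2},
    {"name": "pyruvate", "n_carbons": 3},
    {"name": "fructose-6-phosphate", "n_carbons": 6},
    {"name": "ribulose-5-phosphate", "n_carbons": 5},
    {"name": "ribose-5-phosphate", "n_carbons": 5},
    {"name": "oxaloacetate", "n_carbons": 4},
    {"name": "aspartate", "n_carbons": 4},
    {"name": "serine", "n_carbons": 3},
    {"name": "glycine", "n_carbons": 2},
    {"name": "pyrimidine-base", "n_carbons": 4},
    {"name": "purine-base", "n_carbons": 5}
  ],
  "reactions": [
    {
      "product": "methyl-H4SPT",
      "assignments": ["MEOH"],
      "lost": [],
      "note": "Methanol methyl group transferred onto tetrahydrosarcinapterin."
    },
    {
      "product": "formyl-H4SPT",
      "assignments": [["methyl-H4SPT", 0]],
      "lost": [],
      "note": "Oxidation of the carrier-bound methyl to the formyl level (reversible C1 interconversion on H4SPT); the carbon atom is unchanged, so C1 units donated at the formyl/methenyl level are methanol-derived."
    },
    {
      "product": "acetyl-CoA",
      "assignments": ["DIC", ["methyl-H4SPT", 0]],
      "lost": [],
      "note": "CODH/ACS: carbonyl (atom 0) from CO2, methyl (atom 1) from methyl-H4SPT."
    },
    {
      "product": "pyruvate",
      "assignments": ["DIC", ["acetyl-CoA", 0], ["acetyl-CoA", 1]],
      "lost": [],
      "note": "Pyruvate synthase (reductive carboxylation): C1 carboxyl from CO2, C2 carbonyl from the acetyl carbonyl, C3 methyl from the acetyl methyl."
    },
    {
      "product": "fructose-6-phosphate",
      "assignments": [["pyruvate", 2], ["pyruvate", 1], ["pyruvate", 0], ["pyruvate", 0], ["pyruvate", 1], ["pyruvate", 2]],
      "lost": [],
      "note": "Reverse gluconeogenesis: two pyruvate -> PEP -> GAP/DHAP -> aldolase -> F6P. Hexose C1=pyr methyl (via DHAP), C2=pyr C2, C3=pyr carboxyl, C4=pyr carboxyl, C5=pyr C2, C6=pyr methyl: the two methanol-derived carbons sit at C1 and C6."
    },
    {
      "product": "ribulose-5-phosphate",
      "assignments": [["fructose-6-phosphate", 1], ["fructose-6-phosphate", 2], ["fructose-6-phosphate", 3], ["fructose-6-phosphate", 4], ["fructose-6-phosphate", 5]],
      "lost": [["fructose-6-phosphate", 0]],
      "note": "Reverse ribulose monophosphate route: hexulose-6-phosphate cleavage releases C1 as formaldehyde, leaving the pentose C2-C6 with a single methanol-derived carbon at the former C6."
    },
    {
      "product": "ribose-5-phosphate",
      "assignments": [["ribulose-5-phosphate", 0], ["ribulose-5-phosphate", 1], ["ribulose-5-phosphate", 2], ["ribulose-5-phosphate", 3], ["ribulose-5-phosphate", 4]],
      "lost": [],
      "note": "Phosphopentose isomerase; carbon skeleton unchanged."
    },
    {
      "product": "oxaloacetate",
      "assignments": [["pyruvate", 0], ["pyruvate", 1], ["pyruvate", 2], "DIC"],
      "lost": [],
      "note": "Pyruvate carboxylation: C1-C3 from pyruvate, C4 carboxyl from CO2."
    },
    {
      "product": "aspartate",
      "assignments": [["oxaloacetate", 0], ["oxaloacetate", 1], ["oxaloacetate", 2], ["oxaloacetate", 3]],
      "lost": [],
      "note": "Transamination; carbon skeleton unchanged."
    },
    {
      "product": "serine",
      "assignments": [["pyruvate", 0], ["pyruvate", 1], ["pyruvate", 2]],
      "lost": [],
      "note": "Via 3-phosphoglycerate (phosphoserine route); C1 carboxyl = pyruvate carboxyl, C3 hydroxymethyl = pyruvate methyl (methanol-derived)."
    },
    {
      "product": "glycine",
      "assignments": [["serine", 0], ["serine", 1]],
      "lost": [["serine", 2]],
      "note": "Serine hydroxymethyltransferase: C3 leaves as a methylene-C1 unit; glycine keeps the two DIC-derived carbons."
    },
    {
      "product": "pyrimidine-base",
      "assignments": ["DIC", ["aspartate", 3], ["aspartate", 2], ["aspartate", 1]],
      "lost": [["aspartate", 0]],
      "note": "Ring carbons in order C2, C4, C5, C6. C2 from carbamoyl phosphate (CO2); C4-C6 from aspartate C4, C3, C2; the aspartate alpha-carboxyl (C1) is lost on OMP decarboxylation. One of four carbons (C5) is methanol-derived."
    },
    {
      "product": "purine-base",
      "assignments": [["formyl-H4SPT", 0], ["glycine", 0], ["glycine", 1], "DIC", ["formyl-H4SPT", 0]],
      "lost": [],
      "note": "Ring carbons in order C2, C4, C5, C6, C8. C4/C5 from glycine C1/C2 (DIC-derived), C6 from CO2, C2 and C8 from two formyl-level C1 units, here methanol-derived: two of five carbons trace to methanol."
    }
  ]
}
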
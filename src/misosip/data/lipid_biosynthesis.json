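{
  "name": "archaeal-isoprenoid-lipid-biosynthesis",
  "description": "Carbon atom fates from methanol (methyl-H4SPT) and DIC through the modified mevalonate pathway to geranylgeranyl diphosphate and the phytanyl side chains of archaeol/hydroxyarchaeol. Atom order within each compound follows chemical numbering noted per reaction.",
  "sources": ["MEOH", "DIC"],
  "compounds": [
    {"name": "methyl-H4SPT", "n_carbons": 1},
    {"name": "acetyl-CoA", "n_carbons": 2},
    {"name": "acetoacetyl-CoA", "n_carbons": 4},
    {"name": "HMG-CoA", "n_carbons": 6},
    {"name": "mevalonate-5-phosphate", "n_carbons": 6},
    {"name": "IPP", "n_carbons": 5},
    {"name": "DMAPP", "n_carbons": 5},
    {"name": "GGPP", "n_carbons": 20},
    {"name": "phytanyl", "n_carbons": 20}
  ],
  "reactions": [
    {
      "product": "methyl-H4SPT",
      "assignments": ["MEOH"],
      "lost": [],
      "note": "Methanol methyl group transferred onto tetrahydrosarcinapterin (MtaABC methyltransferase)."
    },
    {
      "product": "acetyl-CoA",
      "assignments": ["DIC", ["methyl-H4SPT", 0]],
      "lost": [],
      "note": "CODH/ACS: carbonyl (atom 0) from CO2, methyl (atom 1) from methyl-H4SPT. Only the two transferred carbons are counted; CoA carbons are carrier atoms."
    },
    {
      "product": "acetoacetyl-CoA",
      "assignments": [["acetyl-CoA", 0], ["acetyl-CoA", 1], ["acetyl-CoA", 0], ["acetyl-CoA", 1]],
      "lost": [],
      "note": "Thiolase Claisen condensation of two acetyl-CoA. Atoms C1(thioester C)=carbonyl of acceptor, C2=its methyl, C3(keto)=carbonyl of donor, C4(methyl)=its methyl."
    },
    {
      "product": "HMG-CoA",
      "assignments": [["acetyl-CoA", 0], ["acetyl-CoA", 1], ["acetoacetyl-CoA", 2], ["acetoacetyl-CoA", 3], ["acetoacetyl-CoA", 1], ["acetoacetyl-CoA", 0]],
      "lost": [],
      "note": "HMG-CoA synthase. Atoms: C1 carboxyl (acetyl carbonyl), C2 (acetyl methyl), C3 quaternary (acetoacetyl C3), C3' branch methyl (acetoacetyl C4), C4 (acetoacetyl C2), C5 thioester (acetoacetyl C1)."
    },
    {
      "product": "mevalonate-5-phosphate",
      "assignments": [["HMG-CoA", 0], ["HMG-CoA", 1], ["HMG-CoA", 2], ["HMG-CoA", 3], ["HMG-CoA", 4], ["HMG-CoA", 5]],
      "lost": [],
      "note": "Reduction and phosphorylation; carbon skeleton unchanged."
    },
    {
      "product": "IPP",
      "assignments": [["mevalonate-5-phosphate", 1], ["mevalonate-5-phosphate", 2], ["mevalonate-5-phosphate", 3], ["mevalonate-5-phosphate", 4], ["mevalonate-5-phosphate", 5]],
      "lost": [["mevalonate-5-phosphate", 0]],
      "note": "Decarboxylation loses the C1 carboxyl (DIC-derived); three of the five remaining carbons trace to methanol."
    },
    {
      "product": "DMAPP",
      "assignments": [["IPP", 0], ["IPP", 1], ["IPP", 2], ["IPP", 3], ["IPP", 4]],
      "lost": [],
      "note": "IPP isomerase; no carbon change."
    },
    {
      "product": "GGPP",
      "assignments": [["DMAPP", 0], ["DMAPP", 1], ["DMAPP", 2], ["DMAPP", 3], ["DMAPP", 4],
                      ["IPP", 0], ["IPP", 1], ["IPP", 2], ["IPP", 3], ["IPP", 4],
                      ["IPP", 0], ["IPP", 1], ["IPP", 2], ["IPP", 3], ["IPP", 4],
                      ["IPP", 0], ["IPP", 1], ["IPP", 2], ["IPP", 3], ["IPP", 4]],
      "lost": [],
      "note": "Head-to-tail condensation of DMAPP with three IPP units (GGPP synthase); all 20 carbons retained."
    },
    {
      "product": "phytanyl",
      "assignments": [["GGPP", 0], ["GGPP", 1], ["GGPP", 2], ["GGPP", 3], ["GGPP", 4],
                      ["GGPP", 5], ["GGPP", 6], ["GGPP", 7], ["GGPP", 8], ["GGPP", 9],
                      ["GGPP", 10], ["GGPP", 11], ["GGPP", 12], ["GGPP", 13], ["GGPP", 14],
                      ["GGPP", 15], ["GGPP", 16], ["GGPP", 17], ["GGPP", 18], ["GGPP", 19]],
      "lost": [],
      "note": "Saturation of the geranylgeranyl chain after ether-bond formation; the phytane/phytene moieties released by ether cleavage carry these 20 carbons."
    }
  ]
}
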
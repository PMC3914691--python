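{
  "comment": "Candidate ancestral-karyotype scenarios for the grass paleotetraploidy, judged against the observed post-WGD (n=12) dominance/centromere labels. The arm fission of A12 plus translocation of its acentric fragment onto A3 in the n=7 scenario encodes the ancestral A3-A12 translocation; its placement is interpretive (the narrative does not tie the single fission to a named chromosome).",
  "observed": {
    "A1": {"dominance": "D"},
    "A2": {"dominance": "D", "segments": ["D", "S"]},
    "A3": {"dominance": "D", "segments": ["D", "D"]},
    "A4": {"dominance": "D"},
    "A5": {"dominance": "S"},
    "A6": {"dominance": "S"},
    "A7": {"dominance": "S"},
    "A8": {"dominance": "S"},
    "A9": {"dominance": "D"},
    "A10": {"dominance": "S"},
    "A11": {"dominance": "D"},
    "A12": {"dominance": "S"}
  },
  "scenarios": [
    {
      "id": "scenario1_n5",
      "description": "n=5 ancestor (A4,A5,A7,A8,A11) in which sensitive A5/A7/A8 produce dominant A1/A3/A9 after WGD; triplications resolved by centromeric fissions and fusions.",
      "ancestor": [
        {"name": "A4", "dominance": "D"},
        {"name": "A5", "dominance": "S"},
        {"name": "A7", "dominance": "S"},
        {"name": "A8", "dominance": "S"},
        {"name": "A11", "dominance": "D"}
      ],
      "events": [
        {"kind": "WGD", "operands": {"copies": {
          "A5": [["A5", "S"], ["A1", "D"]],
          "A7": [["A7", "S"], ["A10", "S"]],
          "A8": [["A8", "S"], ["A9", "D"]],
          "A4": [["A4", "D"], ["A6", "S"]],
          "A11": [["A11", "D"], ["A12", "S"]]
        }}},
        {"kind": "fission", "operands": {"chrom": "A7", "products": ["A7", "A7l"], "mode": "centromeric"}},
        {"kind": "fission", "operands": {"chrom": "A10", "products": ["A10", "A10s"], "mode": "centromeric"}},
        {"kind": "CCF", "operands": {"chroms": ["A7l", "A10s"], "name": "A3"}},
        {"kind": "fission", "operands": {"chrom": "A4", "products": ["A4", "A4x"], "mode": "centromeric"}},
        {"kind": "fission", "operands": {"chrom": "A6", "products": ["A6", "A6x"], "mode": "centromeric"}},
        {"kind": "CCF", "operands": {"chroms": ["A4x", "A6x"], "name": "A2"}},
        {"kind": "fission", "operands": {"chrom": "A12", "products": ["A12", "A12f"], "mode": "arm"}},
        {"kind": "CCF", "operands": {"chroms": ["A3", "A12f"], "name": "A3"}}
      ]
    },
    {
      "id": "scenario2_n5",
      "description": "n=5 dominant ancestor (A1,A3,A4,A9,A11); the sensitive WGD copies A3' and A4' are split by centromeric fissions into A7/A10 and A6/A2.",
      "ancestor": [
        {"name": "A1", "dominance": "D"},
        {"name": "A3", "dominance": "D"},
        {"name": "A4", "dominance": "D"},
        {"name": "A9", "dominance": "D"},
        {"name": "A11", "dominance": "D"}
      ],
      "events": [
        {"kind": "WGD", "operands": {"copies": {
          "A1": [["A1", "D"], ["A5", "S"]],
          "A9": [["A9", "D"], ["A8", "S"]],
          "A11": [["A11", "D"], ["A12", "S"]],
          "A3": [["A3", "D"], ["A3p", "S"]],
          "A4": [["A4", "D"], ["A4p", "S"]]
        }}},
        {"kind": "fission", "operands": {"chrom": "A3p", "products": ["A7", "A10"], "mode": "centromeric"}},
        {"kind": "fission", "operands": {"chrom": "A4p", "products": ["A6", "A2"], "mode": "centromeric"}}
      ]
    },
    {
      "id": "scenario3_n7",
      "description": "n=7 dominant ancestor (A1,A9,A11,A4,A6',A7',A10'); A3 = TCF of A10'(D)+A7'(D), A2 = CCF of A6'(D)+A4'(S); ancestral A3-A12 translocation as arm fission of A12 plus fragment join.",
      "ancestor": [
        {"name": "A1", "dominance": "D"},
        {"name": "A9", "dominance": "D"},
        {"name": "A11", "dominance": "D"},
        {"name": "A4", "dominance": "D"},
        {"name": "A6p", "dominance": "D"},
        {"name": "A7p", "dominance": "D"},
        {"name": "A10p", "dominance": "D"}
      ],
      "events": [
        {"kind": "WGD", "operands": {"copies": {
          "A1": [["A1", "D"], ["A5", "S"]],
          "A9": [["A9", "D"], ["A8", "S"]],
          "A11": [["A11", "D"], ["A12", "S"]],
          "A4": [["A4", "D"], ["A4p", "S"]],
          "A6p": [["A6p", "D"], ["A6", "S"]],
          "A7p": [["A7p", "D"], ["A7", "S"]],
          "A10p": [["A10p", "D"], ["A10", "S"]]
        }}},
        {"kind": "TCF", "operands": {"chroms": ["A10p", "A7p"], "name": "A3"}},
        {"kind": "CCF", "operands": {"chroms": ["A6p", "A4p"], "name": "A2"}},
        {"kind": "fission", "operands": {"chrom": "A12", "products": ["A12", "A12f"], "mode": "arm"}},
        {"kind": "translocation", "operands": {"frag": "A12f", "to": "A3"}}
      ]
    },
    {
      "id": "scenario4_n6",
      "description": "n=6 hybrid: fusion origin for A3 (as in n=7) but fission origin for A2-A4-A6 (as in n=5).",
      "ancestor": [
        {"name": "A1", "dominance": "D"},
        {"name": "A9", "dominance": "D"},
        {"name": "A11", "dominance": "D"},
        {"name": "A4", "dominance": "D"},
        {"name": "A7p", "dominance": "D"},
        {"name": "A10p", "dominance": "D"}
      ],
      "events": [
        {"kind": "WGD", "operands": {"copies": {
          "A1": [["A1", "D"], ["A5", "S"]],
          "A9": [["A9", "D"], ["A8", "S"]],
          "A11": [["A11", "D"], ["A12", "S"]],
          "A4": [["A4", "D"], ["A4p", "S"]],
          "A7p": [["A7p", "D"], ["A7", "S"]],
          "A10p": [["A10p", "D"], ["A10", "S"]]
        }}},
        {"kind": "TCF", "operands": {"chroms": ["A10p", "A7p"], "name": "A3"}},
        {"kind": "fission", "operands": {"chrom": "A4p", "products": ["A6", "A2"], "mode": "centromeric"}}
      ]
    },
    {
      "id": "scenario5_n6",
      "description": "n=6 hybrid: fusion origin for A2 (as in n=7) but fission origin for A3-A7-A10 (as in n=5).",
      "ancestor": [
        {"name": "A1", "dominance": "D"},
        {"name": "A9", "dominance": "D"},
        {"name": "A11", "dominance": "D"},
        {"name": "A4", "dominance": "D"},
        {"name": "A6p", "dominance": "D"},
        {"name": "A3", "dominance": "D"}
      ],
      "events": [
        {"kind": "WGD", "operands": {"copies": {
          "A1": [["A1", "D"], ["A5", "S"]],
          "A9": [["A9", "D"], ["A8", "S"]],
          "A11": [["A11", "D"], ["A12", "S"]],
          "A4": [["A4", "D"], ["A4p", "S"]],
          "A6p": [["A6p", "D"], ["A6", "S"]],
          "A3": [["A3", "D"], ["A3p", "S"]]
        }}},
        {"kind": "CCF", "operands": {"chroms": ["A6p", "A4p"], "name": "A2"}},
        {"kind": "fission", "operands": {"chrom": "A3p", "products": ["A7", "A10"], "mode": "centromeric"}}
      ]
    }
  ]
}
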
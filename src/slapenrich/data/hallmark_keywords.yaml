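# Demonstration keyword map routing pathway gene sets onto the ten
# canonical cancer hallmarks.  name_keywords are matched case-insensitively
# as substrings of the pathway name; gene_keywords are matched as prefixes
# of member gene symbols (key nodes).  A production analysis should supply
# its own, fully curated map in this same format.
Sustaining proliferative signaling:
  name_keywords: ["proliferat", "growth factor", "EGFR"]
  gene_keywords: []
Evading growth suppressors:
  name_keywords: ["growth suppress", "RB1", "cell cycle checkpoint"]
  gene_keywords: ["RB1"]
Resisting cell death:
  name_keywords: ["apopto", "programmed cell death"]
  gene_keywords: ["BCL2"]
Enabling replicative immortality:
  name_keywords: ["telomer", "senescence"]
  gene_keywords: ["TERT"]
Inducing angiogenesis:
  name_keywords: ["angiogen", "VEGF"]
  gene_keywords: ["VEGF"]
Activating invasion and metastasis:
  name_keywords: ["metasta", "matrix metalloprotein", "invasion"]
  gene_keywords: ["MMP"]
Genome instability and mutation:
  name_keywords: ["DNA repair", "DNA damage"]
  gene_keywords: []
Tumour-promoting inflammation:
  name_keywords: ["inflammat", "cytokine"]
  gene_keywords: ["TGF", "SMAD", "IFN"]
Deregulating cellular energetics:
  name_keywords: ["glycolysis", "warburg", "energetic"]
  gene_keywords: []
Avoiding immune destruction:
  name_keywords: ["immune", "antigen present"]
  gene_keywords: []
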
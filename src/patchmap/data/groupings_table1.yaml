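# Default lineage-grouping assumptions for origin counting.
#
# "ancient" modes contribute a single origin however widely they are
# spread: respiration (He) is shared by the greatest variety of lineages
# in both domains, and methanogenesis (Me) spans seven euryarchaeal
# lineages, so both are treated as ancestral with secondary loss.
#
# Merge rules collapse lineages assumed to share one origin of a trait.
ancient: [He, Me]
merges:
  - label: proteobacteria
    lineages:
      - proteobacteria_alpha
      - proteobacteria_beta
      - proteobacteria_gamma
      - proteobacteria_delta
      - proteobacteria_epsilon
    modes: all
    note: common origin assumed for the proteobacterial subgroups
  - label: euryarchaeal_iron_oxidizers
    lineages:
      - archaeglobi
      - thermoplasmata
      - unclassified_euryarchaea
    modes: [FO]
    note: >
      common origin assumed for iron oxidation in the archaeoglobi, the
      thermoplasmata and the unclassified euryarchaeon
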
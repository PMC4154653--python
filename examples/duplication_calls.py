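"""Classify extra gene copies in a gene tree against a species backbone.

Builds a small gene tree containing the classic call patterns — two
species-specific duplication pairs, a duplication predating a species
split, a copy nested among a foreign lineage, and an ancient paralog
clade — and prints the call for every extra copy.
"""

from patchmap.gene_tree_classifier import (
    GeneFamily,
    SupportThresholds,
    classify_copy,
    detect_paralog_clade,
    extra_copies,
)
from patchmap.phylo import tree_from_string

GENE_TREE = """(
  (
    ((Pe_carFR__c1,Pe_carFR__c2)0.99/95,De_vulSR__c1,De_oleHe__c1)0.96/88,
    (Th_marHe__c1,(Th_petHe__c1,De_oleHe__c2)0.98/85)0.99/95,
    ((Sa_eryHe__c1,Sa_eryHe__c2)1.0/99,My_tubHe__c1)0.97/90,
    ((My_agaHe__c2,Ur_parHe__c2)0.99/92,(My_agaHe__c1,Ur_parHe__c1)0.99/92)0.96/85,
    ((Rh_palFO__c1,Ba_japAP__c1)0.9/70,(Sy_700OP__c1,Sy_eloOP__c1)0.9/70)0.5/40
  )0.9/60,
  (Pe_carFR__c3,Rh_palFO__c2,Sy_700OP__c2)1.0/98
);"""

LINEAGES = {
    "Pe_carFR": "proteobacteria_delta", "De_oleHe": "proteobacteria_delta",
    "De_vulSR": "proteobacteria_delta", "Sa_eryHe": "actinobacteria",
    "My_tubHe": "actinobacteria", "Th_marHe": "thermotogae",
    "Th_petHe": "thermotogae", "My_agaHe": "tenericutes",
    "Ur_parHe": "tenericutes", "Rh_palFO": "proteobacteria_alpha",
    "Ba_japAP": "proteobacteria_alpha", "Sy_700OP": "cyanobacteria",
    "Sy_eloOP": "cyanobacteria",
}

BACKBONE = tree_from_string(
    "(thermotogae,proteobacteria_delta,proteobacteria_gamma,"
    "proteobacteria_alpha,actinobacteria,tenericutes,cyanobacteria);"
)

family = GeneFamily.from_newick(GENE_TREE, lineage_map=LINEAGES)
thresholds = SupportThresholds()

print("extra copies per species:", extra_copies(family))
clade = detect_paralog_clade(family, min_lineages=3, thresholds=thresholds)
print("paralog clade:", sorted(lf.taxon.label for lf in clade.leaf_iter()))
print()
dup_species = set(extra_copies(family))
for leaf in family.tree.leaf_node_iter():
    label = leaf.taxon.label
    if family.species_of(label) not in dup_species:
        continue
    call = classify_copy(family, BACKBONE, label, thresholds, min_lineages=3)
    donor = f"  donor={call.donor_lineage}" if call.donor_lineage else ""
    print(f"{label:16s} -> {call.call}{donor}")
print()
print("SSD/LSD: duplication within one species / before a species split;")
print("HGT_candidate nests among a foreign lineage with robust support;")
print("paralog_clade marks an anciently transferred additional locus.")
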
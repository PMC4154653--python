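"""Shared fixtures: packaged tables, the lineage backbone, and a hand-built
gene-tree modeled on the published subunit-a phylogeny."""

from __future__ import annotations

import pytest

from patchmap import datasets
from patchmap.gene_tree_classifier import GeneFamily
from patchmap.phylo import tree_from_string
from patchmap.trait_tables import build_trait_matrix


@pytest.fixture(scope="session")
def table1_records():
    return datasets.load_table1_species()


@pytest.fixture(scope="session")
def trait_matrix(table1_records):
    return build_trait_matrix(table1_records)


@pytest.fixture(scope="session")
def default_groupings():
    return datasets.load_default_groupings()


@pytest.fixture(scope="session")
def fig4_loci():
    return datasets.load_fig4_loci()


@pytest.fixture(scope="session")
def natpase_loci():
    return datasets.load_fig4_natpase_loci()


#: Lineage-level species backbone (lineages as a root polytomy).
BACKBONE_NEWICK = (
    "(thermotogae,proteobacteria_delta,proteobacteria_gamma,"
    "proteobacteria_alpha,actinobacteria,tenericutes,cyanobacteria);"
)

#: Lineages of the species appearing in the gene-tree fixture.
LINEAGE_MAP = {
    "Pe_carFR": "proteobacteria_delta",
    "De_oleHe": "proteobacteria_delta",
    "De_vulSR": "proteobacteria_delta",
    "Sa_eryHe": "actinobacteria",
    "My_tubHe": "actinobacteria",
    "Th_marHe": "thermotogae",
    "Th_petHe": "thermotogae",
    "My_agaHe": "tenericutes",
    "Ur_parHe": "tenericutes",
    "Rh_palFO": "proteobacteria_alpha",
    "Ba_japAP": "proteobacteria_alpha",
    "Sy_700OP": "cyanobacteria",
    "Sy_eloOP": "cyanobacteria",
}

#: Gene tree with: two species-specific duplication pairs (Pe_carFR,
#: Sa_eryHe); a lineage-specific pre-split duplication shared by the two
#: tenericutes; a copy nested among the thermotogae (transfer candidate);
#: and a robust multi-lineage clade of extra copies (ancient paralog locus).
GENE_TREE_NEWICK = """(
  (
    ((Pe_carFR__c1,Pe_carFR__c2)0.99/95,De_vulSR__c1,De_oleHe__c1)0.96/88,
    (Th_marHe__c1,(Th_petHe__c1,De_oleHe__c2)0.98/85)0.99/95,
    ((Sa_eryHe__c1,Sa_eryHe__c2)1.0/99,My_tubHe__c1)0.97/90,
    ((My_agaHe__c2,Ur_parHe__c2)0.99/92,(My_agaHe__c1,Ur_parHe__c1)0.99/92)0.96/85,
    ((Rh_palFO__c1,Ba_japAP__c1)0.9/70,(Sy_700OP__c1,Sy_eloOP__c1)0.9/70)0.5/40
  )0.9/60,
  (Pe_carFR__c3,Rh_palFO__c2,Sy_700OP__c2)1.0/98
);"""


@pytest.fixture()
def gene_family():
    return GeneFamily.from_newick(GENE_TREE_NEWICK, lineage_map=dict(LINEAGE_MAP))


@pytest.fixture()
def backbone():
    return tree_from_string(BACKBONE_NEWICK)
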
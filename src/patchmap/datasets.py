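"""Packaged fixtures: the lineage-by-mode census, grouping defaults, and
representative locus maps.

``table1_species.tsv`` transcribes the published lineage-by-mode species
census at lineage-count resolution: every lineage/mode cell is filled with
the printed number of species.  Named rows are real exemplar species (the
single-species lineages and the species discussed in the duplication
analysis); the remaining rows are synthetic placeholder binomials, since
the per-species list lives in a supplementary table not packaged here.
The counts, lineages, domain assignments and exemplar abbreviations are
faithful; only filler names are invented.

``fig4_loci.tsv`` carries one representative canonical ATP-synthase locus
per lineage, reconstructed from the per-lineage locus-organization summary
(split junctions, in-locus 0B duplications, documented subunit absences);
``fig4_natpase_loci.tsv`` carries N-ATPase-style example loci.
"""

from __future__ import annotations

import io
from importlib import resources

from patchmap.grouping_model import GroupingAssumptions, load_assumptions
from patchmap.locus_architect import GenomeLocus, locus_from_pattern, read_locus_table
from patchmap.trait_tables import (
    SpeciesRecord,
    make_abbreviation,
    parse_species_table,
)

__all__ = [
    "TABLE1_COUNTS",
    "FIG4_PATTERNS",
    "FIG4_NATPASE_PATTERNS",
    "build_table1_records",
    "build_fig4_loci",
    "load_table1_species",
    "load_default_groupings",
    "load_fig4_loci",
    "load_fig4_natpase_loci",
]

#: (lineage, domain group, {mode: species count}) — the published census.
TABLE1_COUNTS: list[tuple[str, str, dict[str, int]]] = [
    ("acidobacteria", "bacteria", {"He": 3, "FR": 1}),
    ("actinobacteria", "bacteria", {"He": 4, "FO": 1}),
    ("aquificae", "bacteria", {"He": 1, "SO": 1, "FR": 1}),
    ("bacteroidetes", "bacteria", {"He": 5}),
    ("chlamydiae", "bacteria", {"He": 2}),
    ("chlorobi", "bacteria", {"AP": 11}),
    ("chloroflexi", "bacteria", {"AP": 13}),
    ("chrysiogenetes", "bacteria", {"He": 1}),
    ("cyanobacteria", "bacteria", {"OP": 25}),
    ("deferribacteres", "bacteria", {"He": 2}),
    ("deinococci", "bacteria", {"He": 2, "SO": 1}),
    ("dictyoglomi", "bacteria", {"He": 2}),
    ("fibrobacteres", "bacteria", {"He": 1}),
    ("firmicutes", "bacteria", {"He": 4, "AP": 1, "SR": 3, "FR": 3, "FO": 1}),
    ("fusobacteria", "bacteria", {"He": 3}),
    ("gemmatimonadetes", "bacteria", {"He": 1}),
    ("nitrospirae", "bacteria", {"He": 1}),
    ("planctomycetes", "bacteria", {"He": 2}),
    ("proteobacteria_alpha", "bacteria", {"He": 4, "AP": 8, "FR": 1, "FO": 1}),
    ("proteobacteria_beta", "bacteria", {"He": 6, "FR": 1, "FO": 6}),
    ("proteobacteria_gamma", "bacteria",
     {"He": 5, "AP": 9, "SO": 7, "FR": 2, "FO": 4}),
    ("proteobacteria_delta", "bacteria", {"He": 1, "SR": 13, "FR": 6}),
    ("proteobacteria_epsilon", "bacteria", {"He": 3, "SfR": 2, "SO": 4}),
    ("spirochaetes", "bacteria", {"He": 4}),
    ("synergistetes", "bacteria", {"He": 2}),
    ("tenericutes", "bacteria", {"He": 5}),
    ("thermotogae", "bacteria", {"He": 5}),
    ("verrucomicrobia", "bacteria", {"He": 3}),
    ("acidilobales", "crenarchaea", {"He": 1}),
    ("desulfurococcales", "crenarchaea", {"He": 7, "SfR": 3}),
    ("sulfolobales", "crenarchaea", {"He": 4, "SO": 1, "FO": 1}),
    ("thermoproteales", "crenarchaea", {"He": 5, "SR": 3}),
    ("archaeglobi", "euryarchaea", {"SR": 2, "FO": 1}),
    ("halobacteria", "euryarchaea", {"He": 4}),
    ("methanobacteria", "euryarchaea", {"Me": 6}),
    ("methanocellales", "euryarchaea", {"Me": 2}),
    ("methanococcales", "euryarchaea", {"Me": 10}),
    ("methanomicrobiales", "euryarchaea", {"Me": 7}),
    ("methanopyri", "euryarchaea", {"Me": 1}),
    ("methanosarcinales", "euryarchaea", {"Me": 8}),
    ("thermococci", "euryarchaea", {"He": 3}),
    ("thermoplasmata", "euryarchaea", {"He": 2, "FO": 1}),
    ("unclassified_euryarchaea", "euryarchaea", {"FO": 1}),
    ("korarchaea", "korarchaea", {"He": 1}),
]

#: Real exemplar species per (lineage, mode): (full name, abbreviation
#: override or None for the standard scheme).
_EXEMPLARS: dict[tuple[str, str], list[tuple[str, str | None]]] = {
    ("fibrobacteres", "He"): [("Fibrobacter succinogenes", None)],
    ("gemmatimonadetes", "He"): [("Gemmatimonas aurantiaca", None)],
    ("nitrospirae", "He"): [("Candidatus Nitrospira defluvii", "CNi_deHe")],
    ("chrysiogenetes", "He"): [("Bacterium S5", None)],
    ("korarchaea", "He"): [("Candidatus Korarchaeum cryptofilum", "CKorarHe")],
    ("acidilobales", "He"): [("Acidilobus saccharovorans", None)],
    ("methanopyri", "Me"): [("Methanopyrus kandleri", None)],
    ("unclassified_euryarchaea", "FO"): [("Aciduliprofundum boonei", None)],
    ("proteobacteria_delta", "FR"): [("Pelobacter carbinolicus", None)],
    ("proteobacteria_delta", "He"): [("Desulfococcus oleovorans", None)],
    ("proteobacteria_gamma", "He"): [("Photobacterium profundum", None)],
    ("proteobacteria_beta", "FO"): [("Thiobacillus denitrificans", None)],
    ("proteobacteria_gamma", "FO"): [("Acidithiobacillus ferrooxidans", "At_ferFO")],
    ("actinobacteria", "He"): [("Saccharopolyspora erythraea", None)],
    ("firmicutes", "FR"): [("Alkaliphilus metalliredigens", None)],
    ("tenericutes", "He"): [("Mycoplasma agalactiae", None),
                            ("Ureaplasma parvum", None)],
    ("aquificae", "He"): [("Aquifex aeolicus", None)],
    ("cyanobacteria", "OP"): [("Nostoc sp. PCC 7120", "No_712OP"),
                              ("Synechococcus sp. PCC 7002", "Sy_700OP")],
}


def _genus(lineage: str) -> str:
    return lineage.replace("_", " ").title().replace(" ", "")


def _epithets():
    """Endless deterministic stream of synthetic species epithets whose
    first three letters are globally unique."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for c1 in letters:
        for c2 in letters:
            yield f"{c1}{c2}um"


def build_table1_records() -> list[SpeciesRecord]:
    """Synthesize the 272-species table from the census counts.

    Exemplar cells get their real species; remaining slots get synthetic
    placeholder binomials with scheme-conformant, collision-free
    abbreviations.  Deterministic.
    """
    records: list[SpeciesRecord] = []
    assigned: set[str] = set()
    epithets = _epithets()
    for lineage, domain, modes in TABLE1_COUNTS:
        for mode, count in modes.items():
            names = list(_EXEMPLARS.get((lineage, mode), []))
            while len(names) < count:
                epithet = next(epithets)
                full = f"{_genus(lineage)} {epithet}"
                try:
                    make_abbreviation(full, mode, existing=assigned)
                except ValueError:
                    continue
                names.append((full, None))
            for full, override in names[:count]:
                abbrev = override or make_abbreviation(full, mode, existing=assigned)
                assigned.add(abbrev)
                records.append(
                    SpeciesRecord(
                        full_name=full,
                        abbreviation=abbrev,
                        lineage=lineage,
                        domain_group=domain,
                        mode=mode,
                        abbrev_ok=True,
                    )
                )
    return records


#: Representative canonical locus per lineage, in pattern notation
#: (semicolons mark splits; duplicated 0B written as a raw 0B pair — the
#: prime is assigned by ``name_b_prime``, never in inputs).
FIG4_PATTERNS: dict[str, str] = {
    "dictyoglomi": "I-sI-0A-0C-0B-IA-IG-IB-IE",          # no ID
    "planctomycetes": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "firmicutes": "I-0A-0C-0B-ID-IA-IG-IB-IE",
    "thermotogae": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "chloroflexi": "0A-0C-0B-ID-IA-IG-IB-IE",            # no I/sI
    "actinobacteria": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "tenericutes": "I-0A-0C-0B-ID-IA-IG-IB-IE",
    "verrucomicrobia": "0A-0C-0B-ID-IA-IG-IB-IE",        # no I/sI
    "fusobacteria": "sI-0A-0C-0B-ID-IA-IG-IB-IE",        # no I
    "proteobacteria_beta": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "proteobacteria_gamma": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "spirochaetes": "I-sI-0A-0C-0B-ID-IA-IG-IB-IE",
    "chlorobi": "I-sI-0A-0C-0B-ID;IA-IG;IB-IE",
    "bacteroidetes": "I-sI-0A-0C-0B-ID-IA-IG;IB-IE",
    "cyanobacteria": "I-sI-0A-0C-0B-0B-ID-IA-IG;IB-IE",
    "aquificae": "I;0A-0C;0B-0B-ID-IA;IG;IB;IE",
    "nitrospirae": "I-sI-0A-0C-0B;ID-IA-IG-IB-IE",
    "proteobacteria_alpha": "I-sI-0A-0C-0B-0B;ID-IA-IG-IB-IE",
    "acidobacteria": "I-sI-0A-0C;0B-0B-ID-IA-IG-IB-IE",
    "deferribacteres": "I-sI-0A-0C;0B-0B-ID-IA-IG-IB-IE",
    "proteobacteria_delta": "I-sI-0A-0C;0B-0B-ID-IA-IG-IB-IE",
    "proteobacteria_epsilon": "I-sI-0A;0C;0B-0B-ID-IA-IG-IB-IE",
}

#: N-ATPase-style example loci (always additional to the canonical locus).
FIG4_NATPASE_PATTERNS: dict[str, str] = {
    "alpha_natpase": "IB-IE-I-R-0A-0C-0B-IA-IG",
    "delta_natpase": "IB-IE-I-R-0A-0C-0B-IA-IG",
    "bacteroides_fragilis_like": "IB-IE-I-0A-0C-0B-IA-IG",   # R-less variant
    "split_natpase_no_r": "IB-IE;I-0A-0C-0B-IA-IG",
}


def build_fig4_loci(natpase: bool = False) -> list[GenomeLocus]:
    """Materialize the per-lineage locus patterns as locus tables."""
    patterns = FIG4_NATPASE_PATTERNS if natpase else FIG4_PATTERNS
    return [locus_from_pattern(sp, pat) for sp, pat in patterns.items()]


def _read_packaged(name: str) -> str:
    return (resources.files("patchmap.data") / name).read_text()


def load_table1_species() -> list[SpeciesRecord]:
    """The packaged 272-row species table."""
    return parse_species_table(io.StringIO(_read_packaged("table1_species.tsv")))


def load_default_groupings() -> GroupingAssumptions:
    """The packaged default grouping assumptions."""
    return load_assumptions(_read_packaged("groupings_table1.yaml"))


def load_fig4_loci() -> list[GenomeLocus]:
    """The packaged canonical locus fixture (one locus per lineage)."""
    return read_locus_table(io.StringIO(_read_packaged("fig4_loci.tsv")))


def load_fig4_natpase_loci() -> list[GenomeLocus]:
    """The packaged N-ATPase-style example loci."""
    return read_locus_table(io.StringIO(_read_packaged("fig4_natpase_loci.tsv")))
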
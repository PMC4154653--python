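"""Locus segmentation, junctions, duplicate placement, signatures, and
ancestral-order inference."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchmap.locus_architect import (
    CANONICAL_ORDER,
    N_ATPASE_ORDER,
    Gene,
    GenomeLocus,
    ancestral_order,
    classify_placement,
    detect_n_atpase,
    locus_from_pattern,
    name_b_prime,
    parse_pattern,
    pattern_string,
    read_locus_table,
    segment_blocks,
    split_junctions,
    write_locus_table,
)


def locus(*indices_labels, species="sp", replicon="chr", strand="+"):
    genes = [
        Gene(label=l, replicon=replicon, orf_index=i, strand=strand)
        for i, l in indices_labels
    ]
    return GenomeLocus(species=species, genes=genes)


# --- segmentation --------------------------------------------------------


def test_four_orf_gap_splits_at_threshold_three():
    loc = locus((0, "0A"), (1, "0C"), (2, "0B"), (7, "IA"), (8, "IG"))
    blocks = segment_blocks(loc, max_intervening=3)
    assert [len(b) for b in blocks.blocks] == [3, 2]
    assert blocks.gaps == [4]


def test_contiguous_locus_is_one_block():
    loc = locus(*enumerate(CANONICAL_ORDER))
    blocks = segment_blocks(loc, max_intervening=0)
    assert len(blocks.blocks) == 1
    assert blocks.gaps == []


def test_huge_gap_reported():
    loc = locus((0, "IA"), (5027, "IB"))
    blocks = segment_blocks(loc, max_intervening=3)
    assert len(blocks.blocks) == 2
    assert blocks.gaps == [5026]


def test_replicon_change_always_splits():
    genes = [Gene("0A", "chr", 0), Gene("0C", "chr", 1), Gene("IE", "plasmid", 2)]
    blocks = segment_blocks(GenomeLocus(species="sp", genes=genes), max_intervening=10)
    assert len(blocks.blocks) == 2
    assert blocks.gaps == [None]


def test_hypothetical_x_rides_inside_blocks_but_never_anchors():
    # X inside a block is kept; a trailing X beyond the gap is dropped
    loc = locus((0, "0A"), (1, "X"), (2, "0C"), (9, "X"), (20, "IB"))
    blocks = segment_blocks(loc, max_intervening=3)
    assert [[g.label for g in b] for b in blocks.blocks] == [["0A", "X", "0C"], ["IB"]]


# --- split junctions -----------------------------------------------------


def test_chlorobi_style_junctions(fig4_loci):
    chlorobi = next(l for l in fig4_loci if l.species == "chlorobi")
    blocks = segment_blocks(chlorobi)
    assert split_junctions(blocks) == {"IG|IB", "ID|IA"}


def test_intact_locus_has_no_junctions():
    blocks = segment_blocks(locus(*enumerate(CANONICAL_ORDER)))
    assert split_junctions(blocks) == set()


def test_epsilon_proteobacteria_style_junctions(fig4_loci):
    eps = next(l for l in fig4_loci if l.species == "proteobacteria_epsilon")
    assert split_junctions(segment_blocks(eps)) == {"0A|0C", "0C|0B"}


def test_label_missing_from_reference_is_an_error():
    blocks = segment_blocks(locus((0, "R"), (1, "0A")))
    with pytest.raises(ValueError, match="'R'"):
        split_junctions(blocks, CANONICAL_ORDER)


# --- 0B' naming ----------------------------------------------------------


def test_upstream_in_block_copy_becomes_b_prime():
    loc = locus((0, "0C"), (1, "0B"), (2, "0B"), (3, "ID"))
    named = name_b_prime(loc)
    assert [g.label for g in named.genes] == ["0C", "0B'", "0B", "ID"]


def test_single_copy_unchanged():
    loc = locus((0, "0C"), (1, "0B"), (2, "ID"))
    assert [g.label for g in name_b_prime(loc).genes] == ["0C", "0B", "ID"]


def test_cross_block_copies_are_not_primed():
    loc = locus((0, "0C"), (1, "0B"), (500, "0B"), (501, "ID"))
    assert all(g.label != "0B'" for g in name_b_prime(loc).genes)


def test_reverse_strand_naming_follows_transcription_order():
    # transcription runs right-to-left: the high-index copy is upstream
    loc = locus((0, "ID"), (1, "0B"), (2, "0B"), (3, "0C"), strand="-")
    named = name_b_prime(loc)
    assert [g.label for g in named.genes] == ["ID", "0B", "0B'", "0C"]


def test_three_in_block_copies_flagged_for_review():
    loc = locus((0, "0B"), (1, "0B"), (2, "0B"))
    with pytest.warns(UserWarning, match="manual review"):
        named = name_b_prime(loc)
    assert [g.label for g in named.genes] == ["0B", "0B", "0B"]


# --- duplicate placement -------------------------------------------------


def test_in_locus_duplicate_pair():
    loc = locus(*enumerate(["0A", "0C", "0B", "ID", "ID", "IA", "IG"]))
    blocks = segment_blocks(loc)
    calls = classify_placement(loc, blocks)
    assert sorted(c for c in calls.values()) == ["in_locus", "in_locus"]
    assert {g.label for g in calls} == {"ID"}


def test_lone_far_copy_is_ectopic():
    genes = [Gene(l, "chr", i) for i, l in enumerate(CANONICAL_ORDER)]
    genes.append(Gene("0A", "chr", 1500))
    loc = GenomeLocus(species="sp", genes=genes)
    calls = classify_placement(loc, segment_blocks(loc))
    assert len(calls) == 1
    ((gene, call),) = calls.items()
    assert (gene.label, gene.orf_index, call) == ("0A", 1500, "ectopic")


def test_no_duplicates_gives_empty_map():
    loc = locus(*enumerate(CANONICAL_ORDER))
    assert classify_placement(loc, segment_blocks(loc)) == {}


def test_main_block_tie_is_an_error():
    loc = locus((0, "0A"), (1, "0C"), (100, "IA"), (101, "IG"))
    with pytest.raises(ValueError, match="max_intervening"):
        classify_placement(loc, segment_blocks(loc))


# --- N-ATPase signature --------------------------------------------------


def test_n_atpase_signature_order_is_detected():
    assert detect_n_atpase(N_ATPASE_ORDER)


def test_canonical_order_is_not_n_atpase():
    assert not detect_n_atpase(CANONICAL_ORDER)


def test_r_less_variant_needs_the_switch():
    bacteroides_like = ["IB", "IE", "I", "0A", "0C", "0B", "IA", "IG"]
    assert not detect_n_atpase(bacteroides_like)
    assert detect_n_atpase(bacteroides_like, require_R=False)


def test_no_block_with_delta_subunit_is_ever_n_atpase(fig4_loci, natpase_loci):
    for loc in list(fig4_loci) + list(natpase_loci):
        for block in segment_blocks(loc).blocks:
            if any(g.label == "ID" for g in block):
                assert not detect_n_atpase(block)


def test_packaged_natpase_examples(natpase_loci):
    by_name = {l.species: l for l in natpase_loci}
    full = segment_blocks(by_name["alpha_natpase"]).blocks[0]
    assert detect_n_atpase(full)
    rless = segment_blocks(by_name["bacteroides_fragilis_like"]).blocks[0]
    assert not detect_n_atpase(rless)
    assert detect_n_atpase(rless, require_R=False)


# --- pattern notation ----------------------------------------------------


def test_pattern_string_canonical(fig4_loci):
    plancto = next(l for l in fig4_loci if l.species == "planctomycetes")
    assert pattern_string(plancto) == "I-sI-0A-0C-0B-ID-IA-IG-IB-IE"


def test_pattern_single_gene():
    assert pattern_string(locus((0, "IE"))) == "IE"


def test_pattern_marks_splits_with_semicolons(fig4_loci):
    bact = next(l for l in fig4_loci if l.species == "bacteroidetes")
    assert pattern_string(bact) == "I-sI-0A-0C-0B-ID-IA-IG;IB-IE"


_label_st = st.sampled_from(sorted(set(CANONICAL_ORDER + ["R", "X", "?"])))
_pattern_st = st.lists(
    st.lists(_label_st, min_size=2, max_size=6).map(
        # X never sits at a block edge (it cannot anchor one)
        lambda ls: ["0A" if i in (0, len(ls) - 1) and l == "X" else l
                    for i, l in enumerate(ls)]
    ),
    min_size=1,
    max_size=3,
).map(lambda blocks: ";".join("-".join(b) for b in blocks))


@settings(max_examples=80, deadline=None)
@given(_pattern_st)
def test_pattern_round_trip(text):
    loc = locus_from_pattern("sp", text)
    assert pattern_string(loc) == text


def test_locus_table_round_trip(fig4_loci):
    buf = io.StringIO()
    write_locus_table(fig4_loci, buf)
    buf.seek(0)
    again = read_locus_table(buf)
    assert [pattern_string(l) for l in again] == [
        pattern_string(l) for l in fig4_loci
    ]


# --- ancestral order -----------------------------------------------------


def test_ancestral_order_from_lineage_fixture(fig4_loci):
    assert ancestral_order(fig4_loci) == CANONICAL_ORDER


def test_single_locus_returns_its_own_order():
    loc = locus(*enumerate(["0A", "0C", "0B", "IA"]))
    assert ancestral_order([loc]) == ["0A", "0C", "0B", "IA"]


def test_ancestral_order_invariant_under_input_permutation(fig4_loci):
    reversed_loci = list(reversed(fig4_loci))
    assert ancestral_order(reversed_loci) == ancestral_order(fig4_loci)
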
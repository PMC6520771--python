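"""ORF annotation under genetic codes 1 and 4."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscan.genetic_code import get_code
from mitoscan.orf import (
    CompletenessCall,
    NoOrfFound,
    assess_completeness,
    extend_with_alternative_start,
    find_primary_orf,
    propose_start_by_conservation,
    translate,
)
from mitoscan.seq_io import NucSeq, reverse_complement

TOY = "CCUAAAUGUGAUGGUAACC"


def test_code4_differs_from_code1_exactly_at_uga():
    t1, t4 = get_code(1).table, get_code(4).table
    diff = {c for c in t1 if t1[c] != t4[c]}
    assert diff == {"UGA"}
    assert t4["UGA"] == "W" and t1["UGA"] == "*"


@pytest.mark.parametrize(
    "cds, code, expected",
    [
        ("AUGUGAUGG", 4, "MWW"),
        ("AUGUGAUGG", 1, "M*W"),
        ("AUGNNAUAA", 4, "MX*"),
    ],
)
def test_translate(cds, code, expected):
    assert translate(cds, code) == expected


def test_translate_rejects_partial_codon():
    with pytest.raises(ValueError, match="divisible by 3"):
        translate("AUGA", 4)


def test_primary_orf_code4_worked_example():
    orf = find_primary_orf(NucSeq("toy", TOY), 4)
    assert (orf.start, orf.end, orf.frame) == (5, 17, 2)
    assert orf.protein == "MWW"
    assert (orf.ntr5_len, orf.ntr3_len) == (5, 2)
    assert orf.has_terminal_stop
    assert orf.upstream_stop_end == 5


def test_primary_orf_is_code_dependent():
    orf = find_primary_orf(NucSeq("toy", TOY), 1)
    assert (orf.start, orf.frame) == (10, 1)
    assert orf.protein == "MVT"
    assert not orf.has_terminal_stop


def test_no_aug_anywhere():
    with pytest.raises(NoOrfFound):
        find_primary_orf(NucSeq("a", "AAAAAAAAA"), 4)


def test_completeness_categories():
    both = find_primary_orf(NucSeq("toy", TOY), 4)
    assert assess_completeness(both) == CompletenessCall.CODING_COMPLETE_BOTH_FLANKS
    no_upstream = find_primary_orf(NucSeq("x", "AUGUGGUAA"), 4)
    assert (
        assess_completeness(no_upstream)
        == CompletenessCall.CODING_COMPLETE_NO_UPSTREAM_STOP
    )
    open_ended = find_primary_orf(NucSeq("y", "AUGGGGCCC"), 4)
    assert assess_completeness(open_ended) == CompletenessCall.INCOMPLETE_3PRIME


def test_upstream_gug_proposal():
    seq = NucSeq("x", "UAAGUGAAAAUGUGAUAA")
    orf = find_primary_orf(seq, 4)
    assert orf.start == 9
    props = extend_with_alternative_start(seq, orf, 4)
    assert [(p.proposed_start, p.proposed_codon, p.delta_aa) for p in props] == [
        (3, "GUG", 2)
    ]


def test_upstream_auu_two_codons_before_aug():
    seq = NucSeq("x", "UAAAUUAAAAUGUGGUAA")
    orf = find_primary_orf(seq, 4)
    props = extend_with_alternative_start(seq, orf, 4)
    assert [(p.proposed_codon, p.delta_aa) for p in props] == [("AUU", 2)]


def test_no_alternative_start_candidates():
    seq = NucSeq("x", "UAACCCAAAAUGUGGUAA")
    orf = find_primary_orf(seq, 4)
    assert extend_with_alternative_start(seq, orf, 4) == []


# -- conservation-refined starts ---------------------------------------------

_TAIL = "CUUGAUGAACGUGAAAAACAAUGG"  # ...LDEREKQW
_CORE = "AUGAGUAAA" + _TAIL  # MSKLDEREKQW


def _taxa(seqs):
    return [(s, find_primary_orf(s, 4)) for s in seqs]


def test_conservation_proposes_upstream_auu():
    """Three taxa begin MSK...; the fourth reaches those residues only via
    an upstream in-frame AUU and receives a supported proposal."""
    others = [
        NucSeq(f"t{i}", ntr + _CORE + "UAAGC")
        for i, ntr in enumerate(["CAAUAA", "GGUUAA", "ACGUAA"])
    ]
    auu_taxon = NucSeq("t4", "GCUAA" + "AUUAGUAAA" + "AUG" + _TAIL + "UAAGC")
    props = propose_start_by_conservation(_taxa([*others, auu_taxon]), 4)
    assert [(p.seq_id, p.proposed_codon, p.support) for p in props] == [
        ("t4", "AUU", 3)
    ]
    assert props[0].delta_aa > 0


def test_conservation_silent_when_taxa_identical():
    seqs = [
        NucSeq(f"t{i}", ntr + _CORE + "UAAGC")
        for i, ntr in enumerate(["CAAUAA", "GGUUAA", "ACGUAA"])
    ]
    assert propose_start_by_conservation(_taxa(seqs), 4) == []


def test_conservation_proposes_downstream_aug():
    """A taxon whose first AUG precedes the conserved start is assigned its
    second in-frame AUG, shortening the protein."""
    others = [
        NucSeq(f"o{i}", ntr + _CORE + "UAAGC")
        for i, ntr in enumerate(["CAAUAA", "GGUUAA", "ACGUAA"])
    ]
    early = NucSeq("d", "GCUAA" + "AUGCCCCAUGGU" + _CORE + "UAAGC")
    props = propose_start_by_conservation(_taxa([*others, early]), 4)
    assert [(p.seq_id, p.proposed_codon) for p in props] == [("d", "AUG")]
    assert props[0].delta_aa == -4


def test_conservation_needs_two_taxa():
    seq = NucSeq("t", "CAAUAA" + _CORE + "UAAGC")
    with pytest.raises(ValueError):
        propose_start_by_conservation(_taxa([seq]), 4)


# -- invariants ---------------------------------------------------------------


def test_plus_strand_polarity(small_dataset):
    """Scanning is plus-strand only: the reverse complement never
    reproduces the forward annotation."""
    seqs, truths = small_dataset
    s, t = seqs[0], truths[0]
    rc = NucSeq(s.id, reverse_complement(s.residues))
    try:
        orf_rc = find_primary_orf(rc, 4)
        assert (orf_rc.start, orf_rc.end, orf_rc.protein) != (
            t.orf_start, t.orf_end, t.protein
        )
    except NoOrfFound:
        pass


def test_code1_orf_shorter_when_cds_contains_uga(small_dataset):
    """Under the standard code a UGA-containing mitovirus CDS yields a
    strictly shorter (or unterminated) primary ORF."""
    seqs, truths = small_dataset
    checked = 0
    for s, t in zip(seqs, truths):
        if t.trp_uga == 0:
            continue
        orf1 = find_primary_orf(s, 1)
        assert len(orf1.protein) < len(t.protein) or not orf1.has_terminal_stop
        checked += 1
    assert checked > 0


@given(st.integers(0, 40), st.data())
@settings(max_examples=40, derandomize=True)
def test_translate_distributes_over_codon_aligned_splits(n_codons, data):
    alphabet = "ACGU"
    cds = "".join(
        data.draw(st.sampled_from(alphabet)) for _ in range(3 * n_codons)
    )
    cut = 3 * data.draw(st.integers(0, n_codons))
    assert translate(cds, 4) == translate(cds[:cut], 4) + translate(cds[cut:], 4)
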
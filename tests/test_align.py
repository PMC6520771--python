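"""Affine-gap global alignment against independent oracles."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscan.align import (
    AlignmentParams,
    global_align,
    identity_matrix,
)
from mitoscan.seq_io import NucSeq

NEG = float("-inf")


def oracle(a, b, params):
    """Memoized plain recursion over (i, j, previous-move): optimal score
    plus the set of (identical columns, total columns) over all co-optimal
    alignments.  Written independently of the production DP (no affine
    state matrices)."""
    n, m = len(a), len(b)
    free = not params.end_gaps_penalized
    go, ge = params.gap_open, params.gap_extend

    def sub(x, y):
        return params.match if x == y else params.mismatch

    def gap_cost(prev, same, edge):
        if free and edge:
            return 0.0
        return ge if prev == same else go

    @lru_cache(maxsize=None)
    def best(i, j, prev):
        if i == n and j == m:
            return 0.0
        cands = []
        if i < n and j < m:
            cands.append(sub(a[i], b[j]) + best(i + 1, j + 1, "d"))
        if i < n:  # gap in b, consume a
            cands.append(best(i + 1, j, "u") - gap_cost(prev, "u", j in (0, m)))
        if j < m:  # gap in a, consume b
            cands.append(best(i, j + 1, "l") - gap_cost(prev, "l", i in (0, n)))
        return max(cands)

    @lru_cache(maxsize=None)
    def outcomes(i, j, prev):
        """Set of (n_identical, n_columns) over optimal suffix alignments."""
        if i == n and j == m:
            return frozenset({(0, 0)})
        target = best(i, j, prev)
        out = set()
        if i < n and j < m:
            if abs(sub(a[i], b[j]) + best(i + 1, j + 1, "d") - target) < 1e-6:
                inc = 1 if a[i] == b[j] else 0
                out |= {(inc + x, 1 + c) for x, c in outcomes(i + 1, j + 1, "d")}
        if i < n:
            cost = gap_cost(prev, "u", j in (0, m))
            if abs(best(i + 1, j, "u") - cost - target) < 1e-6:
                out |= {(x, 1 + c) for x, c in outcomes(i + 1, j, "u")}
        if j < m:
            cost = gap_cost(prev, "l", i in (0, n))
            if abs(best(i, j + 1, "l") - cost - target) < 1e-6:
                out |= {(x, 1 + c) for x, c in outcomes(i, j + 1, "l")}
        return frozenset(out)

    return best(0, 0, "s"), outcomes(0, 0, "s")


def test_self_alignment():
    r = global_align("ACGUACGU", "ACGUACGU")
    assert r.percent_identity == 100.0
    assert r.score == 8 * 5
    assert r.n_gap_columns == 0


def test_single_mismatch_ungapped_optimum():
    r = global_align("ACGU", "ACGA")
    assert r.score == 3 * 5 - 4
    assert r.percent_identity == 75.0
    assert (r.aligned_a, r.aligned_b) == ("ACGU", "ACGA")


def test_free_end_gap_identity_denominator():
    r = global_align("AAAA", "AAAAAA")
    assert r.score == 4 * 5
    assert r.percent_identity == pytest.approx(100 * 4 / 6)
    r2 = global_align("AAAA", "AAAAAA", identity_denominator="shorter")
    assert r2.percent_identity == 100.0


def test_ambiguity_scores_as_self_match_only():
    assert global_align("N", "N").score == 5.0
    penalized = AlignmentParams(end_gaps_penalized=True)
    assert global_align("NN", "AA", penalized).score == -8.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACGU")


@pytest.mark.parametrize("penalize_ends", [False, True])
@settings(max_examples=120, deadline=None, derandomize=True)
@given(data=st.data())
def test_matches_bruteforce_oracle_on_short_pairs(data, penalize_ends):
    """Score equals the memoized-recursion oracle and identity is realized
    by one of the co-optimal alignments, on random pairs up to 12 nt."""
    params = AlignmentParams(end_gaps_penalized=penalize_ends)
    nt = st.text(alphabet="ACGU", min_size=1, max_size=12)
    a, b = data.draw(nt), data.draw(nt)
    score, outcomes = oracle(a, b, params)
    r = global_align(a, b, params)
    assert r.score == pytest.approx(score)
    realized = (
        sum(1 for x, y in zip(r.aligned_a, r.aligned_b) if x == y and x != "-"),
        r.n_columns,
    )
    assert realized in outcomes


@pytest.mark.parametrize("penalize_ends", [False, True])
def test_score_matches_biopython_on_medium_pairs(penalize_ends):
    """Independent cross-check: identical optimal scores from Biopython's
    PairwiseAligner under matched parameters."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    if not penalize_ends:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0

    rng = np.random.default_rng(42)
    params = AlignmentParams(end_gaps_penalized=penalize_ends)
    for _ in range(8):
        n, m = rng.integers(30, 200, size=2)
        a = "".join(rng.choice(list("ACGU"), n))
        b = "".join(rng.choice(list("ACGU"), m))
        assert global_align(a, b, params).score == pytest.approx(
            aligner.score(a.replace("U", "T"), b.replace("U", "T"))
        )


def test_identity_symmetric_under_argument_swap():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join(rng.choice(list("ACGU"), 120))
        b = list(a)
        for p in rng.choice(120, size=15, replace=False):
            b[p] = rng.choice([c for c in "ACGU" if c != a[p]])
        b = "".join(b)
        assert global_align(a, b).percent_identity == pytest.approx(
            global_align(b, a).percent_identity
        )


def test_identity_decreases_with_substitutions():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACGU"), 300))
    prev = 100.0
    for k in (6, 30, 60):
        b = list(a)
        for p in range(0, 3 * k, 3):
            b[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[a[p]]
        pid = global_align(a, "".join(b)).percent_identity
        assert pid < prev
        prev = pid


def test_identity_matrix_identical_sequences():
    seqs = [NucSeq(f"s{i}", "ACGUACGUACGU") for i in range(3)]
    m = identity_matrix(seqs)
    assert np.all(m.values == 100.0)


def test_identity_matrix_rejects_duplicates():
    seqs = [NucSeq("s", "ACGU"), NucSeq("s", "ACGG")]
    with pytest.raises(ValueError, match="duplicate"):
        identity_matrix(seqs)


def test_strain_pair_identity_is_analytic(small_dataset):
    """For substitution-only strains the percent identity equals
    100 (n - k) / n with k the tracked substitution-position count."""
    from mitoscan.synthetic import generate_dataset
    from tests.conftest import small_spec

    seqs, truths = generate_dataset(
        small_spec(9, ntr_indels_between_strains=False, n_species=1)
    )
    for (sa, ta), (sb, tb) in itertools.combinations(zip(seqs, truths), 2):
        assert len(sa) == len(sb)
        k = len(ta.substitution_positions) + len(tb.substitution_positions)
        expect = 100.0 * (len(sa) - k) / len(sa)
        r = global_align(sa, sb)
        assert r.n_gap_columns == 0
        assert r.percent_identity == pytest.approx(expect)
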
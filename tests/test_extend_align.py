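"""X-drop extension and the seed-and-extend pipeline vs a full-DP oracle."""

import numpy as np
import pytest

import adaseed as a
from adaseed.extend_align import (
    GaplessAlignment,
    ScoringScheme,
    default_gapless_threshold,
    gapless_extend,
    gapped_extend,
    rescore_record,
)
from adaseed.index_seed import mask_lowercase
from adaseed.patterns import parse_pattern

from conftest import codes_to_text, mutate


def toy_scheme(min_score=1, gap_exist=7, gap_extend=1):
    sub = np.full((4, 4), -1, dtype=np.int64)
    np.fill_diagonal(sub, 1)
    return ScoringScheme("toy", sub, gap_exist=gap_exist, gap_extend=gap_extend,
                         min_score=min_score, n_score=-1)


def gotoh_local(q, r, sc):
    """Independent full local-alignment DP (plain Python, no pruning)."""
    sub = sc.full_matrix()
    go, ge = sc.gap_exist, sc.gap_extend
    NEG = -(10**12)
    lq, lr = q.size, r.size
    M = [[0] * (lr + 1) for _ in range(lq + 1)]
    D = [[NEG] * (lr + 1) for _ in range(lq + 1)]
    I = [[NEG] * (lr + 1) for _ in range(lq + 1)]
    best = 0
    for i in range(1, lq + 1):
        for j in range(1, lr + 1):
            D[i][j] = max(M[i - 1][j] - go - ge, D[i - 1][j] - ge,
                          I[i - 1][j] - go - ge)
            I[i][j] = max(M[i][j - 1] - go - ge, I[i][j - 1] - ge,
                          D[i][j - 1] - go - ge)
            m = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            M[i][j] = max(0, m + int(sub[q[i - 1], r[j - 1]]),
                          D[i][j], I[i][j])
            best = max(best, M[i][j])
    return best


# ------------------------------------------------------------- gapless

def test_gapless_identical_sequences_full_length():
    q = mask_lowercase("GATTACA")
    g = gapless_extend(3, 3, 1, q, q, toy_scheme(), y=10)
    assert (g.query_start, g.query_end, g.score) == (0, 7, 7)


def test_gapless_xdrop_trims_to_best_core():
    """AATTTT vs AACCCC with y=2: the drop stops extension after three
    mismatches and trimming keeps the scoring 'AA' prefix."""
    g = gapless_extend(0, 0, 2, mask_lowercase("AATTTT"),
                       mask_lowercase("AACCCC"), toy_scheme(), y=2)
    assert (g.query_start, g.query_end, g.score) == (0, 2, 2)


def test_gapless_negative_flanks_keep_seed_core():
    g = gapless_extend(2, 2, 2, mask_lowercase("TTAATT"),
                       mask_lowercase("CCAACC"), toy_scheme(), y=0)
    assert (g.query_start, g.query_end, g.score) == (2, 4, 2)


def test_gapless_alignment_invariant():
    with pytest.raises(ValueError):
        GaplessAlignment(0, 5, 0, 4, 3)


# ------------------------------------------------------- default d rule

@pytest.mark.parametrize(
    "m,n,r,t,expected",
    [
        (1000, 1, 1363595724, 96.1735, 2466),
        (10, 8, 1363595724, 96.1735, 1823),
    ],
)
def test_default_threshold_endpoints(m, n, r, t, expected):
    assert default_gapless_threshold(m, n, r, t) == expected


def test_default_threshold_unit_case():
    # m*r/(10*n) ~ e makes t*ln() round to 1
    assert default_gapless_threshold(1, 1, 27, 1.0) == 1


def test_default_threshold_rejects_nonpositive():
    with pytest.raises(ValueError):
        default_gapless_threshold(0, 1, 100, 1.0)


# --------------------------------------------------------------- gapped

def test_gapped_no_gap_equals_gapless_on_identical():
    q = mask_lowercase("ACGTACGTACGT")
    seg = gapless_extend(4, 4, 2, q, q, toy_scheme(), y=100)
    rec = gapped_extend(seg, q, q, toy_scheme(), ydrop_gapped=50)
    assert rec.score == seg.score == 12
    assert rec.ops == [("M", 12)]


def test_gapped_recovers_deletion_against_full_dp():
    rng = np.random.default_rng(8)
    anc = rng.integers(0, 4, size=60)
    der = np.concatenate([anc[:30], anc[33:]])
    sc = toy_scheme(gap_exist=2, gap_extend=1)
    q = mask_lowercase(codes_to_text(der))
    r = mask_lowercase(codes_to_text(anc))
    seg = gapless_extend(5, 5, 3, q, r, sc, y=10**6)
    rec = gapped_extend(seg, q, r, sc, ydrop_gapped=10**6)
    assert rec.score == gotoh_local(q.code, r.code, sc)
    assert rescore_record(rec, q, r, sc) == rec.score
    assert any(op == "R" and ln == 3 for op, ln in rec.ops)


def test_gapped_never_loses_anchor_at_zero_ydrop():
    q = mask_lowercase("ACGTACG")
    seg = gapless_extend(2, 2, 3, q, q, toy_scheme(), y=0)
    rec = gapped_extend(seg, q, q, toy_scheme(), ydrop_gapped=0)
    assert rec.score >= seg.score


# ---------------------------------------------------------------- align

def test_align_unique_substring_perfect_score(rng, last_sc):
    """A query equal to a unique reference substring aligns end to end."""
    text = codes_to_text(rng.integers(0, 4, size=8000))
    ref = mask_lowercase(text, "r")
    query = mask_lowercase(text[5000:6000], "q")
    idx = a.build_index(ref, parse_pattern("1T1"), w=1)
    recs = a.align(query, [idx], last_sc, m=10, k=1, y=10, d=30)
    assert recs
    best = recs[0]
    assert best.score == 1000
    assert best.strand == "+"
    assert (best.ref_start, best.ref_end) == (5000, 6000)
    assert (best.query_start, best.query_end) == (0, 1000)


def test_align_all_n_query_is_empty(last_sc):
    ref = mask_lowercase("ACGT" * 300, "r")
    idx = a.build_index(ref, parse_pattern("1"), w=1)
    assert a.align(mask_lowercase("n" * 100, "q"), [idx], last_sc, m=10, d=35) == []


def test_align_degenerate_equals_full_dp(rng, last_sc):
    """Pattern '1', huge m/y/ydrop, d=min_score: top score = local DP."""
    for _ in range(8):
        L = int(rng.integers(120, 200))
        anc = rng.integers(0, 4, size=L)
        der = mutate(anc, rng, 0.08, indel=bool(rng.integers(0, 2)))
        q = mask_lowercase(codes_to_text(der), "q")
        r = mask_lowercase(codes_to_text(anc), "r")
        idx = a.build_index(r, parse_pattern("1"))
        recs = a.align(q, [idx], last_sc, m=r.length + 1, k=1, y=10**7,
                       d=last_sc.min_score, ydrop_gapped=10**7)
        oracle = max(gotoh_local(q.code, r.code, last_sc),
                     gotoh_local(q.reverse_complement().code, r.code, last_sc))
        got = recs[0].score if recs else 0
        if oracle >= last_sc.min_score:
            assert got == oracle
        else:
            assert got == 0


def test_align_score_self_consistency(small_pair, last_sc):
    ref = mask_lowercase(small_pair.ancestor, "anc")
    query = mask_lowercase(small_pair.derived[3000:4000], "q")
    idx = a.build_index(ref, parse_pattern("11T01"), w=1)
    recs = a.align(query, [idx], last_sc, m=50, k=1, y=10, d=25)
    assert recs
    for rec in recs[:5]:
        assert rescore_record(rec, query, ref, last_sc) == rec.score


def test_align_strand_mirror(small_pair, last_sc):
    """Reverse-complementing the query mirrors strands, same scores."""
    from adaseed.io_cli import _revcomp

    ref = mask_lowercase(small_pair.ancestor, "anc")
    chunk = small_pair.derived[7000:7600]
    idx = a.build_index(ref, parse_pattern("1T1"), w=1)
    fwd = a.align(mask_lowercase(chunk, "q"), [idx], last_sc, m=20, d=30)
    rev = a.align(mask_lowercase(_revcomp(chunk), "q"), [idx], last_sc, m=20, d=30)
    assert fwd and rev
    assert {r.score for r in fwd} == {r.score for r in rev}
    assert {"+", "-"} >= {r.strand for r in fwd}
    top_f, top_r = fwd[0], rev[0]
    assert (top_f.ref_start, top_f.ref_end) == (top_r.ref_start, top_r.ref_end)
    assert top_f.strand != top_r.strand


def test_align_threshold_monotonicity(small_pair, last_sc):
    """Lowering d or raising m/y/ydrop never loses a reported alignment."""
    ref = mask_lowercase(small_pair.ancestor, "anc")
    query = mask_lowercase(small_pair.derived[11000:12000], "q")
    idx = a.build_index(ref, parse_pattern("1T1"), w=1)
    base = a.align(query, [idx], last_sc, m=10, k=2, y=10, d=40, ydrop_gapped=30)
    assert base
    base_coords = {r.coordinates() for r in base}
    def overlaps(r1, r2):
        return (r1.strand == r2.strand
                and r1.query_start < r2.query_end and r2.query_start < r1.query_end
                and r1.ref_start < r2.ref_end and r2.ref_start < r1.ref_end)

    for kwargs in (dict(m=50, k=2, y=10, d=40, ydrop_gapped=30),
                   dict(m=10, k=2, y=30, d=40, ydrop_gapped=30),
                   dict(m=10, k=2, y=10, d=25, ydrop_gapped=30),
                   dict(m=10, k=2, y=10, d=40, ydrop_gapped=80)):
        more = a.align(query, [idx], last_sc, **kwargs)
        for rec in base:
            # the alignment survives: an overlapping record scores >= it
            assert any(overlaps(rec, r2) and r2.score >= rec.score
                       for r2 in more)
    assert base_coords  # sanity: the base run reported something


def test_hoxd70_scheme_values(hoxd70_sc):
    assert hoxd70_sc.substitution[0, 0] == 91
    assert hoxd70_sc.substitution[1, 2] == -125
    assert hoxd70_sc.min_score == 4000 and hoxd70_sc.n_score == -100
    assert hoxd70_sc.t_scale == pytest.approx(96.1735)
    assert hoxd70_sc.default_y == 962 and hoxd70_sc.default_ydrop == 3999


def test_scheme_validation():
    bad = np.zeros((4, 4), dtype=np.int64)
    with pytest.raises(ValueError):
        ScoringScheme("bad", bad, 7, 1, 35, -1)
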
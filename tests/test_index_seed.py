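"""Subset suffix arrays and adaptive seeds against a quadratic oracle."""

import numpy as np
import pytest

import adaseed as a
from adaseed.index_seed import (
    adaptive_seeds_bruteforce,
    build_index,
    load_index,
    mask_lowercase,
    save_index,
)
from adaseed.patterns import parse_pattern


@pytest.mark.parametrize(
    "raw,masked",
    [("acgT", "NNNT"), ("ACGT", "ACGT"), ("AcNg", "ANNN"), ("aNnU*", "NNNNN")],
)
def test_mask_lowercase(raw, masked):
    assert mask_lowercase(raw).letters == masked


def test_reverse_complement_keeps_n():
    seq = mask_lowercase("ACGTN")
    assert seq.reverse_complement().letters == "NACGT"


def test_index_contains_all_positions_for_plain_pattern():
    idx = build_index(mask_lowercase("AAAA"), parse_pattern("1"))
    assert sorted(idx.sa.tolist()) == [0, 1, 2, 3]


def test_transition_pattern_groups_purines():
    """Under pattern 'T', A and G are one class: 'A' occurs 4x in AGAG."""
    idx = build_index(mask_lowercase("AGAG"), parse_pattern("T"))
    seeds = a.adaptive_seeds(mask_lowercase("A"), idx, m=10)
    assert len(seeds) == 4
    # and brute force agrees
    bf = adaptive_seeds_bruteforce(
        mask_lowercase("A"), mask_lowercase("AGAG"), parse_pattern("T"), m=10
    )
    assert len(bf) == 4


def test_sparse_sampling_keeps_every_wth_position():
    idx = build_index(mask_lowercase("ACGTACGT"), parse_pattern("1"), w=2)
    assert sorted(idx.sa.tolist()) == [0, 2, 4, 6]


def test_n_positions_excluded_from_index():
    idx = build_index(mask_lowercase("ANGN"), parse_pattern("1"))
    assert sorted(idx.sa.tolist()) == [0, 2]


def test_adaptive_seed_minimal_length_example():
    """In ACACAC the prefix must grow to length 3 before <= 2 occurrences."""
    idx = build_index(mask_lowercase("ACACAC"), parse_pattern("1"))
    seeds = a.adaptive_seeds(mask_lowercase("ACA"), idx, m=2)
    at0 = sorted((s.ref_pos, s.length) for s in seeds if s.query_pos == 0)
    assert at0 == [(0, 3), (2, 3)]


def test_adaptive_seed_immediate_stop():
    idx = build_index(mask_lowercase("AAAA"), parse_pattern("1"))
    seeds = a.adaptive_seeds(mask_lowercase("A"), idx, m=10)
    assert sorted(s.ref_pos for s in seeds) == [0, 1, 2, 3]
    assert all(s.length == 1 for s in seeds)


def test_query_n_emits_nothing():
    idx = build_index(mask_lowercase("ACGTACGT"), parse_pattern("1"))
    assert a.adaptive_seeds(mask_lowercase("NNN"), idx, m=4) == []


def test_count_never_drops_emits_nothing():
    """If the occurrence count stays above m to the query end, no seed."""
    idx = build_index(mask_lowercase("AAAAAA"), parse_pattern("1"))
    assert a.adaptive_seeds(mask_lowercase("AA"), idx, m=1) == []


def _random_instance(rng):
    ref = "".join(
        rng.choice(list("ACGTacgtN"), size=int(rng.integers(30, 400)),
                   p=[0.22, 0.22, 0.22, 0.22, 0.025, 0.025, 0.025, 0.025, 0.02])
    )
    query = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(4, 50)),
                               p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    span = int(rng.integers(1, 6))
    pat = "".join(rng.choice(list("1T0"), size=span, p=[0.5, 0.3, 0.2]))
    return ref, query, parse_pattern(pat)


def test_equivalence_with_quadratic_matcher(rng):
    """Suffix-array narrowing = brute-force class scan on small references."""
    for _ in range(60):
        ref, query, pat = _random_instance(rng)
        w = int(rng.integers(1, 4))
        k = int(rng.integers(1, 4))
        m = int(rng.integers(1, 10))
        refm, qm = mask_lowercase(ref), mask_lowercase(query)
        idx = build_index(refm, pat, w=w)
        got = sorted((s.query_pos, s.ref_pos, s.length)
                     for s in a.adaptive_seeds(qm, idx, m, k))
        exp = sorted((s.query_pos, s.ref_pos, s.length)
                     for s in adaptive_seeds_bruteforce(qm, refm, pat, m, k, w))
        assert got == exp


def test_minimality_and_count_bound(rng):
    """Emitted matches: count <= m at the emitted length, > m one shorter."""
    for _ in range(20):
        ref, query, pat = _random_instance(rng)
        m = int(rng.integers(1, 6))
        refm, qm = mask_lowercase(ref), mask_lowercase(query)
        idx = build_index(refm, pat, w=1)
        seeds = a.adaptive_seeds(qm, idx, m)
        by_start: dict[int, list] = {}
        for s in seeds:
            by_start.setdefault(s.query_pos, []).append(s)
        for q0, group in by_start.items():
            L = group[0].length
            assert all(s.length == L for s in group)
            assert len(group) <= m
            if L > 1:
                # count occurrences of the (L-1)-prefix directly
                assert _count_prefix_occurrences(qm, refm, pat, q0, L - 1) > m


def _count_prefix_occurrences(qm, refm, pat, q0, L):
    from adaseed.index_seed import _pattern_classmap

    cm = _pattern_classmap(pat)
    period = pat.span
    count = 0
    for p in range(refm.length):
        ok = True
        for j in range(L):
            if (q0 + j >= qm.length or p + j >= refm.length
                    or cm[j % period, qm.code[q0 + j]] == 0
                    or cm[j % period, qm.code[q0 + j]] != cm[j % period, refm.code[p + j]]):
                ok = False
                break
        if ok:
            count += 1
    return count


def test_dense_even_matches_are_subset_of_sparse(rng):
    """Sparser indexing lowers counts, so seeds stop at shorter prefixes:
    every w=1 match at an even reference position is found under w=2."""
    for _ in range(20):
        ref, query, pat = _random_instance(rng)
        m = int(rng.integers(1, 6))
        refm, qm = mask_lowercase(ref), mask_lowercase(query)
        dense = a.adaptive_seeds(qm, build_index(refm, pat, w=1), m)
        sparse = a.adaptive_seeds(qm, build_index(refm, pat, w=2), m)
        sparse_pairs = {(s.query_pos, s.ref_pos) for s in sparse}
        for s in dense:
            if s.ref_pos % 2 == 0:
                assert (s.query_pos, s.ref_pos) in sparse_pairs


def test_index_save_load_round_trip(tmp_path):
    refm = mask_lowercase("ACGTACGTacgt", "chr1")
    idx = build_index(refm, parse_pattern("1T0"), w=2)
    save_index(idx, tmp_path / "idx.json")
    idx2 = load_index(tmp_path / "idx.json", refm)
    assert np.array_equal(idx.sa, idx2.sa)
    assert idx2.pattern == idx.pattern and idx2.step == 2


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        build_index(mask_lowercase(""), parse_pattern("1"))
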
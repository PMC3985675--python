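"""Scoring schemes, X-drop extension, and the seed-and-extend pipeline.

Each adaptive seed is first extended without gaps; only segments whose
gapless score reaches the threshold d are handed to the much slower
gapped X-drop extension, and only gapped alignments scoring at least
the scheme's minimum are reported.  The default d follows LAST's rule
d = round(t * ln(m*r / (10*n))): the rarer and more numerous the seeds
(m, n) and the larger the unmasked reference (r), the more gapless
candidates exist, so the bar for gapped extension rises to keep the
gapped phase's workload proportional to the gapless phase's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .index_seed import MaskedSequence, N_CODE, SubsetSuffixIndex, adaptive_seeds_arrays

#: HoxD70 substitution scores (Chiaromonte, Yap & Miller 2002), order ACGT.
HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, affine gap costs and reporting threshold.

    A gap of length g costs gap_exist + gap_extend * g (so with costs
    7/1 a single-base gap costs 8).  ``n_score`` is the score of N
    aligned to anything, including another N.  ``t_scale`` is the scale
    factor of the score matrix, used only by the default-d rule; it is
    a user-supplied quantity.
    """

    name: str
    substitution: np.ndarray = field(repr=False)
    gap_exist: int
    gap_extend: int
    min_score: int
    n_score: int
    t_scale: float | None = None
    default_y: int = 10
    default_ydrop: int | None = None

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=np.int64)
        if sub.shape != (4, 4) or not np.array_equal(sub, sub.T):
            raise ValueError("substitution table must be a symmetric 4x4 matrix")
        if np.any(np.diag(sub) <= 0):
            raise ValueError("substitution diagonal must be positive")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.gap_exist < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        object.__setattr__(self, "substitution", sub)

    def full_matrix(self) -> np.ndarray:
        """5x5 matrix over (A, C, G, T, N) with the N row/column filled."""
        m = np.full((5, 5), self.n_score, dtype=np.int64)
        m[:4, :4] = self.substitution
        return m

    def default_d(self, m: int, n: int, r: int) -> int:
        if self.t_scale is None:
            raise ValueError(
                f"scheme {self.name!r} has no scale factor; pass d explicitly"
            )
        return default_gapless_threshold(m, n, r, self.t_scale)


def last_scheme() -> ScoringScheme:
    """Match/mismatch +1/-1, gaps 7/1, minimum score 35, N scores -1."""
    sub = np.full((4, 4), -1, dtype=np.int64)
    np.fill_diagonal(sub, 1)
    return ScoringScheme("last", sub, gap_exist=7, gap_extend=1,
                         min_score=35, n_score=-1, default_y=10)


def hoxd70_scheme() -> ScoringScheme:
    """HoxD70 matrix, gaps 400/30, minimum score 4000, N scores -100.

    The scale factor 96.1735 and the gapless drop default y=962 match
    the values used with this scheme in mammal-genome comparison.
    """
    return ScoringScheme("hoxd70", HOXD70, gap_exist=400, gap_extend=30,
                         min_score=4000, n_score=-100, t_scale=96.1735,
                         default_y=962, default_ydrop=3999)


SCHEMES = {"last": last_scheme, "hoxd70": hoxd70_scheme}


def default_gapless_threshold(m: int, n: int, r: int, t_scale: float) -> int:
    """d = round(t * ln(m*r / (10*n))).

    m: rareness threshold; n: number of seed patterns; r: unmasked
    reference bases; t_scale: score-matrix scale factor.
    """
    if m <= 0 or n <= 0 or r <= 0 or t_scale <= 0:
        raise ValueError("all arguments must be positive")
    return round(t_scale * math.log(m * r / (10 * n)))


@dataclass(frozen=True)
class GaplessAlignment:
    """An ungapped segment: equal-length spans on query and reference."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    score: int
    anchor: int = 0  # column offset (from query_start) of the score peak

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.ref_end - self.ref_start:
            raise ValueError("gapless spans must have equal lengths")


@dataclass
class AlignmentRecord:
    """A gapped local alignment with its column path.

    Coordinates are 0-based half-open on the aligned strand of the
    query ('-' strand coordinates count from the reverse-complement
    start, as in MAF).  ops is a list of (op, length) runs with op 'M'
    (aligned columns), 'Q' (query-only, gap in reference text) or 'R'
    (reference-only, gap in query text).
    """

    query_name: str
    ref_name: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    score: int
    ops: list[tuple[str, int]]
    query_length: int = 0
    ref_length: int = 0

    def coordinates(self) -> tuple[int, int, int, int, str]:
        return (self.query_start, self.query_end,
                self.ref_start, self.ref_end, self.strand)


def rescore_record(rec: AlignmentRecord, query: MaskedSequence,
                   ref: MaskedSequence, sc: ScoringScheme) -> int:
    """Recompute a record's score from its column path (consistency check)."""
    sub = sc.full_matrix()
    qc = query.code if rec.strand == "+" else query.reverse_complement().code
    qi, ri = rec.query_start, rec.ref_start
    total = 0
    for op, length in rec.ops:
        if op == "M":
            for t in range(length):
                total += int(sub[qc[qi + t], ref.code[ri + t]])
            qi += length
            ri += length
        elif op == "Q":
            total -= sc.gap_exist + sc.gap_extend * length
            qi += length
        elif op == "R":
            total -= sc.gap_exist + sc.gap_extend * length
            ri += length
        else:
            raise ValueError(f"unknown op {op!r}")
    if (qi, ri) != (rec.query_end, rec.ref_end):
        raise ValueError("ops do not span the record coordinates")
    return total


def gapless_extend(
    seed_qpos: int,
    seed_rpos: int,
    seed_len: int,
    query: MaskedSequence,
    ref: MaskedSequence,
    sc: ScoringScheme,
    y: int,
) -> GaplessAlignment:
    """X-drop gapless extension of one seed, trimmed to its best core."""
    if y < 0:
        raise ValueError("gapless drop y must be >= 0")
    out = np.empty((1, 6), dtype=np.int64)
    _kernels.gapless_extend_batch(
        np.array([seed_qpos], dtype=np.int64),
        np.array([seed_rpos], dtype=np.int64),
        np.array([seed_len], dtype=np.int64),
        query.code, ref.code, sc.full_matrix(), y, out,
    )
    qs, qe, rs, re, score, anchor = (int(v) for v in out[0])
    return GaplessAlignment(qs, qe, rs, re, score, anchor)


def _traceback(tb: np.ndarray, jlo: np.ndarray, end_i: int, end_j: int
               ) -> list[tuple[str, int]]:
    """Walk predecessor bytes from (end_i, end_j, state M) back to origin."""
    ops: list[str] = []
    i, j, state = end_i, end_j, 0
    while not (i == 0 and j == 0):
        byte = int(tb[i, j - jlo[i]])
        if state == 0:  # M: consumed one column of both
            pred = byte & 3
            ops.append("M")
            i -= 1
            j -= 1
        elif state == 1:  # D: consumed query only
            pred = (byte >> 2) & 3
            ops.append("Q")
            i -= 1
        else:  # I: consumed reference only
            pred = (byte >> 4) & 3
            ops.append("R")
            j -= 1
        if pred == 3:
            if not (i == 0 and j == 0):
                # row-0 insertion run reaches the origin via pred=3 at j=1
                if i == 0 and j >= 1 and state == 2:
                    pred = 2
                else:
                    raise RuntimeError("broken traceback")
            else:
                break
        state = pred
    ops.reverse()
    # run-length encode
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return runs


def _xdrop_one_direction(qs_codes: np.ndarray, rs_codes: np.ndarray,
                         sc: ScoringScheme, ydrop: int
                         ) -> tuple[int, int, int, list[tuple[str, int]]]:
    """Run the X-drop kernel, growing the window on overflow."""
    sub = sc.full_matrix()
    ge = max(sc.gap_extend, 1)
    width = int(min(rs_codes.size + 1, 2 * (ydrop // ge) + 8))
    while True:
        tb = np.zeros((qs_codes.size + 1, width), dtype=np.uint8)
        jlo = np.zeros(qs_codes.size + 1, dtype=np.int64)
        best, bi, bj, overflow = _kernels.xdrop_affine(
            qs_codes, rs_codes, sub, sc.gap_exist, sc.gap_extend,
            ydrop, width, tb, jlo,
        )
        if not overflow:
            ops = _traceback(tb, jlo, bi, bj) if best > 0 or (bi, bj) != (0, 0) else []
            return int(best), int(bi), int(bj), ops
        if width >= rs_codes.size + 1:
            raise RuntimeError("X-drop window overflow at full width")
        width = int(min(rs_codes.size + 1, width * 2))


def _reverse_runs(runs: list[tuple[str, int]]) -> list[tuple[str, int]]:
    return list(reversed(runs))


def _merge_runs(a: list[tuple[str, int]], b: list[tuple[str, int]]
                ) -> list[tuple[str, int]]:
    if a and b and a[-1][0] == b[0][0]:
        return a[:-1] + [(a[-1][0], a[-1][1] + b[0][1])] + b[1:]
    return a + b


def gapped_extend(
    anchor: GaplessAlignment,
    query: MaskedSequence,
    ref: MaskedSequence,
    sc: ScoringScheme,
    ydrop_gapped: int,
    query_name: str = "query",
    strand: str = "+",
    anchor_col: int | None = None,
) -> AlignmentRecord:
    """Affine-gap X-drop extension in both directions from an anchor column.

    By default the anchor is the column of the gapless segment
    achieving its maximum score (leftmost on ties); anchor_col
    overrides it with an explicit query column on the segment's
    diagonal (the pipeline passes the originating seed's start, so
    that in exhaustive-seeding configurations every candidate anchor
    on an optimal path is tried).  The two half-extensions meet at the
    anchor; the path may pass through it with or without aligning it.
    """
    if ydrop_gapped < 0:
        raise ValueError("ydrop must be >= 0")
    if anchor_col is None:
        qa = anchor.query_start + anchor.anchor
    else:
        qa = anchor_col
    ra = anchor.ref_start - anchor.query_start + qa
    # forward: suffixes starting at the anchor column (inclusive)
    fwd_q = query.code[qa:]
    fwd_r = ref.code[ra:]
    f_best, f_i, f_j, f_ops = _xdrop_one_direction(fwd_q, fwd_r, sc, ydrop_gapped)
    # backward: reversed prefixes ending just before the anchor column
    bwd_q = np.ascontiguousarray(query.code[:qa][::-1])
    bwd_r = np.ascontiguousarray(ref.code[:ra][::-1])
    b_best, b_i, b_j, b_ops = _xdrop_one_direction(bwd_q, bwd_r, sc, ydrop_gapped)

    ops = _merge_runs(_reverse_runs(b_ops), f_ops)
    score = f_best + b_best
    rec = AlignmentRecord(
        query_name=query_name,
        ref_name=ref.name,
        query_start=qa - b_i,
        query_end=qa + f_i,
        ref_start=ra - b_j,
        ref_end=ra + f_j,
        strand=strand,
        score=int(score),
        ops=ops,
        query_length=query.length,
        ref_length=ref.length,
    )
    return rec


def align(
    query: MaskedSequence,
    indexes: list[SubsetSuffixIndex],
    sc: ScoringScheme,
    m: int = 10,
    k: int = 1,
    y: int | None = None,
    d: int | None = None,
    ydrop_gapped: int | None = None,
    strands: str = "both",
) -> list[AlignmentRecord]:
    """Seed-and-extend alignment of a query against indexed references.

    Pipeline per strand: adaptive seeds -> gapless X-drop extension ->
    keep segments with score >= d -> gapped X-drop extension -> keep
    records with score >= the scheme's minimum.  Exact-duplicate
    coordinates are merged; records are sorted by score descending.
    """
    if not indexes:
        raise ValueError("need at least one index")
    ref = indexes[0].reference
    if y is None:
        y = sc.default_y
    if ydrop_gapped is None:
        ydrop_gapped = sc.default_ydrop if sc.default_ydrop is not None else 2 * y + 100
    if d is None:
        r_unmasked = int(np.count_nonzero(ref.code != N_CODE))
        d = sc.default_d(m, len(indexes), max(r_unmasked, 1))
    sub = sc.full_matrix()

    records: dict[tuple, AlignmentRecord] = {}
    strand_list = ["+", "-"] if strands == "both" else [strands]
    for strand in strand_list:
        q = query if strand == "+" else query.reverse_complement()
        # collect seeds over all patterns, then extend gaplessly in batch;
        # one gapped extension per distinct (segment, seed-cell anchor)
        seen_anchors: set[tuple[int, int, int, int]] = set()
        for idx in indexes:
            qp, rp, ln = adaptive_seeds_arrays(q, idx, m, k)
            if qp.size == 0:
                continue
            out = np.empty((qp.size, 6), dtype=np.int64)
            _kernels.gapless_extend_batch(qp, rp, ln, q.code, ref.code,
                                          sub, y, out)
            good = out[:, 4] >= d
            for seed_q, (qs, qe, rs, re, score, anchor_off) in zip(
                qp[good], out[good]
            ):
                key = (int(qs), int(qe), int(rs), int(seed_q))
                if key in seen_anchors:
                    continue
                seen_anchors.add(key)
                seg = GaplessAlignment(int(qs), int(qe), int(rs), int(re),
                                       int(score), int(anchor_off))
                rec = gapped_extend(seg, q, ref, sc, ydrop_gapped,
                                    query_name=query.name, strand=strand,
                                    anchor_col=int(seed_q))
                if rec.score >= sc.min_score:
                    prev = records.get(rec.coordinates())
                    if prev is None or rec.score > prev.score:
                        records[rec.coordinates()] = rec
    out_records = sorted(records.values(), key=lambda r: (-r.score, r.coordinates()))
    return out_records
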
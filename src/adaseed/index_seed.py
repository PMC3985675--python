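"""Subset suffix arrays and adaptive seed discovery.

A reference is indexed once per seed pattern: sampled suffix positions
are sorted under the position-dependent letter equivalence classes of
the cyclically extended pattern ('1' keeps the four bases distinct, 'T'
merges the transition pairs A/G and C/T, '0' merges everything; N acts
as a terminator).  Adaptive seeds are then found by narrowing a suffix
array interval one pattern position at a time until the number of
matching reference positions drops to the rareness threshold m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .patterns import SeedPattern

logger = logging.getLogger(__name__)

BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASE = "ACGTN"
N_CODE = 4

_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


@dataclass
class MaskedSequence:
    """A sequence ready for indexing/alignment: only A, C, G, T, N.

    Lowercase (repeat-masked) letters and any non-ACGT uppercase have
    already been replaced by N.  ``code`` holds the uint8 encoding.
    """

    name: str
    code: np.ndarray

    @property
    def length(self) -> int:
        return int(self.code.size)

    @property
    def letters(self) -> str:
        return "".join(CODE_BASE[c] for c in self.code)

    def reverse_complement(self) -> "MaskedSequence":
        return MaskedSequence(self.name, _COMPLEMENT[self.code[::-1]].copy())


def mask_lowercase(seq: str, name: str = "seq") -> MaskedSequence:
    """Replace every lowercase letter, and any non-ACGT, with N.

    Lowercase indicates repeat masking; repeats must neither seed nor
    score as matches, so they become N before indexing and alignment.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = _ENCODE_TABLE[raw]  # table maps only uppercase ACGT; rest -> N
    return MaskedSequence(name, code)


def _pattern_classmap(pattern: SeedPattern) -> np.ndarray:
    """(period x 5) map from (pattern position, base code) to class code.

    Class 0 is the terminator (N); real classes start at 1.  At a 'T'
    position A/G share a class and C/T share a class; at a '0' position
    all four bases share one class.
    """
    period = pattern.span
    cm = np.zeros((period, 5), dtype=np.uint8)
    for j, sym in enumerate(pattern.symbols):
        if sym == "1":
            cm[j, :4] = (1, 2, 3, 4)
        elif sym == "T":
            cm[j, :4] = (1, 2, 1, 2)  # A,G -> purine class; C,T -> pyrimidine
        else:  # '0'
            cm[j, :4] = (1, 1, 1, 1)
        cm[j, 4] = 0
    return cm


@dataclass
class SubsetSuffixIndex:
    """Suffix array of sampled reference positions under pattern classes."""

    pattern: SeedPattern
    reference: MaskedSequence
    sa: np.ndarray
    step: int = 1
    max_depth: int = 512
    classmap: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.classmap is None:
            self.classmap = _pattern_classmap(self.pattern)


@dataclass(frozen=True)
class SeedMatch:
    """A minimal-length adaptive seed hit."""

    query_pos: int
    ref_pos: int
    length: int
    pattern_id: int = 0


def _transformed_keys(
    code: np.ndarray, positions: np.ndarray, classmap: np.ndarray, depth: int
) -> np.ndarray:
    """(n_positions x depth) uint8 class keys with terminator propagation."""
    period = classmap.shape[0]
    n = positions.size
    keys = np.zeros((n, depth), dtype=np.uint8)
    alive = np.ones(n, dtype=bool)
    L = code.size
    for j in range(depth):
        if not alive.any():
            break
        pos = positions + j
        ok = alive & (pos < L)
        cls = np.zeros(n, dtype=np.uint8)
        cls[ok] = classmap[j % period, code[pos[ok]]]
        keys[:, j] = cls
        alive = ok & (cls != 0)
    return keys


def build_index(
    ref: MaskedSequence,
    pattern: SeedPattern,
    w: int = 1,
    max_depth: int = 512,
) -> SubsetSuffixIndex:
    """Sort every w-th reference position by its transformed suffix.

    Positions whose first transformed letter is the terminator (an N at
    a '1'/'T'/'0' position) are excluded.  Ties deeper than max_depth
    are left in position order; adaptive-seed matches are capped at the
    same depth, so search never relies on unsorted depths.
    """
    if w < 1:
        raise ValueError("sample step w must be >= 1")
    if ref.length == 0:
        raise ValueError("cannot index an empty reference")
    classmap = _pattern_classmap(pattern)
    positions = np.arange(0, ref.length, w, dtype=np.int64)
    depth = int(min(max_depth, ref.length))
    keys = _transformed_keys(ref.code, positions, classmap, depth)
    keep = keys[:, 0] != 0
    positions = positions[keep]
    keys = np.ascontiguousarray(keys[keep])
    if positions.size:
        flat = keys.view(f"S{depth}").ravel()
        order = np.argsort(flat, kind="stable")
        sa = positions[order]
    else:
        sa = positions
    logger.debug(
        "indexed %d/%d sampled positions of %s under %s",
        positions.size, (ref.length + w - 1) // w, ref.name, pattern.symbols,
    )
    return SubsetSuffixIndex(pattern, ref, sa, step=w, max_depth=max_depth,
                             classmap=classmap)


def adaptive_seeds(
    query: MaskedSequence,
    idx: SubsetSuffixIndex,
    m: int,
    k: int = 1,
) -> list[SeedMatch]:
    """Minimum-length matches occurring at most m times in the reference.

    From every k-th query start, the match is lengthened along the
    cyclically extended pattern until at most m indexed reference
    positions remain; all of them are then emitted at that minimal
    length.  Starts whose count never drops to m (query end, N, or the
    depth cap reached first) emit nothing.
    """
    qp, rp, ln = adaptive_seeds_arrays(query, idx, m, k)
    return [
        SeedMatch(int(q), int(r), int(l)) for q, r, l in zip(qp, rp, ln)
    ]


def adaptive_seeds_arrays(
    query: MaskedSequence,
    idx: SubsetSuffixIndex,
    m: int,
    k: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array-valued version of :func:`adaptive_seeds` (hot path)."""
    if m < 1:
        raise ValueError("rareness threshold m must be >= 1")
    if k < 1:
        raise ValueError("query step k must be >= 1")
    empty = np.empty(0, dtype=np.int64)
    if query.length == 0 or idx.sa.size == 0:
        return empty, empty, empty
    period = idx.classmap.shape[0]
    n = _kernels.seed_search(
        query.code, idx.sa, idx.reference.code, idx.classmap, period,
        m, k, idx.max_depth, empty, empty, empty, True,
    )
    out_q = np.empty(n, dtype=np.int64)
    out_r = np.empty(n, dtype=np.int64)
    out_len = np.empty(n, dtype=np.int64)
    _kernels.seed_search(
        query.code, idx.sa, idx.reference.code, idx.classmap, period,
        m, k, idx.max_depth, out_q, out_r, out_len, False,
    )
    return out_q, out_r, out_len


def adaptive_seeds_bruteforce(
    query: MaskedSequence,
    ref: MaskedSequence,
    pattern: SeedPattern,
    m: int,
    k: int = 1,
    w: int = 1,
    max_depth: int = 512,
) -> list[SeedMatch]:
    """Quadratic-scan oracle for adaptive seeds (small references only).

    Re-derives per-position class matching directly from the pattern
    symbols, with no suffix array involved.
    """
    classmap = _pattern_classmap(pattern)
    period = pattern.span
    qc, rc = query.code, ref.code
    sampled = [p for p in range(0, ref.length, w)
               if classmap[0, rc[p]] != 0]
    out: list[SeedMatch] = []
    for q in range(0, query.length, k):
        live = list(sampled)
        j = 0
        while True:
            if q + j >= query.length or j >= max_depth:
                break
            qcls = classmap[j % period, qc[q + j]]
            if qcls == 0:
                break
            live = [
                p for p in live
                if p + j < ref.length and classmap[j % period, rc[p + j]] == qcls
            ]
            if not live:
                break
            if len(live) <= m:
                out.extend(SeedMatch(q, p, j + 1) for p in live)
                break
            j += 1
    return out


def save_index(idx: SubsetSuffixIndex, path: str | Path) -> None:
    """Persist the suffix array and metadata as a JSON sidecar."""
    payload = {
        "pattern": idx.pattern.symbols,
        "step": idx.step,
        "max_depth": idx.max_depth,
        "reference_name": idx.reference.name,
        "reference_length": idx.reference.length,
        "sa": idx.sa.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_index(path: str | Path, ref: MaskedSequence) -> SubsetSuffixIndex:
    payload = json.loads(Path(path).read_text())
    if payload["reference_length"] != ref.length:
        raise ValueError("index does not match the supplied reference")
    return SubsetSuffixIndex(
        SeedPattern(payload["pattern"]),
        ref,
        np.asarray(payload["sa"], dtype=np.int64),
        step=payload["step"],
        max_depth=payload["max_depth"],
    )
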
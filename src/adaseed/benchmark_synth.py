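"""Synthetic related-genome pairs and the chunk-based sensitivity benchmark.

The simulator produces an ancestral genome and a diverged copy with a
configurable per-column identity, transition:transversion ratio, indel
rate, and lowercase-masked self-similar repeat tracts, recording the
true column-level homology so that substitution rates can be counted
without re-alignment.  The benchmark takes random 1 kb chunks of one
genome, aligns them to the other under a grid of configurations, and
counts per configuration the chunks whose best score falls short of
the best score any configuration achieved on that chunk.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extend_align import ScoringScheme, align
from .index_seed import MaskedSequence, build_index, mask_lowercase
from .patterns import SeedSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_LOWER = np.frombuffer(b"acgt", dtype=np.uint8)
#: transition partner of each base code (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
#: the two transversion partners of each base code
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome pair.

    identity is the per-aligned-column match probability; the remaining
    probability is split between transitions and transversions in the
    ts_tv_ratio (e.g. 1.5 for 3:2, matching distant mammal genomes
    where roughly 70% of aligned columns are identical, 18% transitions
    and 12% transversions).  Indels occur at indel_rate per ancestral
    base, insertion or deletion with equal probability, with geometric
    lengths of the given mean.  repeat_fraction of the ancestor is
    overwritten by copies of other segments and lowercased (so repeats
    are self-similar, as real repeats are).
    """

    genome_length: int = 1_000_000
    identity: float = 0.70
    ts_tv_ratio: float = 1.5
    indel_rate: float = 0.02
    indel_length_mean: float = 3.0
    repeat_fraction: float = 0.0
    repeat_length: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must be in [0, 1]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")

    @property
    def p_transition(self) -> float:
        return (1 - self.identity) * self.ts_tv_ratio / (1 + self.ts_tv_ratio)

    @property
    def p_transversion(self) -> float:
        return (1 - self.identity) / (1 + self.ts_tv_ratio)


@dataclass
class GenomePair:
    """A simulated pair with its recorded truth alignment.

    ancestor/derived are case-preserving base strings (lowercase =
    repeat-masked).  anc_idx/der_idx give, per aligned (gapless truth)
    column, the 0-based coordinates in each sequence.  blocks lists the
    maximal colinear gapless interval pairs
    (anc_start, anc_end, der_start, der_end).
    """

    ancestor: str
    derived: str
    anc_idx: np.ndarray
    der_idx: np.ndarray
    blocks: list[tuple[int, int, int, int]]


def synth_genome_pair(cfg: SimulationConfig) -> GenomePair:
    """Simulate a related genome pair with recorded truth columns."""
    rng = np.random.default_rng(cfg.rng_seed)
    L = cfg.genome_length
    anc = rng.integers(0, 4, size=L, dtype=np.int8)
    lower = np.zeros(L, dtype=bool)

    # self-similar repeats: overwrite target segments with copies of
    # random source segments and lowercase the targets
    if cfg.repeat_fraction > 0 and L > 2 * cfg.repeat_length:
        target_bases = int(cfg.repeat_fraction * L)
        placed = 0
        while placed < target_bases:
            length = min(cfg.repeat_length, target_bases - placed)
            if length < 1:
                break
            src = int(rng.integers(0, L - length))
            dst = int(rng.integers(0, L - length))
            anc[dst:dst + length] = anc[src:src + length]
            lower[dst:dst + length] = True
            placed += length

    # per-column substitutions on the whole ancestor
    u = rng.random(L)
    der_aligned = anc.copy()
    is_ts = u < cfg.p_transition
    is_tv = (u >= cfg.p_transition) & (u < cfg.p_transition + cfg.p_transversion)
    der_aligned[is_ts] = _TRANSITION[anc[is_ts]]
    pick = rng.integers(0, 2, size=int(is_tv.sum()))
    der_aligned[is_tv] = _TRANSVERSIONS[anc[is_tv], pick]

    # indels: at each ancestral position, an event with prob indel_rate;
    # deletions remove derived columns, insertions add new derived bases
    ev = rng.random(L) < cfg.indel_rate
    ev_pos = np.flatnonzero(ev)
    is_del = rng.random(ev_pos.size) < 0.5
    # geometric with mean indel_length_mean (support >= 1)
    p_geom = 1.0 / max(cfg.indel_length_mean, 1.0)
    lengths = rng.geometric(p_geom, size=ev_pos.size)

    deleted = np.zeros(L, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    for pos, dele, ln in zip(ev_pos, is_del, lengths):
        if dele:
            deleted[pos:pos + ln] = True
        else:
            insertions[int(pos)] = rng.integers(0, 4, size=int(ln), dtype=np.int8)

    # assemble the derived sequence and the truth column map
    der_parts: list[np.ndarray] = []
    der_lower_parts: list[np.ndarray] = []
    kept = ~deleted
    anc_idx = np.flatnonzero(kept)
    der_idx = np.empty_like(anc_idx)
    cursor = 0
    out_len = 0
    ins_positions = sorted(insertions)
    ptr = 0
    # walk segments between insertion points
    seg_start = 0
    for ipos in ins_positions + [L]:
        seg_kept = kept[seg_start:ipos]
        seg = der_aligned[seg_start:ipos][seg_kept]
        der_parts.append(seg)
        der_lower_parts.append(lower[seg_start:ipos][seg_kept])
        n_kept_before = cursor
        # derived coords of kept columns in this segment
        n_seg = seg.size
        der_idx[n_kept_before:n_kept_before + n_seg] = out_len + np.arange(n_seg)
        cursor += n_seg
        out_len += n_seg
        if ipos < L:
            ins = insertions[ipos]
            der_parts.append(ins)
            der_lower_parts.append(np.zeros(ins.size, dtype=bool))
            out_len += ins.size
        seg_start = ipos
        ptr += 1

    der = np.concatenate(der_parts) if der_parts else np.empty(0, dtype=np.int8)
    der_lower = (np.concatenate(der_lower_parts)
                 if der_lower_parts else np.empty(0, dtype=bool))

    def to_text(codes: np.ndarray, lower_mask: np.ndarray) -> str:
        up = _BASES[codes]
        lo = _BASES_LOWER[codes]
        return np.where(lower_mask, lo, up).tobytes().decode("ascii")

    blocks = _colinear_blocks(anc_idx, der_idx)
    return GenomePair(
        ancestor=to_text(anc, lower),
        derived=to_text(der, der_lower),
        anc_idx=anc_idx,
        der_idx=der_idx,
        blocks=blocks,
    )


def _colinear_blocks(anc_idx: np.ndarray, der_idx: np.ndarray
                     ) -> list[tuple[int, int, int, int]]:
    if anc_idx.size == 0:
        return []
    breaks = np.flatnonzero(
        (np.diff(anc_idx) != 1) | (np.diff(der_idx) != 1)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [anc_idx.size]))
    return [
        (int(anc_idx[s]), int(anc_idx[e - 1]) + 1,
         int(der_idx[s]), int(der_idx[e - 1]) + 1)
        for s, e in zip(starts, ends)
    ]


def count_substitutions(ref_bases: str | np.ndarray, other_bases: str | np.ndarray
                        ) -> tuple[float, float, float]:
    """(identity%, transition%, transversion%) over aligned ACGT columns.

    Transitions are A<->G and C<->T; every other mismatch is a
    transversion.  Columns containing a gap, N, or any non-ACGT letter
    are excluded from the denominator.
    """
    def encode(x) -> np.ndarray:
        if isinstance(x, np.ndarray) and x.dtype != np.dtype("U1"):
            return x.astype(np.int8)
        s = "".join(x).upper()
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        code = np.full(raw.size, -1, dtype=np.int8)
        for i, b in enumerate("ACGT"):
            code[raw == ord(b)] = i
        return code

    a = encode(ref_bases)
    b = encode(other_bases)
    if a.size != b.size:
        raise ValueError("aligned columns must have equal length")
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no valid ACGT columns")
    a, b = a[ok], b[ok]
    n = a.size
    ident = np.count_nonzero(a == b)
    ts = np.count_nonzero((a != b) & (_TRANSITION[a] == b))
    tv = n - ident - ts
    return 100.0 * ident / n, 100.0 * ts / n, 100.0 * tv / n


def sample_chunks(
    genome: str,
    count: int,
    length: int,
    rng: np.random.Generator,
    max_rejections: int = 100_000,
) -> list[tuple[int, str]]:
    """Random chunks with no non-ACGT uppercase letter.

    Start positions are drawn without replacement; chunks containing an
    uppercase letter outside ACGT (e.g. N runs) are rejected and
    redrawn, up to max_rejections.  Lowercase letters are allowed: they
    are masked later, not here.  Returns (start, chunk) pairs.
    """
    L = len(genome)
    if L <= length:
        raise ValueError("genome shorter than the chunk length")
    raw = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    is_upper = (raw >= ord("A")) & (raw <= ord("Z"))
    ok_upper = np.isin(raw, np.frombuffer(b"ACGT", dtype=np.uint8))
    bad = is_upper & ~ok_upper
    bad_cum = np.concatenate(([0], np.cumsum(bad)))

    chosen: list[tuple[int, str]] = []
    used: set[int] = set()
    rejections = 0
    while len(chosen) < count:
        start = int(rng.integers(0, L - length + 1))
        if start in used:
            continue
        used.add(start)
        if bad_cum[start + length] - bad_cum[start] > 0:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"rejected {rejections} chunks; genome too N-rich"
                )
            continue
        chosen.append((start, genome[start:start + length]))
    return chosen


@dataclass(frozen=True)
class AlignConfig:
    """One benchmark configuration: a seed set plus aligner knobs."""

    label: str
    seeds: SeedSet
    m: int
    k: int = 1
    y: int | None = None
    d: int | None = None
    ydrop: int | None = None
    w: int = 1


def error_counts(scores: np.ndarray) -> np.ndarray:
    """Per-config error counts from a (chunks x configs) score matrix.

    A config errs on a chunk when its best score is below the maximum
    best score any config achieved on that chunk; a single config
    therefore has zero errors by definition.
    """
    scores = np.asarray(scores)
    best = scores.max(axis=1)
    return (scores < best[:, None]).sum(axis=0)


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # columns: label, errors, total_chunks, wall_time_s
    per_chunk: pd.DataFrame = field(repr=False, default=None)  # scores per config

    def errors(self, label: str) -> int:
        row = self.table[self.table.label == label]
        return int(row.errors.iloc[0])


def run_benchmark(
    chunks: list[tuple[int, str]],
    target_genome: str,
    configs: list[AlignConfig],
    sc: ScoringScheme,
    max_depth: int = 64,
) -> BenchmarkResult:
    """Per-chunk best scores under each config, and per-config error counts.

    A config's error count is the number of chunks where its best score
    is below the maximum best score any config achieved on that chunk.
    Chunks and target are lowercase-masked before alignment.  Indexes
    are built once per distinct (pattern, w) and shared across configs.
    """
    if not configs:
        raise ValueError("need at least one config")
    target = mask_lowercase(target_genome, "target")
    index_cache: dict[tuple[str, int], object] = {}

    def get_index(pattern, w):
        key = (pattern.symbols, w)
        if key not in index_cache:
            index_cache[key] = build_index(target, pattern, w=w,
                                           max_depth=max_depth)
        return index_cache[key]

    masked_chunks = [
        mask_lowercase(text, f"chunk_{start}") for start, text in chunks
    ]
    scores = np.zeros((len(chunks), len(configs)), dtype=np.int64)
    times = np.zeros(len(configs))
    for ci, cfg in enumerate(configs):
        indexes = [get_index(p, cfg.w) for p in cfg.seeds]
        t0 = time.perf_counter()
        for qi, q in enumerate(masked_chunks):
            recs = align(q, indexes, sc, m=cfg.m, k=cfg.k, y=cfg.y,
                         d=cfg.d, ydrop_gapped=cfg.ydrop)
            scores[qi, ci] = recs[0].score if recs else 0
        times[ci] = time.perf_counter() - t0

    errors = error_counts(scores)
    table = pd.DataFrame({
        "label": [c.label for c in configs],
        "errors": errors,
        "total_chunks": len(chunks),
        "wall_time_s": times,
    })
    per_chunk = pd.DataFrame(scores, columns=[c.label for c in configs])
    return BenchmarkResult(table=table, per_chunk=per_chunk)
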
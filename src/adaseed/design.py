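"""Hill-climbing co-design of transition-constrained seed patterns.

Seeds are designed for a fixed weight (number of '1's plus half the
number of 'T's) and a bounded span, maximizing the exact Bernoulli
sensitivity of the whole set on gapless alignments of a chosen length.
The search is random-restart greedy hill climbing; for multiple seeds
the climb is coordinate-wise, improving one pattern at a time against
the joint sensitivity of the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .patterns import SeedPattern, SeedSet
from .sensitivity import BernoulliModel, sensitivity_dp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    """Parameters for seed-set design.

    ``weight`` is a half-integer (2*weight must be integral); spans are
    searched in ``[span_min, span_max]``; ``l`` is the gapless-alignment
    length the sensitivity objective uses; ``c`` the seeding sparsity.
    """

    n: int
    weight: float
    span_min: int
    span_max: int
    model: BernoulliModel
    l: int = 64
    c: int = 1
    restarts: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (1 <= self.span_min <= self.span_max):
            raise ValueError("need 1 <= span_min <= span_max")
        if self.weight > self.span_min:
            raise ValueError("weight must be <= span_min")
        if round(2 * self.weight) != 2 * self.weight:
            raise ValueError("weight must be a half-integer")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class DesignResult:
    seeds: SeedSet
    sensitivity: float
    history: list[float] = field(default_factory=list)  # best-so-far per restart


def feasible_counts(weight: float, span: int) -> list[tuple[int, int]]:
    """All (k1, kT) with k1 + kT/2 == weight and k1 + kT <= span."""
    tw = round(2 * weight)
    out = []
    for kT in range(0, tw + 1, 2 if tw % 2 == 0 else 1):
        if (tw - kT) % 2:
            continue
        k1 = (tw - kT) // 2
        if k1 >= 0 and k1 + kT <= span:
            out.append((k1, kT))
    return out


def random_pattern(weight: float, span: int, rng: np.random.Generator) -> SeedPattern:
    """Uniformly random pattern of the requested weight and span.

    Picks feasible symbol counts (k1 ones, kT transition symbols) at
    random, shuffles positions, and forces the first and last symbol to
    be non-'0' by swapping when needed (conventional for designed
    seeds; with a single non-'0' symbol only the first position can be
    forced).  Trimming may later remove the constraint.
    """
    choices = feasible_counts(weight, span)
    if not choices:
        raise ValueError(f"no feasible pattern with weight {weight}, span {span}")
    k1, kT = choices[rng.integers(len(choices))]
    symbols = ["1"] * k1 + ["T"] * kT + ["0"] * (span - k1 - kT)
    rng.shuffle(symbols)
    # force non-'0' endpoints when any non-'0' symbol exists
    nonzero = [i for i, x in enumerate(symbols) if x != "0"]
    if nonzero:
        if symbols[0] == "0":
            i = nonzero[0]
            symbols[0], symbols[i] = symbols[i], symbols[0]
            nonzero = [i for i, x in enumerate(symbols) if x != "0"]
        if symbols[-1] == "0" and nonzero[-1] != 0:
            i = nonzero[-1]
            symbols[-1], symbols[i] = symbols[i], symbols[-1]
    return SeedPattern("".join(symbols))


def neighbors(p: SeedPattern) -> list[SeedPattern]:
    """Weight-preserving local moves, duplicates removed.

    Moves: (i) swap two unequal symbols; (ii) turn one '1' into two 'T's
    placed at a '0' and the '1' position; (iii) turn two 'T's into a '1'
    and a '0'.  Span is always preserved.
    """
    s = list(p.symbols)
    n = len(s)
    seen: dict[str, None] = {}

    def add(sym_list: list[str]) -> None:
        text = "".join(sym_list)
        if text != p.symbols:
            seen.setdefault(text)

    for i in range(n):
        for j in range(i + 1, n):
            if s[i] != s[j]:
                t = s.copy()
                t[i], t[j] = t[j], t[i]
                add(t)
    ones = [i for i, x in enumerate(s) if x == "1"]
    zeros = [i for i, x in enumerate(s) if x == "0"]
    ts = [i for i, x in enumerate(s) if x == "T"]
    for i in ones:  # '1' -> 'T', '0' -> 'T'
        for j in zeros:
            t = s.copy()
            t[i] = "T"
            t[j] = "T"
            add(t)
    for a_idx in range(len(ts)):  # two 'T's -> '1' + '0'
        for b_idx in range(a_idx + 1, len(ts)):
            i, j = ts[a_idx], ts[b_idx]
            for one_pos, zero_pos in ((i, j), (j, i)):
                t = s.copy()
                t[one_pos] = "1"
                t[zero_pos] = "0"
                add(t)
    return [SeedPattern(text) for text in seen]


def _climb_one(
    patterns: list[SeedPattern],
    idx: int,
    score: float,
    cfg: DesignConfig,
) -> tuple[list[SeedPattern], float, bool]:
    """Try to improve pattern ``idx`` against the joint sensitivity."""
    best, best_score = patterns, score
    improved = False
    for cand in sorted(neighbors(patterns[idx]), key=lambda q: q.symbols):
        trial = patterns.copy()
        trial[idx] = cand
        sc = sensitivity_dp(SeedSet(tuple(trial)), cfg.model, cfg.l, cfg.c)
        # strict improvement; ties keep the lexicographically smaller text
        if sc > best_score + 1e-15 or (
            abs(sc - best_score) <= 1e-15 and cand.symbols < best[idx].symbols
        ):
            best, best_score = trial, sc
            improved = True
    return best, best_score, improved


def design_seeds(cfg: DesignConfig) -> DesignResult:
    """Random-restart greedy hill climbing over seed sets.

    Each restart draws ``n`` random patterns (random feasible spans),
    then repeatedly sweeps the patterns coordinate-wise, replacing one
    with its best improving neighbor, until no move improves the joint
    sensitivity.  Deterministic given ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    best_set: list[SeedPattern] | None = None
    best_score = -1.0
    history: list[float] = []
    for r in range(cfg.restarts):
        spans = rng.integers(cfg.span_min, cfg.span_max + 1, size=cfg.n)
        patterns = [random_pattern(cfg.weight, int(sp), rng) for sp in spans]
        score = sensitivity_dp(SeedSet(tuple(patterns)), cfg.model, cfg.l, cfg.c)
        moved = True
        while moved:
            moved = False
            for i in range(cfg.n):
                patterns, score, improved = _climb_one(patterns, i, score, cfg)
                moved = moved or improved
        if score > best_score or (
            score == best_score
            and best_set is not None
            and [p.symbols for p in patterns] < [p.symbols for p in best_set]
        ):
            best_set, best_score = patterns, score
        history.append(best_score)
        logger.debug("restart %d: best sensitivity so far %.6f", r, best_score)
    assert best_set is not None
    return DesignResult(SeedSet(tuple(best_set)), best_score, history)
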
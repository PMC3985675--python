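"""Exact hit probability of a seed set on i.i.d. gapless alignments.

The alignment model is a Bernoulli (i.i.d.) distribution over the
three-letter alignment alphabet (transversion, transition, match).  The
sensitivity of a seed set for alignments of length ``l`` is the
probability that at least one pattern in the set hits the alignment at
an allowed start offset.  It is computed exactly by forward dynamic
programming over a deterministic automaton that recognizes "some seed
has hit", and cross-checkable against a brute-force enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import (
    ACCEPTS,
    ALIGNMENT_LETTERS,
    MATCH,
    TRANSITION,
    TRANSVERSION,
    SeedSet,
)


@dataclass(frozen=True)
class BernoulliModel:
    """I.i.d. probabilities of (transversion, transition, match).

    The letter order matches the convention used throughout this
    package: probabilities are always given as (p_v, p_s, p_m).
    """

    p_v: float
    p_s: float
    p_m: float

    def __post_init__(self) -> None:
        probs = (self.p_v, self.p_s, self.p_m)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"probabilities must be in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1: {probs}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_v, self.p_s, self.p_m], dtype=float)

    @classmethod
    def from_string(cls, text: str) -> "BernoulliModel":
        """Parse ``"pv,ps,pm"`` (e.g. ``"0.12,0.18,0.7"``)."""
        parts = [float(x) for x in text.split(",")]
        if len(parts) != 3:
            raise ValueError(f"expected three comma-separated probabilities: {text!r}")
        return cls(*parts)


class SeedAutomaton:
    """Deterministic automaton recognizing "some seed in the set has hit".

    States track (position mod sparsity, live pattern-prefix positions);
    the single accepting state is absorbing.  ``transitions[state, letter]``
    gives the successor over the 3-letter alphabet.
    """

    def __init__(self, transitions: np.ndarray, start: int, accept: int):
        self.transitions = transitions
        self.start = start
        self.accept = accept

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    def accepts(self, letters) -> bool:
        state = self.start
        for a in letters:
            state = self.transitions[state, a]
            if state == self.accept:
                return True
        return state == self.accept


def build_automaton(s: SeedSet, c: int = 1) -> SeedAutomaton:
    """Subset construction over live pattern-prefix positions.

    A live item ``(pattern_id, j)`` records that the last ``j`` consumed
    letters match the first ``j`` symbols of a pattern whose start offset
    was a multiple of the sparsity ``c``.  New items can only be seeded
    when the current position is such a multiple; completing any pattern
    moves to the absorbing accepting state.
    """
    if c < 1:
        raise ValueError("sparsity must be >= 1")
    pats = [p.symbols for p in s]

    ACCEPT = "ACCEPT"
    start_key = (0, frozenset())
    index: dict = {start_key: 0, ACCEPT: 1}
    table: list[list[int]] = [[0, 0, 0], [1, 1, 1]]
    stack = [start_key]
    while stack:
        key = stack.pop()
        r, items = key
        src = index[key]
        for a in ALIGNMENT_LETTERS:
            hit = False
            new_items = set()
            candidates = list(items)
            if r == 0:
                candidates.extend((pid, 0) for pid in range(len(pats)))
            for pid, j in candidates:
                if a in ACCEPTS[pats[pid][j]]:
                    if j + 1 == len(pats[pid]):
                        hit = True
                        break
                    new_items.add((pid, j + 1))
            if hit:
                table[src][a] = 1
                continue
            new_key = ((r + 1) % c, frozenset(new_items))
            if new_key not in index:
                index[new_key] = len(table)
                table.append([0, 0, 0])
                stack.append(new_key)
            table[src][a] = index[new_key]
    return SeedAutomaton(np.asarray(table, dtype=np.int64), start=0, accept=1)


def sensitivity_dp(s: SeedSet, model: BernoulliModel, l: int, c: int = 1) -> float:
    """P(the seed set hits a random length-``l`` alignment), exactly.

    Forward DP over the automaton states: the accepting state is
    absorbing, so the returned value is the probability mass there after
    ``l`` steps.
    """
    if l < 0:
        raise ValueError("alignment length must be >= 0")
    auto = build_automaton(s, c)
    probs = model.as_array()
    v = np.zeros(auto.n_states)
    v[auto.start] = 1.0
    trans = auto.transitions
    for _ in range(l):
        nxt = np.zeros_like(v)
        for a in ALIGNMENT_LETTERS:
            np.add.at(nxt, trans[:, a], v * probs[a])
        v = nxt
    return float(v[auto.accept])


def sensitivity_bruteforce(
    s: SeedSet, model: BernoulliModel, l: int, c: int = 1, max_l: int = 14
) -> float:
    """Enumeration oracle: exact sum over all 3^l alignment strings.

    The search tree over strings is pruned at the first position where a
    pattern hit completes (all extensions of a hit prefix are hits, with
    total probability equal to the prefix probability).  Independent of
    the automaton: matching is re-derived from the pattern symbols.
    """
    if l > max_l:
        raise ValueError(f"l={l} too large for brute force (max {max_l})")
    if c < 1:
        raise ValueError("sparsity must be >= 1")
    pats = [p.symbols for p in s]
    probs = (model.p_v, model.p_s, model.p_m)

    def hit_ending_at(letters: list[int]) -> bool:
        end = len(letters)
        for pat in pats:
            off = end - len(pat)
            if off >= 0 and off % c == 0 and all(
                letters[off + j] in ACCEPTS[sym] for j, sym in enumerate(pat)
            ):
                return True
        return False

    total = 0.0
    stack: list[tuple[list[int], float]] = [([], 1.0)]
    while stack:
        letters, p = stack.pop()
        if len(letters) == l:
            continue
        for a, pa in zip(ALIGNMENT_LETTERS, probs):
            if pa == 0.0:
                continue
            ext = letters + [a]
            if hit_ending_at(ext):
                total += p * pa
            else:
                stack.append((ext, p * pa))
    return total


# convenience aliases used by the CLI and benchmark
__all__ = [
    "BernoulliModel",
    "SeedAutomaton",
    "build_automaton",
    "sensitivity_dp",
    "sensitivity_bruteforce",
    "TRANSVERSION",
    "TRANSITION",
    "MATCH",
]
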
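"""Seed patterns over the alphabet {0, T, 1}.

A seed pattern describes which columns of a candidate gapless alignment
must match ('1'), may be a transition, i.e. A<->G or C<->T ('T'), or are
don't-care positions ('0').  The *weight* of a pattern is the number of
'1' symbols plus half the number of 'T' symbols; together with the span
(total length) it governs how rare seed hits are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PATTERN_ALPHABET = frozenset("01T")

#: alignment letters, in the fixed order (transversion, transition, match)
TRANSVERSION, TRANSITION, MATCH = 0, 1, 2
ALIGNMENT_LETTERS = (TRANSVERSION, TRANSITION, MATCH)

#: which alignment letters each seed symbol accepts:
#: '0' accepts anything, 'T' accepts transition and match, '1' only match.
ACCEPTS = {
    "0": frozenset(ALIGNMENT_LETTERS),
    "T": frozenset((TRANSITION, MATCH)),
    "1": frozenset((MATCH,)),
}


@dataclass(frozen=True)
class SeedPattern:
    """A seed pattern: an immutable string over {0, T, 1}.

    Attributes
    ----------
    symbols : str
        The pattern text, e.g. ``"11T0TT010T"``.
    """

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("seed pattern must be non-empty")
        bad = set(self.symbols) - PATTERN_ALPHABET
        if bad:
            raise ValueError(
                f"invalid symbol(s) {sorted(bad)} in pattern {self.symbols!r}; "
                "allowed symbols are '0', 'T', '1'"
            )

    @property
    def span(self) -> int:
        """Total number of symbols."""
        return len(self.symbols)

    @property
    def twice_weight(self) -> int:
        """2 x weight, always an exact integer (avoids float ties)."""
        return 2 * self.symbols.count("1") + self.symbols.count("T")

    @property
    def weight(self) -> float:
        """Number of '1' symbols plus half the number of 'T' symbols."""
        return self.twice_weight / 2

    def __str__(self) -> str:
        return self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]

    def cyclic_symbol(self, i: int) -> str:
        """Symbol at position ``i`` of the infinite cyclic extension."""
        return self.symbols[i % len(self.symbols)]


@dataclass(frozen=True)
class SeedSet:
    """A non-empty collection of seed patterns used together."""

    patterns: tuple[SeedPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("seed set must contain at least one pattern")

    @property
    def n(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


def parse_pattern(text: str) -> SeedPattern:
    """Parse a pattern string such as ``"11T0TT010T"``.

    Only the characters '0', 'T' (uppercase) and '1' are accepted.
    Patterns beginning or ending with '0' are legal (trimming can
    produce them) but unusual, so they draw a warning.
    """
    p = SeedPattern(text)
    if text[0] == "0" or text[-1] == "0":
        warnings.warn(
            f"pattern {text!r} begins or ends with '0'; this is legal "
            "(trimming can produce it) but unusual",
            stacklevel=2,
        )
    return p


def render(p: SeedPattern) -> str:
    """Inverse of :func:`parse_pattern`."""
    return p.symbols


def seed_set(patterns: Iterable[str | SeedPattern]) -> SeedSet:
    """Build a :class:`SeedSet` from strings or patterns."""
    return SeedSet(
        tuple(p if isinstance(p, SeedPattern) else parse_pattern(p) for p in patterns)
    )


def cyclic_extend(p: SeedPattern, length: int) -> SeedPattern:
    """First ``length`` symbols of the infinite cyclic repetition of ``p``.

    E.g. ``110T`` extended to length 12 gives ``110T110T110T``.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    reps = -(-length // p.span)  # ceil division
    return SeedPattern((p.symbols * reps)[:length])


def trim_to_cyclic_prefix(p: SeedPattern) -> SeedPattern:
    """Shortest prefix whose cyclic extension regenerates ``p``.

    A pattern with no shorter generating prefix is returned unchanged.
    Note the result need not be primitive: '1011' trims to '101'
    (because '10' extends to '1010'), yet '101' itself trims to '10' —
    the operation is only idempotent on whole-multiple extensions.
    """
    s = p.symbols
    for k in range(1, len(s) + 1):
        prefix = s[:k]
        reps = -(-len(s) // k)
        if (prefix * reps)[: len(s)] == s:
            return SeedPattern(prefix)
    return p  # unreachable: k == len(s) always works


def pattern_matches_at(p: SeedPattern, letters: Sequence[int], offset: int) -> bool:
    """Does ``p`` match the alignment letters starting at ``offset``?"""
    if offset < 0 or offset + p.span > len(letters):
        return False
    return all(
        letters[offset + j] in ACCEPTS[sym] for j, sym in enumerate(p.symbols)
    )


def seed_hits_alignment(s: SeedSet, letters: Sequence[int], c: int = 1) -> bool:
    """True iff some pattern hits the gapless alignment at an allowed offset.

    Offsets are restricted to multiples of the sparsity ``c``; a pattern
    symbol accepts an alignment letter per :data:`ACCEPTS` ('0' anything,
    'T' transition or match, '1' match only).
    """
    if c < 1:
        raise ValueError("sparsity must be >= 1")
    if len(letters) == 0:
        return False
    for p in s:
        for off in range(0, len(letters) - p.span + 1, c):
            if pattern_matches_at(p, letters, off):
                return True
    return False


def read_seed_file(path: str | Path) -> SeedSet:
    """Read a seed set: one pattern per line, '#' comments and blanks ignored."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_pattern(line))
    if not patterns:
        raise ValueError(f"no seed patterns found in {path}")
    return SeedSet(tuple(patterns))


def write_seed_file(s: SeedSet, path: str | Path) -> None:
    """Write a seed set, one pattern per line."""
    Path(path).write_text("".join(f"{p.symbols}\n" for p in s))
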
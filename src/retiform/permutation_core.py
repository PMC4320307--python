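"""Permutations of 1..n, lexicographic ranking, and negation operators.

A permutation system on *n* values carries ``n - 1`` negation operators
``N_1 .. N_{n-1}``.  Under the default *value-swap* semantics, ``N_i``
exchanges the numerals ``i`` and ``i + 1`` wherever they stand; under
*position-swap* semantics it exchanges the entries at positions ``i`` and
``i + 1``.  Both are involutions and yield isomorphic adjacency structures
(the inverse-permutation map carries one onto the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from retiform.errors import BoundError, OperatorError, ValidationError

#: Default upper bound on the valuedness; raising it is an explicit opt-in.
DEFAULT_MAX_N = 8


class Semantics(str, Enum):
    """Which adjacent pair a negation operator exchanges."""

    VALUE = "value"
    POSITION = "position"


@dataclass(frozen=True, order=True)
class Permutation:
    """An arrangement of the integers ``1..n``, each exactly once."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.values)
        if n < 1:
            raise ValidationError("permutation must contain at least one value")
        if sorted(self.values) != list(range(1, n + 1)):
            raise ValidationError(
                f"values {self.values!r} are not a bijection of 1..{n}"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    def inverse(self) -> "Permutation":
        """The inverse arrangement: position of each value, read off in value order."""
        inv = [0] * self.n
        for pos, val in enumerate(self.values, start=1):
            inv[val - 1] = pos
        return Permutation(tuple(inv))

    def parity(self) -> int:
        """0 for even permutations, 1 for odd."""
        inversions = sum(
            1
            for a in range(self.n)
            for b in range(a + 1, self.n)
            if self.values[a] > self.values[b]
        )
        return inversions % 2

    def __str__(self) -> str:
        return format_permutation(self)

    @classmethod
    def from_string(cls, text: str) -> "Permutation":
        return parse_permutation(text)


@dataclass(frozen=True)
class PermutationSystem:
    """The n-valued system: its size ``n!`` and operator alphabet ``N_1..N_{n-1}``."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise BoundError(f"valuedness must be >= 1, got {self.n}")

    @property
    def size(self) -> int:
        return math.factorial(self.n)

    @property
    def operator_count(self) -> int:
        return self.n - 1

    @property
    def operators(self) -> range:
        return range(1, self.n)


def _check_n(n: int, max_n: int) -> None:
    if not isinstance(n, int) or isinstance(n, bool):
        raise BoundError(f"valuedness must be an integer, got {n!r}")
    if n < 1 or n > max_n:
        raise BoundError(
            f"valuedness n={n} outside the permitted range 1..{max_n}; "
            "pass max_n explicitly to raise the cap"
        )


def all_permutations(n: int, max_n: int = DEFAULT_MAX_N) -> list[Permutation]:
    """All ``n!`` permutations of ``1..n`` in strictly increasing lexicographic order."""
    _check_n(n, max_n)
    import itertools

    return [Permutation(v) for v in itertools.permutations(range(1, n + 1))]


def lex_rank(p: Permutation) -> int:
    """1-based lexicographic rank of ``p`` among all permutations of 1..n.

    Computed with the factorial number system in O(n^2); the identity has
    rank 1 and the reversed arrangement rank n!.
    """
    n = p.n
    rank = 0
    remaining = list(p.values)
    for i, v in enumerate(p.values):
        smaller = sum(1 for w in remaining if w < v)
        rank += smaller * math.factorial(n - 1 - i)
        remaining.remove(v)
    return rank + 1


def lex_unrank(k: int, n: int, max_n: int = DEFAULT_MAX_N) -> Permutation:
    """The ``k``-th (1-based) permutation of ``1..n`` in lexicographic order."""
    _check_n(n, max_n)
    size = math.factorial(n)
    if not isinstance(k, int) or isinstance(k, bool) or k < 1 or k > size:
        raise BoundError(f"rank k={k!r} outside 1..{size} for n={n}")
    k -= 1
    pool = list(range(1, n + 1))
    out: list[int] = []
    for i in range(n, 0, -1):
        f = math.factorial(i - 1)
        idx, k = divmod(k, f)
        out.append(pool.pop(idx))
    return Permutation(tuple(out))


def apply_negation(
    p: Permutation, i: int, semantics: Semantics = Semantics.VALUE
) -> Permutation:
    """Apply negation operator ``N_i`` to ``p``.

    Value-swap semantics exchanges the numerals ``i`` and ``i+1`` wherever
    they stand; position-swap exchanges the entries at positions ``i`` and
    ``i+1``.  Either way the operator is an involution.
    """
    if not isinstance(i, int) or isinstance(i, bool) or i < 1 or i > p.n - 1:
        raise OperatorError(
            f"operator index {i!r} outside 1..{p.n - 1} for an n={p.n} system"
        )
    semantics = Semantics(semantics)
    if semantics is Semantics.VALUE:
        swapped = tuple(
            i + 1 if v == i else i if v == i + 1 else v for v in p.values
        )
    else:
        vals = list(p.values)
        vals[i - 1], vals[i] = vals[i], vals[i - 1]
        swapped = tuple(vals)
    return Permutation(swapped)


def format_permutation(p: Permutation) -> str:
    """Digit string for n <= 9 (``"1234"``), comma-separated otherwise."""
    if p.n <= 9:
        return "".join(str(v) for v in p.values)
    return ",".join(str(v) for v in p.values)


def parse_permutation(text: str) -> Permutation:
    """Inverse of :func:`format_permutation`; raises ValidationError on malformed input."""
    text = text.strip()
    if not text:
        raise ValidationError("empty permutation string")
    try:
        if "," in text:
            values = tuple(int(t) for t in text.split(","))
        else:
            values = tuple(int(c) for c in text)
    except ValueError as exc:
        raise ValidationError(f"cannot parse permutation string {text!r}") from exc
    return Permutation(values)


def write_permutations(perms: Iterable[Permutation], path) -> None:
    """One permutation per line, digit-string format."""
    with open(path, "w") as fh:
        for p in perms:
            fh.write(format_permutation(p) + "\n")


def read_permutations(path) -> Iterator[Permutation]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield parse_permutation(line)
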
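"""Hamilton loops through the permutograph and their tabulations.

A Hamilton loop is a closed walk that visits every one of the n!
permutations exactly once; in this model each such loop is one intentional
program.  The module verifies candidate loops, constructs one
deterministically by plain changes, exhaustively enumerates all of them
for small systems (n <= 4; the quadrivalent system has 44 up to rotation
and reversal, 88 directed), and tabulates the visit orders obtained by
entering a loop at every possible start (the Guenther matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from retiform.errors import BoundError, RefusalError, ValidationError
from retiform.permutation_core import (
    Permutation,
    Semantics,
    apply_negation,
    format_permutation,
    lex_rank,
    lex_unrank,
)

Counting = Literal["directed", "undirected"]


@dataclass(frozen=True)
class HamiltonLoop:
    """A start permutation plus a sequence of n! operator indices.

    ``direction`` is bookkeeping only (+1 forward, -1 for a reversal); it
    does not affect how ``ops`` are applied.
    """

    start: Permutation
    ops: tuple[int, ...]
    direction: int = 1
    semantics: Semantics = Semantics.VALUE

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValidationError(f"direction must be +1 or -1, got {self.direction!r}")
        if len(self.ops) != math.factorial(self.n):
            raise ValidationError(
                f"ops length {len(self.ops)} != n! = {math.factorial(self.n)} for n={self.n}"
            )
        object.__setattr__(self, "semantics", Semantics(self.semantics))

    @property
    def n(self) -> int:
        return self.start.n

    def walk(self) -> Iterator[Permutation]:
        """Yield the n! + 1 permutations along the loop, start repeated at the end.

        Out-of-range operator indices are yielded through verification, so
        this walker validates each op before applying it.
        """
        cur = self.start
        yield cur
        for op in self.ops:
            cur = apply_negation(cur, op, self.semantics)
            yield cur

    def visit_ranks(self) -> list[int]:
        """Lexicographic ranks of the n! visited permutations (closing repeat dropped)."""
        ranks = [lex_rank(p) for p in self.walk()]
        return ranks[:-1]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "start": format_permutation(self.start),
            "ops": list(self.ops),
            "direction": self.direction,
            "semantics": self.semantics.value,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HamiltonLoop":
        from retiform.permutation_core import parse_permutation

        start = parse_permutation(str(data["start"]))
        if "n" in data and int(data["n"]) != start.n:
            raise ValidationError(
                f"declared n={data['n']} disagrees with start permutation {data['start']!r}"
            )
        return cls(
            start=start,
            ops=tuple(int(o) for o in data["ops"]),
            direction=int(data.get("direction", 1)),
            semantics=Semantics(data.get("semantics", "value")),
        )


@dataclass(frozen=True)
class LoopVerdict:
    """Outcome of loop verification; invalid verdicts carry the first violation."""

    valid: bool
    step: int | None = None
    kind: Literal["revisit", "not-closed", "bad-operator"] | None = None

    def __bool__(self) -> bool:
        return self.valid


def verify_loop(loop: HamiltonLoop) -> LoopVerdict:
    """Check that the loop visits all n! permutations once and closes.

    Returns a verdict rather than raising: the first violation is reported
    with its 1-based step index and kind.
    """
    size = math.factorial(loop.n)
    seen = {loop.start.values}
    cur = loop.start
    for step, op in enumerate(loop.ops, start=1):
        if not (1 <= op <= loop.n - 1):
            return LoopVerdict(False, step, "bad-operator")
        cur = apply_negation(cur, op, loop.semantics)
        if step < size:
            if cur.values in seen:
                return LoopVerdict(False, step, "revisit")
            seen.add(cur.values)
        else:
            if cur != loop.start:
                return LoopVerdict(False, step, "not-closed")
    return LoopVerdict(True)


def _plain_changes(n: int) -> list[int]:
    """Steinhaus-Johnson-Trotter swap positions generating all n! permutations.

    Returns the n! - 1 adjacent *position* indices (1-based) whose successive
    swaps run through every permutation; the final arrangement differs from
    the start by one further swap at position 1, closing the loop.
    """
    perm = list(range(1, n + 1))
    # direction: -1 looking left, +1 looking right
    direction = {v: -1 for v in perm}
    swaps: list[int] = []
    for _ in range(math.factorial(n) - 1):
        mobile, mobile_pos = 0, -1
        for pos, v in enumerate(perm):
            tgt = pos + direction[v]
            if 0 <= tgt < n and perm[tgt] < v and v > mobile:
                mobile, mobile_pos = v, pos
        tgt = mobile_pos + direction[mobile]
        swaps.append(min(mobile_pos, tgt) + 1)
        perm[mobile_pos], perm[tgt] = perm[tgt], perm[mobile_pos]
        for v in perm:
            if v > mobile:
                direction[v] = -direction[v]
    return swaps


def construct_loop(n: int, semantics: Semantics = Semantics.VALUE) -> HamiltonLoop:
    """Deterministically construct one valid Hamilton loop for 2 <= n <= 7.

    Uses the plain-change order; its position-swap sequence transfers to
    value-swap semantics unchanged through the inverse-permutation
    isomorphism, so the same operator indices work for either semantics.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 2 or n > 7:
        raise BoundError(f"loop construction supported for 2 <= n <= 7, got {n!r}")
    ops = tuple(_plain_changes(n)) + (1,)
    return HamiltonLoop(
        start=lex_unrank(1, n), ops=ops, direction=1, semantics=Semantics(semantics)
    )


def reverse_loop(loop: HamiltonLoop) -> HamiltonLoop:
    """The same vertex cycle traversed in the opposite direction."""
    if not verify_loop(loop):
        raise ValidationError("cannot reverse an invalid loop")
    return replace(loop, ops=loop.ops[::-1], direction=-loop.direction)


def _rotate_to_rank_one(loop: HamiltonLoop) -> tuple[int, ...]:
    """Ops rotated so the traversal starts at the rank-1 permutation."""
    ranks = loop.visit_ranks()
    shift = ranks.index(1)
    return loop.ops[shift:] + loop.ops[:shift]


def canonicalize_loop(loop: HamiltonLoop, counting: Counting = "undirected") -> tuple:
    """Canonical key identifying the loop up to rotation (and, if undirected, reversal).

    The key is ``(n, ops)`` with the traversal rotated to begin at the
    rank-1 permutation; undirected counting additionally takes the
    lexicographically smaller of the two directions' op sequences.
    """
    if counting not in ("directed", "undirected"):
        raise ValidationError(f"unknown counting convention {counting!r}")
    verdict = verify_loop(loop)
    if not verdict:
        raise ValidationError(
            f"cannot canonicalize invalid loop ({verdict.kind} at step {verdict.step})"
        )
    forward = _rotate_to_rank_one(loop)
    if counting == "directed":
        return (loop.n, forward)
    backward = _rotate_to_rank_one(replace(loop, ops=loop.ops[::-1]))
    return (loop.n, min(forward, backward))


@dataclass
class LoopEnumeration:
    """Exhaustive enumeration result: canonical loops and their keys."""

    n: int
    counting: Counting
    loops: list[HamiltonLoop] = field(repr=False)
    keys: set[tuple] = field(repr=False)

    @property
    def count(self) -> int:
        return len(self.loops)


def enumerate_loops(
    n: int,
    counting: Counting = "undirected",
    semantics: Semantics = Semantics.VALUE,
) -> LoopEnumeration:
    """Exhaustively enumerate Hamilton loops of the n-valued permutograph.

    Refused for n >= 5: the pentavalent and higher systems are treated as
    not exhaustively computable.  Backtracking is anchored at the rank-1
    vertex (killing rotations); reversals are killed by requiring the
    second visited rank to be smaller than the last, then restored when
    directed counting is requested.
    """
    if counting not in ("directed", "undirected"):
        raise ValidationError(f"unknown counting convention {counting!r}")
    if not isinstance(n, int) or isinstance(n, bool) or n < 2:
        raise BoundError(f"enumeration requires an integer n >= 2, got {n!r}")
    if n >= 5:
        raise RefusalError(
            f"exhaustive Hamilton-loop enumeration is refused for n={n}: "
            "systems with n >= 5 are treated as not exhaustively computable"
        )
    semantics = Semantics(semantics)
    size = math.factorial(n)
    perms = [lex_unrank(r, n) for r in range(1, size + 1)]
    # adjacency as rank -> {neighbor rank: operator}
    adj: list[dict[int, int]] = [dict() for _ in range(size + 1)]
    for rank, p in enumerate(perms, start=1):
        for i in range(1, n):
            adj[rank][lex_rank(apply_negation(p, i, semantics))] = i

    undirected_paths: list[list[int]] = []
    path = [1]
    used = [False] * (size + 1)
    used[1] = True

    def backtrack() -> None:
        last = path[-1]
        if len(path) == size:
            if 1 in adj[last] and path[1] < path[-1]:
                undirected_paths.append(path.copy())
            return
        for nb in adj[last]:
            if not used[nb]:
                used[nb] = True
                path.append(nb)
                backtrack()
                path.pop()
                used[nb] = False

    backtrack()

    def path_to_loop(ranks: list[int]) -> HamiltonLoop:
        cycle = ranks + [ranks[0]]
        ops = tuple(adj[cycle[k]][cycle[k + 1]] for k in range(size))
        return HamiltonLoop(start=perms[0], ops=ops, direction=1, semantics=semantics)

    loops = [path_to_loop(p) for p in undirected_paths]
    if counting == "directed":
        loops = loops + [reverse_loop(lp) for lp in loops]
    keys = {canonicalize_loop(lp, counting) for lp in loops}
    assert len(keys) == len(loops), "canonical keys must be distinct per enumerated loop"
    return LoopEnumeration(n=n, counting=counting, loops=loops, keys=keys)


@dataclass
class GuentherMatrix:
    """Visit-order table: one row per start choice along a single Hamilton loop.

    ``rows[r-1][c-1]`` is the 1-based visit order of the permutation of
    lexicographic rank ``c`` when the cycle is entered at start choice
    ``r`` (start choices displace stepwise along the original traversal).
    Every row is a permutation of ``1..n!`` and the rows are cyclic
    relabelings of one another.
    """

    n: int
    rows: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return math.factorial(self.n)

    def to_frame(self) -> pd.DataFrame:
        size = self.size
        return pd.DataFrame(
            self.rows,
            index=pd.Index(range(1, size + 1), name="start_choice"),
            columns=pd.Index(range(1, size + 1), name="permutation_rank"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def guenther_matrix(loop: HamiltonLoop) -> GuentherMatrix:
    """Tabulate visit orders for every choice of starting permutation.

    Row ``r`` re-enters the same cycle at the ``r``-th vertex of the
    original traversal, so its visit orders are the first row's shifted by
    ``-(r-1)`` modulo n! and mapped back to ``1..n!``.
    """
    verdict = verify_loop(loop)
    if not verdict:
        raise ValidationError(
            f"cannot tabulate an invalid loop ({verdict.kind} at step {verdict.step})"
        )
    size = math.factorial(loop.n)
    ranks = loop.visit_ranks()
    rows = np.empty((size, size), dtype=np.int64)
    for r in range(size):
        for order_along_loop, vertex in enumerate(ranks):
            rows[r, vertex - 1] = (order_along_loop - r) % size + 1
    return GuentherMatrix(n=loop.n, rows=rows)
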
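"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles on raw tuples — no
imports from the package under test — so the two routes stay independent.
"""

from itertools import permutations as _itertools_permutations


def naive_value_swap(values, i):
    """Exchange the numerals i and i+1 wherever they stand."""
    return tuple(i + 1 if v == i else i if v == i + 1 else v for v in values)


def naive_position_swap(values, i):
    """Exchange the entries at 1-based positions i and i+1."""
    out = list(values)
    out[i - 1], out[i] = out[i], out[i - 1]
    return tuple(out)


def naive_rank(values):
    """1-based lexicographic rank by sorting every arrangement."""
    ordered = sorted(_itertools_permutations(sorted(values)))
    return ordered.index(tuple(values)) + 1


def naive_all(n):
    return sorted(_itertools_permutations(range(1, n + 1)))


def naive_walk(start, ops, swap=naive_value_swap):
    """All visited arrangements including the closing repeat."""
    cur = tuple(start)
    out = [cur]
    for i in ops:
        cur = swap(cur, i)
        out.append(cur)
    return out


def naive_is_hamilton_loop(start, ops, n, swap=naive_value_swap):
    visited = naive_walk(start, ops, swap)
    body = visited[:-1]
    size = len(naive_all(n))
    return (
        len(ops) == size
        and visited[-1] == visited[0]
        and len(set(body)) == size
    )


def naive_adjacency(n, swap=naive_value_swap):
    """Vertex-sequence adjacency sets over raw tuples."""
    verts = naive_all(n)
    return {v: {swap(v, i) for i in range(1, n)} for v in verts}


def naive_hamiltonian_cycles(n, swap=naive_value_swap):
    """All undirected Hamiltonian cycles as frozensets of edges.

    Depth-first over raw vertex sequences anchored at the identity; each
    cycle is recorded as its undirected edge set, which is invariant to
    rotation and reversal, so the returned set size is the undirected count.
    """
    adj = naive_adjacency(n, swap)
    verts = naive_all(n)
    start = verts[0]
    cycles = set()

    def extend(path, used):
        last = path[-1]
        if len(path) == len(verts):
            if start in adj[last]:
                edges = frozenset(
                    frozenset((path[k], path[(k + 1) % len(path)]))
                    for k in range(len(path))
                )
                cycles.add(edges)
            return
        for nxt in adj[last]:
            if nxt not in used:
                used.add(nxt)
                path.append(nxt)
                extend(path, used)
                path.pop()
                used.remove(nxt)

    extend([start], {start})
    return cycles
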
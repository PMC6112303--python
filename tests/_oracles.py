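"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, direct
definitions) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np


def interval_union_membership(intervals, point) -> bool:
    """Is ``point`` covered by any half-open interval?"""
    return any(s <= point < e for s, e in intervals)


def bfs_distances(adj: dict, sources) -> dict:
    """Unweighted shortest distances from a source set, plain BFS."""
    dist = {s: 0 for s in sources if s in adj}
    frontier = list(dist)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s->t path, by BFS-layered DFS."""
    dist = bfs_distances(adj, [s])
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for v in adj.get(node, ()):
            if dist.get(v) == dist[node] + 1 and dist.get(v, np.inf) <= dist[t]:
                walk(v, path + [v])

    walk(s, [s])
    return paths


def betweenness_oracle(adj: dict, nodes) -> dict:
    """Normalized directed betweenness by explicit path enumeration."""
    nodes = list(nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            score[v] += on / len(paths)
    norm = (n - 1) * (n - 2) if n > 2 else 1
    return {v: score[v] / norm for v in nodes}


def closeness_out_oracle(adj: dict, nodes) -> dict:
    """Out-direction closeness over the reachable set only."""
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, [v])
        reach = [d for u, d in dist.items() if u != v]
        out[v] = (len(reach) / sum(reach)) if reach and sum(reach) > 0 else 0.0
    return out


def clustering_oracle(und_adj: dict, nodes) -> dict:
    """Local clustering coefficient by direct triangle counting."""
    out = {}
    for v in nodes:
        nbrs = list(und_adj.get(v, ()))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in und_adj.get(a, ())
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def enumerate_motifs_bruteforce(signed_edges: dict) -> list[tuple]:
    """All signed FFLs and 2/3-cycles by iterating every ordered tuple.

    ``signed_edges`` maps (u, v) -> iterable of signs. Returns tuples
    (motif_class, frozenset_of_nodes, sorted_sign_tuple) — a
    representation that is invariant to role/rotation conventions, so it
    can be compared against any enumerator as a multiset.
    """
    nodes = sorted({x for e in signed_edges for x in e})
    found = []

    def signs(u, v):
        return signed_edges.get((u, v), ())

    for a, b, c in itertools.permutations(nodes, 3):
        for s1 in signs(a, b):
            for s2 in signs(b, c):
                for s3 in signs(a, c):
                    path = "+" if s1 == s2 else "-"
                    cls = "CFF" if s3 == path else "IFF"
                    found.append((cls, frozenset((a, b, c)), tuple(sorted((s1, s2, s3))), ("ffl", a, b, c, s1, s2, s3)))
    for u, v in itertools.combinations(nodes, 2):
        for s1 in signs(u, v):
            for s2 in signs(v, u):
                cls = "PFB" if s1 == s2 else "NFB"
                found.append((cls, frozenset((u, v)), tuple(sorted((s1, s2))), ("fb2", u, v, s1, s2)))
    seen3 = set()
    for a, b, c in itertools.permutations(nodes, 3):
        if a != min(a, b, c):
            continue
        for s1 in signs(a, b):
            for s2 in signs(b, c):
                for s3 in signs(c, a):
                    neg = (s1, s2, s3).count("-")
                    cls = "PFB" if neg % 2 == 0 else "NFB"
                    key = ("fb3", a, b, c, s1, s2, s3)
                    if key in seen3:
                        continue
                    seen3.add(key)
                    found.append((cls, frozenset((a, b, c)), tuple(sorted((s1, s2, s3))), key))
    return [(cls, ns, sg) for cls, ns, sg, _ in found]


def spearman_oracle(x, y) -> float:
    """Spearman rho via explicit average ranks and Pearson on ranks."""
    def rank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = rank(x), rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
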
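"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (O(n^3) reachability closures,
exhaustive triple enumeration) and shares no code with the package.
"""

from fractions import Fraction


def bfs_lengths(adj: dict, source):
    """Shortest directed path lengths from source (dict node -> length)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def reachability(adj: dict, nodes):
    """dict node -> set of nodes reachable by a directed path (self excluded)."""
    out = {}
    for u in nodes:
        out[u] = set(bfs_lengths(adj, u)) - {u}
    return out


def brute_path_stats(adj: dict, nodes):
    """(L, P_C) over ordered pairs of distinct nodes; L is None if no pair reachable."""
    nodes = list(nodes)
    n = len(nodes)
    total, count = 0, 0
    for u in nodes:
        dist = bfs_lengths(adj, u)
        for v, d in dist.items():
            if v != u:
                total += d
                count += 1
    if n < 2 or count == 0:
        return None, 0.0
    return Fraction(total, count), Fraction(count, n * (n - 1))


def brute_bow_tie(adj: dict, nodes):
    """(LSC, IN, OUT) by mutual-reachability closure; ties toward the
    lexicographically smallest sorted member list."""
    nodes = list(nodes)
    if not nodes:
        return set(), set(), set()
    reach = reachability(adj, nodes)
    sccs = []
    seen = set()
    for u in nodes:
        if u in seen:
            continue
        comp = {u} | {v for v in reach[u] if u in reach[v]}
        sccs.append(comp)
        seen |= comp
    best = max(len(c) for c in sccs)
    lsc = set(min((sorted(c) for c in sccs if len(c) == best)))
    in_set = {u for u in nodes if u not in lsc and reach[u] & lsc}
    anchor = next(iter(lsc))
    out_set = (reach[anchor] | lsc) - lsc
    return lsc, in_set, out_set


def brute_clustering(adj: dict, nodes):
    """Transitivity 3*N_triangles/N_triples on the undirected simplification."""
    nodes = sorted(nodes)
    und = {u: set() for u in nodes}
    for u, vs in adj.items():
        for v in vs:
            if u != v:
                und[u].add(v)
                und[v].add(u)
    triples = sum(len(vs) * (len(vs) - 1) // 2 for vs in und.values())
    triangles = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if v not in und[u]:
                continue
            for w in nodes:
                if w > v and w in und[u] and w in und[v]:
                    triangles += 1
    if triples == 0:
        return Fraction(0)
    return Fraction(3 * triangles, triples)


def random_digraph(n, p, rng):
    """Erdos-Renyi directed graph as an adjacency dict over range(n)."""
    adj = {u: set() for u in range(n)}
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                adj[u].add(v)
    return adj


def approx_powerlaw_gamma(degrees, k_min):
    """Continuous-approximation MLE: 1 + n / sum(ln(k_i / (k_min - 1/2)))."""
    import math

    tail = [k for k in degrees if k >= k_min]
    return 1.0 + len(tail) / sum(math.log(k / (k_min - 0.5)) for k in tail)
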
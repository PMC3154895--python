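"""Independent brute-force oracles used to validate the package's graph and
statistics code.  Everything here is written from first principles (plain BFS,
exhaustive enumeration, closed forms) and deliberately avoids the code paths
under test."""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_to_adj(edges, nodes=None) -> dict:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for n in nodes or ():
        adj.setdefault(n, set())
    return adj


def brute_diameter(edges, nodes=None) -> float:
    """Average shortest-path length over connected node pairs, by plain BFS."""
    adj = graph_to_adj(edges, nodes)
    total = count = 0
    for u, v in combinations(sorted(adj), 2):
        dist = bfs_distances(adj, u)
        if v in dist:
            total += dist[v]
            count += 1
    if count == 0:
        raise ValueError("no connected pair")
    return total / count


def _all_shortest_paths(adj: dict, s, t, dist: dict):
    """Enumerate every shortest s-t path by depth-first walk along the BFS levels."""
    if t not in dist:
        return
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            yield path
            continue
        for v in adj[u]:
            if v in dist and dist[v] == dist[u] + 1 and dist.get(u, 0) == len(path) - 1:
                stack.append((v, path + [v]))


def brute_betweenness(edges, nodes=None) -> dict:
    """Unnormalized betweenness by explicit enumeration of all shortest paths."""
    adj = graph_to_adj(edges, nodes)
    score = {v: 0.0 for v in adj}
    for s, t in combinations(sorted(adj), 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = list(_all_shortest_paths(adj, s, t, dist))
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def brute_modularity(edges, partition: dict) -> float:
    """Newman Q evaluated directly from its definition."""
    edges = list(edges)
    m = len(edges)
    communities = set(partition.values())
    q = 0.0
    for c in communities:
        members = {v for v, lab in partition.items() if lab == c}
        l_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(1 for u, v in edges for w in (u, v) if w in members)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number many; keep len <= ~10)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def best_partition_q(edges, nodes) -> float:
    """Maximum modularity over all partitions, by exhaustive enumeration."""
    best = -math.inf
    for blocks in all_partitions(list(nodes)):
        partition = {v: i for i, block in enumerate(blocks) for v in block}
        best = max(best, brute_modularity(edges, partition))
    return best


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct summation of the pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    ) / total


def pooled_t(x, y) -> float:
    """Equal-variance two-sample t statistic by the textbook two-pass formula."""
    nx_, ny = len(x), len(y)
    mx = sum(x) / nx_
    my = sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx_ - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx_ - 1) * sx2 + (ny - 1) * sy2) / (nx_ + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx_ + 1 / ny))


def two_pass_pearson(x, y) -> float:
    """Sample Pearson correlation from the definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)
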
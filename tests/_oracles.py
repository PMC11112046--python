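"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (all-pairs BFS, path counting, power
iteration) that never share code with the package's own feature paths.
"""

from collections import deque

import numpy as np


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


def shortest_path_counts(adj: dict, source):
    """BFS distances and number of shortest paths from source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_centralities(nodes, edges):
    """Normalized degree, betweenness, closeness, eigenvector for every node."""
    nodes = list(nodes)
    n = len(nodes)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    dists = {u: bfs_distances(adj, u) for u in nodes}
    sigmas = {u: shortest_path_counts(adj, u)[1] for u in nodes}

    degree = {u: (len(adj[u]) / (n - 1) if n > 1 else 0.0) for u in nodes}

    closeness = {}
    for u in nodes:
        reach = {v: d for v, d in dists[u].items() if v != u}
        closeness[u] = (len(reach) / sum(reach.values())) if reach else 0.0

    betweenness = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dists[s]:
                continue
            d_st = dists[s][t]
            total = sigmas[s][t]
            for v in nodes:
                if v in (s, t) or v not in dists[s] or t not in dists[v]:
                    continue
                if dists[s][v] + dists[v][t] == d_st:
                    betweenness[v] += sigmas[s][v] * sigmas[v][t] / total
    norm = (n - 1) * (n - 2) / 2
    if norm > 0:
        betweenness = {u: b / norm for u, b in betweenness.items()}

    eigen = {u: 0.0 for u in nodes}
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        comp = sorted(bfs_distances(adj, start))
        seen.update(comp)
        if len(comp) == 1 or all(len(adj[u]) == 0 for u in comp):
            continue
        A = np.zeros((len(comp), len(comp)))
        pos = {u: i for i, u in enumerate(comp)}
        for u in comp:
            for v in adj[u]:
                A[pos[u], pos[v]] = 1.0
        # power iteration on A + I: same eigenvectors, but the Perron
        # eigenvalue is strictly dominant even for bipartite components
        A = A + np.eye(len(comp))
        vec = np.ones(len(comp))
        for _ in range(10000):
            nxt = A @ vec
            norm_v = np.linalg.norm(nxt)
            if norm_v == 0:
                break
            nxt /= norm_v
            if np.linalg.norm(nxt - vec) < 1e-14:
                vec = nxt
                break
            vec = nxt
        vec = np.abs(vec)
        vec /= np.linalg.norm(vec)
        for u in comp:
            eigen[u] = float(vec[pos[u]])

    return {u: {"degree": degree[u], "betweenness": betweenness[u],
                "closeness": closeness[u], "eigenvector": eigen[u]}
            for u in nodes}


def random_graph(rng: np.random.Generator, max_nodes: int = 12):
    n = int(rng.integers(2, max_nodes + 1))
    p = rng.uniform(0.15, 0.7)
    nodes = list(range(n))
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges


def sphere_cap_buried_area(r1: float, r2: float, d: float) -> float:
    """Area of the cap of sphere 1 (radius r1) buried inside sphere 2
    (radius r2) at centre distance d; closed-form spherical-cap geometry."""
    if d >= r1 + r2:
        return 0.0
    cos_theta = (d * d + r1 * r1 - r2 * r2) / (2 * d * r1)
    cos_theta = min(1.0, max(-1.0, cos_theta))
    return 2 * np.pi * r1 * r1 * (1 - cos_theta)
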
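"""Independent brute-force oracles for graph metrics.

Everything here is written directly from the definitions — hand-rolled BFS,
explicit enumeration of all shortest paths — and deliberately shares no code
path with the package implementation.
"""

from collections import deque


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def enumerate_shortest_paths(adj, dist_from_s, s, t):
    """All shortest s-t paths, by walking backwards along the BFS layering."""
    if t not in dist_from_s:
        return []
    paths = []

    def back(node, tail):
        if node == s:
            paths.append([s] + tail)
            return
        for w in adj[node]:
            if w in dist_from_s and dist_from_s[w] == dist_from_s[node] - 1:
                back(w, [node] + tail)

    back(t, [])
    return paths


def betweenness_brute(nodes, edges):
    """Unnormalized betweenness over unordered pairs with fractional credit,
    by literally enumerating every shortest path."""
    adj = adjacency(nodes, edges)
    nodes = list(nodes)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            paths = enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            credit = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    btw[v] += credit
    return btw


def clustering_brute(nodes, edges, gene):
    adj = adjacency(nodes, edges)
    nbrs = list(adj[gene])
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = 0
    for i in range(d):
        for j in range(i + 1, d):
            if nbrs[j] in adj[nbrs[i]]:
                links += 1
    return 2.0 * links / (d * (d - 1))


def mean_path_to_set_brute(nodes, edges, gene, targets, exclude_self=True):
    adj = adjacency(nodes, edges)
    dist = bfs_distances(adj, gene)
    tgt = set(targets)
    if exclude_self:
        tgt.discard(gene)
    hops = [dist[t] for t in tgt if t in dist]
    if not hops:
        return None
    return sum(hops) / len(hops)


def ranksum_exact_p(pos, neg):
    """Exact two-sided rank-sum p-value by full enumeration of group
    assignments (no ties assumed)."""
    from itertools import combinations

    combined = sorted(pos + neg)
    assert len(set(combined)) == len(combined), "exact oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    n1 = len(pos)
    w_obs = sum(ranks[v] for v in pos)
    all_ranks = list(ranks.values())
    mean_w = n1 * (len(combined) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for combo in combinations(all_ranks, n1):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total
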
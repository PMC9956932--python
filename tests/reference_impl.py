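"""Independent brute-force references used as oracles in the tests.

Deliberately written in the most literal style possible (explicit
neighbourhood enumeration, union-find over core pairs, pure Python loops)
so they share no code path with the package implementation.
"""

from __future__ import annotations


def brute_force_dbscan(D, r: float, nmin: int):
    """Literal DBSCAN reference on a dense distance matrix.

    Returns (labels, core_flags) as plain lists. Same variant contract as
    the package: closed ball, self-inclusive neighbourhoods, clusters =
    connected components of core points under mutual reachability, border
    points join the lowest-index reachable core, cluster ids 1..K ordered
    by each cluster's lowest member index, noise = -1.
    """
    n = len(D)
    neighbours = [
        {j for j in range(n) if D[i][j] <= r} for i in range(n)
    ]  # includes i itself since D[i][i] == 0
    core = [len(neighbours[i]) >= nmin for i in range(n)]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if core[i] and core[j] and D[i][j] <= r:
                union(i, j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        if core[i]:
            members.setdefault(find(i), []).append(i)

    for i in range(n):
        if core[i]:
            continue
        reachable_cores = [j for j in range(n) if core[j] and D[i][j] <= r]
        if reachable_cores:
            members[find(min(reachable_cores))].append(i)

    labels = [-1] * n
    for k, cluster in enumerate(sorted(members.values(), key=min), start=1):
        for i in cluster:
            labels[i] = k
    return labels, core
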
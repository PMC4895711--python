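"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms (and numpy where the package
uses scalar arithmetic) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np


def sd_oracle(positions) -> float:
    positions = np.asarray(list(positions), dtype=float)
    return 0.0 if positions.size == 1 else float(np.std(positions, ddof=1))


def partition_oracle(positions, gap: int = 100) -> list[list[int]]:
    """Transitive closure of the pairwise |a - b| <= gap relation."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def greedy_subcluster_oracle(positions, sd_threshold: float = 10.0) -> list[list[int]]:
    """Recursive maximal-prefix partition: the first block is the longest
    prefix whose positional sd stays below the threshold, then recurse."""
    positions = sorted(positions)
    if not positions:
        return []
    k = 1
    while k < len(positions) and sd_oracle(positions[: k + 1]) < sd_threshold:
        k += 1
    return [positions[:k]] + greedy_subcluster_oracle(positions[k:], sd_threshold)


def classify_oracle(candidates, genes, upstream: int = 500, downstream: int = 150) -> dict:
    """Label every candidate by testing each (TSS, gene) pair directly.

    Returns {candidate index: (label, gene_id or None)}.
    """
    in_window = {}
    for ci, cand in enumerate(candidates):
        for g in genes:
            if g.strand != cand.strand:
                continue
            sc = g.start if g.strand == "+" else g.end
            lo = sc - upstream if g.strand == "+" else sc - downstream
            hi = sc + downstream if g.strand == "+" else sc + upstream
            if lo <= cand.position <= hi:
                in_window.setdefault(ci, []).append(g)
    assignment = {}
    for ci, gs in in_window.items():
        sc_of = lambda g: g.start if g.strand == "+" else g.end
        assignment[ci] = min(gs, key=lambda g: (abs(candidates[ci].position - sc_of(g)), g.gene_id))
    result = {}
    by_gene: dict[str, list[int]] = {}
    for ci, g in assignment.items():
        by_gene.setdefault(g.gene_id, []).append(ci)
    for gid, cis in by_gene.items():
        g = next(x for x in genes if x.gene_id == gid)
        sc = g.start if g.strand == "+" else g.end

        def key(ci):
            c = candidates[ci]
            return (-c.height, abs(c.position - sc), c.position if c.strand == "+" else -c.position)

        best = min(cis, key=key)
        for ci in cis:
            result[ci] = ("P" if ci == best else "S", gid)
    for ci, cand in enumerate(candidates):
        if ci in result:
            continue
        same = any(g.strand == cand.strand and g.start <= cand.position <= g.end for g in genes)
        anti = any(g.strand != cand.strand and g.start <= cand.position <= g.end for g in genes)
        result[ci] = ("I" if same else "A" if anti else "N", None)
    return result


_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "N": {"A", "C", "G", "T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "W": {"A", "T"}, "S": {"C", "G"},
}


def scan_oracle(window: str, pattern: str) -> list[int]:
    """0-based start indices of all IUPAC matches of pattern in window."""
    hits = []
    for i in range(len(window) - len(pattern) + 1):
        if all(window[i + j] in _IUPAC_SETS[p] for j, p in enumerate(pattern)):
            hits.append(i)
    return hits


def hclust_oracle(rows: np.ndarray, metric: str = "cityblock", linkage: str = "complete"):
    """Naive O(n^3) agglomeration; returns the list of partitions (as sets of
    frozensets of row indices) after each merge, plus the merge heights.

    Distance ties are broken towards the smallest involved row index.
    """
    n = rows.shape[0]
    if metric == "cityblock":
        point_d = lambda a, b: float(np.abs(rows[a] - rows[b]).sum())
    elif metric == "correlation":
        def point_d(a, b):
            x, y = rows[a] - rows[a].mean(), rows[b] - rows[b].mean()
            return float(1 - (x @ y) / np.sqrt((x @ x) * (y @ y)))
    else:
        raise ValueError(metric)
    clusters = [frozenset([i]) for i in range(n)]
    partitions = [set(clusters)]
    heights = []

    def cluster_d(c1, c2):
        ds = [point_d(a, b) for a in c1 for b in c2]
        return max(ds) if linkage == "complete" else min(ds)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_d(clusters[i], clusters[j])
                key = (d, min(clusters[i] | clusters[j]), min(clusters[j] | clusters[i]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, *_), i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(set(clusters))
        heights.append(d)
    return partitions, heights
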
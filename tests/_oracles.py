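"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule from its plain-language definition
with naive enumeration, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_outlier_mask(fd, dvars, fd_thresh=0.2, dvars_thresh=75.0,
                       pad_before=1, pad_after=2, min_segment=5):
    """Literal interpretation of the censoring rule, frame by frame."""
    n = len(fd)
    hits = [fd[i] > fd_thresh or dvars[i] > dvars_thresh for i in range(n)]
    mask = [False] * n
    for i in range(n):
        if hits[i]:
            for j in range(i - pad_before, i + pad_after + 1):
                if 0 <= j < n:
                    mask[j] = True
    # enumerate maximal surviving segments
    segments = []
    start = None
    for i in range(n + 1):
        free = i < n and not mask[i]
        if free and start is None:
            start = i
        if not free and start is not None:
            segments.append((start, i))
            start = None
    for a, b in segments:
        if b - a < min_segment:
            for j in range(a, b):
                mask[j] = True
    return np.array(mask)


def brute_bh(pvals, q=0.05):
    """Step-up BH by direct definition: reject H_(1..k) for the largest k
    with p_(k) <= k q / m."""
    p = list(pvals)
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(indexed, start=1):
        if p[i] <= rank * q / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(indexed, start=1):
        if rank <= k_star:
            reject[i] = True
    return np.array(reject)


def brute_components(edge_list, n_nodes):
    """Connected components of an undirected graph by repeated DFS.

    Returns a list of frozensets of edge tuples, one per component that
    contains at least one edge.
    """
    adj = {i: set() for i in range(n_nodes)}
    for a, b in edge_list:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for start in range(n_nodes):
        if start in seen or not adj[start]:
            continue
        stack, nodes = [start], set()
        while stack:
            u = stack.pop()
            if u in nodes:
                continue
            nodes.add(u)
            stack.extend(adj[u] - nodes)
        seen |= nodes
        comp_edges = frozenset((min(a, b), max(a, b)) for a, b in edge_list
                               if a in nodes and b in nodes)
        comps.append(comp_edges)
    return comps


def enumerate_family_permutations(families):
    """All distinct permutations that respect family exchangeability blocks
    (within-block reorderings composed with swaps of equal-size blocks)."""
    from itertools import permutations as iperm

    fams = list(families)
    blocks = {}
    for i, f in enumerate(fams):
        blocks.setdefault(f, []).append(i)
    block_list = list(blocks.values())
    by_size = {}
    for bi, b in enumerate(block_list):
        by_size.setdefault(len(b), []).append(bi)

    results = set()

    def rec(size_classes, perm):
        if not size_classes:
            results.add(tuple(perm))
            return
        size, ids = size_classes[0]
        for assignment in iperm(ids):
            for member_orders in _product_perms([block_list[s] for s in assignment]):
                p = list(perm)
                for tgt_id, members in zip(ids, member_orders):
                    for pos, src in zip(block_list[tgt_id], members):
                        p[pos] = src
                rec(size_classes[1:], p)

    def _product_perms(blocks_members):
        if not blocks_members:
            yield []
            return
        for head in iperm(blocks_members[0]):
            for tail in _product_perms(blocks_members[1:]):
                yield [list(head)] + tail

    rec(sorted(by_size.items()), [None] * len(fams))
    return results
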
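"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the data structures and algorithms of the package:
components come from naive flood fills or repeated set expansion, medians
and quantiles from hand-rolled order-statistic interpolation, and path
composition from exhaustive enumeration.
"""

from __future__ import annotations

import math


def flood_fill_components(nodes, edges):
    """Connected components by naive flood fill.

    ``edges`` is an iterable of 2-item pairs over ``nodes``.
    Returns a set of frozensets.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    unseen = set(nodes)
    comps = set()
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        unseen -= comp
        comps.add(frozenset(comp))
    return comps


def shared_eco_partition(links):
    """Partition of medical ids by transitive 'share >= 1 eco id'."""
    medicals = {m for _, m in links}
    edges = []
    by_eco = {}
    for e, m in links:
        by_eco.setdefault(e, set()).add(m)
    for meds in by_eco.values():
        meds = sorted(meds)
        for i in range(len(meds)):
            for j in range(i + 1, len(meds)):
                edges.append((meds[i], meds[j]))
    return flood_fill_components(medicals, edges)


def path_composition(chains):
    """All (first-level, last-level) pairs connected through every matrix,
    by exhaustive path enumeration.  ``chains`` is a list of link sets."""
    paths = [(s, t) for s, t in chains[0]]
    for links in chains[1:]:
        paths = [
            p + (t,) for p in paths for s, t in links if s == p[-1]
        ]
    return {(p[0], p[-1]) for p in paths}


def grid_part_count(cells):
    """Number of edge-connected components of a set of (row, col) cells."""
    comps = flood_fill_components(
        cells,
        [
            (c, (c[0] + dr, c[1] + dc))
            for c in cells
            for dr, dc in ((0, 1), (1, 0))
            if (c[0] + dr, c[1] + dc) in cells
        ],
    )
    return len(comps)


def quantile_type7(values, q):
    """Quantile by linear interpolation between order statistics (R type 7)."""
    xs = sorted(values)
    if not xs:
        raise ValueError("no values")
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def median(values):
    return quantile_type7(values, 0.5)


def point_in_polygon(point, ring):
    """Even-odd ray casting for a single closed ring (list of (x, y))."""
    x, y = point
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
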
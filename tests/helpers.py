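"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the NNLS oracle is a
literal 2-D grid search, the event oracle enumerates every node pair and
every bundle bipartition exhaustively, the region oracles test membership
base by base, and the matching oracle evaluates the containment/overlap
predicate verbatim per pair.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_search_uv(S1, S2, SR, lam, lo=0.0, hi=5.0, step=1e-3, chunk=512):
    """Minimize the penalized least-squares objective on a (u, v) grid.

    The objective Σ(u·S1 + v·S2 − SR)² + λ²[(u−v)² + (u−1)² + (v−1)²] is
    evaluated literally at every grid point (expanded to its quadratic
    coefficients once for speed; the search itself is exhaustive).
    """
    S1, S2, SR = (np.asarray(a, dtype=float) for a in (S1, S2, SR))
    a_uu = np.sum(S1 * S1) + 2 * lam * lam
    a_vv = np.sum(S2 * S2) + 2 * lam * lam
    a_uv = 2 * np.sum(S1 * S2) - 2 * lam * lam
    b_u = -2 * np.sum(S1 * SR) - 2 * lam * lam
    b_v = -2 * np.sum(S2 * SR) - 2 * lam * lam
    vals = np.arange(lo, hi + step / 2, step)
    g = a_vv * vals * vals + b_v * vals
    best = (np.inf, 0.0, 0.0)
    for i0 in range(0, len(vals), chunk):
        u = vals[i0:i0 + chunk]
        sse = (a_uu * u * u + b_u * u)[:, None] + g[None, :] + a_uv * np.outer(u, vals)
        k = int(np.argmin(sse))
        r, c = divmod(k, len(vals))
        if sse[r, c] < best[0]:
            best = (float(sse[r, c]), float(u[r]), float(vals[c]))
    return best[1], best[2]


def brute_force_events(graph):
    """Exhaustive event enumeration on an annotation-mode splicing graph.

    For every node pair and every bipartition of the bundles of traversing
    isoforms, checks mutual edge-exclusivity and minimality directly, then
    applies the documented collapse rule for >2 bundles. Returns the set of
    unordered (path-edge-set, path-edge-set) pairs, artificial edges
    stripped.
    """
    units = dict(graph.isoform_edges)
    node_seq = {
        u: [edges[0].from_node] + [e.to_node for e in edges]
        for u, edges in units.items()
    }
    pairs = set()
    for seq in node_seq.values():
        for i, s in enumerate(seq):
            for t in seq[i + 1:]:
                pairs.add((s, t))
    found = set()
    for s, t in pairs:
        traversing = [
            u for u, seq in node_seq.items()
            if s in seq and t in seq and seq.index(s) < seq.index(t)
        ]
        if len(traversing) < 2:
            continue
        sub = {
            u: tuple(units[u][node_seq[u].index(s):node_seq[u].index(t)])
            for u in traversing
        }
        internal = [set(e.to_node for e in sp[:-1]) for sp in set(sub.values())]
        if set.intersection(*internal):
            continue
        bundles = {}
        for u, sp in sub.items():
            bundles.setdefault(sp, []).append(u)

        def path_rank(sp):
            # rank mirrors the documented rule: transcriptomic length desc,
            # then genomic order of the footprint (junction anchors included)
            exonic = [(e.span.start, e.span.end) for e in sp if e.kind == "exonic"]
            anchors = []
            for e in sp:
                if e.kind == "junction" and e.span is not None:
                    anchors += [(e.span.start - 1, e.span.start),
                                (e.span.end, e.span.end + 1)]
            ivs = sorted(exonic + anchors)
            merged = []
            for a, b in ivs:
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            length = sum(b - a for a, b in exonic)
            left = merged[0][0] if merged else 0
            return (-length, left, tuple(map(tuple, merged)), repr(sp))

        blist = sorted(bundles, key=lambda sp: (-len(bundles[sp]), path_rank(sp)))
        k = len(blist)
        if k < 2:
            continue

        def strip(edges):
            return frozenset(e for e in edges if e.kind != "artificial")

        def disjoint_bipartition(side1, side2):
            e1 = strip(e for sp in side1 for e in sp)
            e2 = strip(e for sp in side2 for e in sp)
            ok = bool(e1) and bool(e2) and not (e1 & e2)
            return ok, e1, e2

        valid = {}
        for mask in range(1, 2 ** k - 1):
            side1 = [blist[i] for i in range(k) if (mask >> i) & 1]
            side2 = [blist[i] for i in range(k) if not (mask >> i) & 1]
            ok, e1, e2 = disjoint_bipartition(side1, side2)
            if ok:
                valid[frozenset(frozenset(map(repr, s)) for s in (side1, side2))] = (
                    e1, e2
                )
        if k == 2:
            for e1, e2 in valid.values():
                found.add(frozenset((e1, e2)))
        else:
            # >2 bundles collapse to one-vs-rest; candidates in rank order,
            # first valid split wins
            for cand in blist:
                key = frozenset((
                    frozenset(map(repr, [cand])),
                    frozenset(map(repr, [sp for sp in blist if sp is not cand])),
                ))
                if key in valid:
                    e1, e2 = valid[key]
                    found.add(frozenset((e1, e2)))
                    break
    return found


def bases(intervals):
    """Expand an interval set into its set of covered base positions."""
    out = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            out.add((iv.chrom, p))
    return out


def subset_by_bases(x, y):
    return bases(x) <= bases(y)


def overlap_by_bases(x, y):
    return bool(bases(x) & bases(y))


def literal_match(f1, f2):
    """Verbatim evaluation of the two matching expressions for one pair."""

    def compat(a, b):
        return subset_by_bases(a, b) or subset_by_bases(b, a)

    ref_overlap = overlap_by_bases(f1.R, f2.R)
    eq_direct = compat(f1.A, f2.A) and compat(f1.B, f2.B) and ref_overlap
    eq_swapped = compat(f1.A, f2.B) and compat(f1.B, f2.A) and ref_overlap
    return eq_direct, eq_swapped
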
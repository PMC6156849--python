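"""Enumeration and classification of binary alternative-splicing events.

An event is a minimal "bubble" in the splicing graph: a divergence node s and
its earliest reconvergence node t, with two edge-disjoint alternative paths
(Path 1 / Path 2) between them and a shared reference path (the nearest
exonic edges flanking the bubble that all traversing isoforms share). Paths 1
and 2 are mutually exclusive in terms of isoforms: an isoform using Path 1
never uses Path 2 and vice versa.

Events are classified structurally as cassette exon, alternative 5'/3'
splice site, mutually exclusive exons, alternative first/last exon, intron
retention, or complex when no canonical pattern fits (including divergences
with more than two path bundles, which are collapsed to a single binary
event with the largest bundle against the union of the rest).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .graph import BoundaryNode, Edge, SplicingGraph
from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

EVENT_TYPES = (
    "cassette",
    "alt5",
    "alt3",
    "mutually_exclusive",
    "alt_first",
    "alt_last",
    "intron_retention",
    "complex",
)

# safety valve for path enumeration on data-driven graphs
MAX_GRAPH_PATHS = 5000


@dataclass(frozen=True)
class Path:
    """An ordered set of edges playing one role within an event."""

    edges: tuple  # tuple[Edge]; chain order for P1/P2, sorted for Ref
    role: str  # {"P1", "P2", "Ref"}

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    @property
    def material_edges(self) -> tuple:
        return tuple(e for e in self.edges if e.is_material)

    @property
    def kind_signature(self) -> tuple:
        return tuple(e.kind for e in self.material_edges)

    @property
    def transcriptomic_length(self) -> int:
        """Length of the path's sequence in the transcriptome (exonic bases)."""
        return sum(e.span.length for e in self.edges if e.kind == "exonic")

    @property
    def footprint(self) -> tuple:
        """Merged genomic intervals of the path.

        Exonic edges contribute their span; each splice junction contributes
        two 1-bp anchors at its donor and acceptor ends so that junction-only
        paths still occupy genomic positions for matching.
        """
        ivs: list[GenomicInterval] = []
        for e in self.edges:
            if e.kind == "exonic":
                ivs.append(e.span)
            elif e.kind == "junction" and e.span is not None:
                s = e.span
                if s.start > 0:
                    ivs.append(GenomicInterval(s.chrom, s.start - 1, s.start, s.strand))
                ivs.append(GenomicInterval(s.chrom, s.end, s.end + 1, s.strand))
        return tuple(merge_intervals(ivs))


@dataclass
class Event:
    event_id: str
    gene_id: str
    chrom: str
    strand: str
    type: str
    path1: Path
    path2: Path
    path_ref: Path
    isoforms1: frozenset = frozenset()
    isoforms2: frozenset = frozenset()
    s_node: Optional[BoundaryNode] = None
    t_node: Optional[BoundaryNode] = None
    n_bundles: int = 2


def _graph_paths(graph: SplicingGraph) -> dict:
    """Source→sink edge paths of a data-driven graph (pseudo-isoforms)."""
    out: dict[BoundaryNode, list[Edge]] = {}
    for e in graph.edges:
        out.setdefault(e.from_node, []).append(e)
    for node in out:
        out[node].sort(key=lambda e: (e.to_node, e.kind))
    paths: dict[str, tuple] = {}
    stack: list[tuple[BoundaryNode, tuple]] = [(graph.source, ())]
    while stack:
        node, chain = stack.pop()
        if node == graph.sink:
            paths[f"path{len(paths):04d}"] = chain
            if len(paths) > MAX_GRAPH_PATHS:
                logger.warning(
                    "gene %s: more than %d graph paths; enumeration truncated",
                    graph.gene_id, MAX_GRAPH_PATHS,
                )
                break
            continue
        for e in out.get(node, ()):
            stack.append((e.to_node, chain + (e,)))
    return paths


def _traversal_units(graph: SplicingGraph) -> dict:
    if graph.isoform_edges:
        return dict(graph.isoform_edges)
    return _graph_paths(graph)


def _strip_artificial(edges: Sequence[Edge]) -> tuple:
    return tuple(e for e in edges if e.kind != "artificial")


def _nearest_shared_exonic(
    chains: list, reverse: bool
) -> Optional[Edge]:
    """Nearest exonic edge present in every chain.

    ``chains`` hold the edges upstream of s (searched in reverse, i.e. from s
    outward) or downstream of t (searched forward).
    """
    if not chains:
        return None
    ref_chain = chains[0][::-1] if reverse else chains[0]
    others = [set(c) for c in chains[1:]]
    for e in ref_chain:
        if e.kind == "exonic" and all(e in o for o in others):
            return e
    return None


def _path_sort_key(path: Path):
    fp = path.footprint
    leftmost = fp[0].start if fp else 0
    return (-path.transcriptomic_length, leftmost, tuple((iv.start, iv.end) for iv in fp))


def enumerate_events(graph: SplicingGraph) -> list[Event]:
    """Enumerate minimal binary splicing events of one gene.

    In annotation mode the traversing units are the gene's isoforms; on a
    data-driven graph every source→sink edge path acts as a pseudo-isoform.
    For every node pair (s, t) the units passing through s then t are grouped
    by their s→t subpath; two edge-disjoint groups with no internal node
    shared by all subpaths form an event. More than two groups collapse into
    one complex event (largest bundle vs. the union of the rest) provided the
    two sides stay edge-disjoint.
    """
    units = _traversal_units(graph)
    if len(units) < 2:
        return []
    node_seqs = {
        uid: [edges[0].from_node] + [e.to_node for e in edges]
        for uid, edges in units.items()
        if edges
    }
    node_index = {
        uid: {n: i for i, n in enumerate(seq)} for uid, seq in node_seqs.items()
    }
    topo = {n: i for i, n in enumerate(graph.topological_nodes())}

    candidate_pairs: set[tuple] = set()
    for uid, seq in node_seqs.items():
        for i, s in enumerate(seq):
            for t in seq[i + 1:]:
                candidate_pairs.add((s, t))

    events: list[Event] = []
    seen_pairs: set = set()
    ordered = sorted(candidate_pairs, key=lambda st: (topo[st[0]], topo[st[1]]))
    for s, t in ordered:
        bundles: dict[tuple, list] = {}
        for uid, idx in node_index.items():
            if s in idx and t in idx and idx[s] < idx[t]:
                sub = tuple(units[uid][idx[s]:idx[t]])
                bundles.setdefault(sub, []).append(uid)
        if len(bundles) < 2:
            continue
        # minimality: no internal node shared by every subpath
        internal_sets = [
            {e.to_node for e in sub[:-1]} for sub in bundles
        ]
        common = set.intersection(*internal_sets) if internal_sets else set()
        if common:
            continue

        subpaths = sorted(
            bundles,
            key=lambda sub: (
                -len(bundles[sub]),
                _path_sort_key(Path(_strip_artificial(sub), "P1")),
            ),
        )
        if len(bundles) == 2:
            side1, side2 = subpaths
            splits = [(side1, side2, frozenset(bundles[side1]), frozenset(bundles[side2]))]
        else:
            # >2 bundles collapse to one binary event: candidates for Path 1
            # are tried in (bundle size, path length) order and the first
            # edge-disjoint split against the union of the rest is kept
            splits = []
            for cand in subpaths:
                rest_subs = [sp for sp in subpaths if sp is not cand]
                rest = tuple(dict.fromkeys(e for sp in rest_subs for e in sp))
                splits.append((
                    cand, rest, frozenset(bundles[cand]),
                    frozenset(u for sp in rest_subs for u in bundles[sp]),
                ))
        chosen = None
        for side1, edges2, iso1, iso2 in splits:
            p1_edges = _strip_artificial(side1)
            p2_edges = _strip_artificial(edges2)
            if not p1_edges or not p2_edges:
                # a bare transcript end against a spliced continuation has no
                # measurable alternative signal
                continue
            if set(p1_edges) & set(p2_edges):
                continue
            chosen = (p1_edges, p2_edges, iso1, iso2)
            break
        if chosen is None:
            logger.debug("gene %s: no edge-disjoint split at (%s, %s)",
                         graph.gene_id, s, t)
            continue
        p1_edges, p2_edges, iso1, iso2 = chosen
        pair_key = frozenset((frozenset(p1_edges), frozenset(p2_edges)))
        if pair_key in seen_pairs:
            continue

        traversing = sorted(iso1 | iso2)
        prefixes = [units[uid][: node_index[uid][s]] for uid in traversing]
        suffixes = [units[uid][node_index[uid][t]:] for uid in traversing]
        ref_edges = []
        if s != graph.source:
            up = _nearest_shared_exonic(prefixes, reverse=True)
            if up is not None:
                ref_edges.append(up)
        if t != graph.sink:
            down = _nearest_shared_exonic(suffixes, reverse=False)
            if down is not None:
                ref_edges.append(down)

        path1 = Path(p1_edges, "P1")
        path2 = Path(p2_edges, "P2")
        # Path 1 is the longer path in the transcriptome (for two bundles);
        # with >2 bundles the largest bundle keeps the Path 1 slot.
        if len(bundles) == 2 and _path_sort_key(path2) < _path_sort_key(path1):
            path1, path2 = Path(p2_edges, "P1"), Path(p1_edges, "P2")
            iso1, iso2 = iso2, iso1
        event = Event(
            event_id=f"{graph.gene_id}.e{len(events) + 1}",
            gene_id=graph.gene_id,
            chrom=graph.chrom,
            strand=graph.strand,
            type="complex",
            path1=path1,
            path2=path2,
            path_ref=Path(tuple(ref_edges), "Ref"),
            isoforms1=iso1,
            isoforms2=iso2,
            s_node=s,
            t_node=t,
            n_bundles=len(bundles),
        )
        event.type = classify_event(event, graph)
        seen_pairs.add(pair_key)
        events.append(event)
    return events


def classify_event(event: Event, graph: SplicingGraph) -> str:
    """Assign exactly one structural label to an event.

    The label is invariant under swapping Path 1 and Path 2: all predicates
    act on the unordered pair of material-edge signatures.
    """
    if event.n_bundles > 2:
        return "complex"
    at_source = event.s_node == graph.source
    at_sink = event.t_node == graph.sink
    if at_source and at_sink:
        return "complex"
    if at_source:
        return "alt_first"
    if at_sink:
        return "alt_last"

    sig = {event.path1.kind_signature: event.path1,
           event.path2.kind_signature: event.path2}
    kinds = frozenset(sig)

    def material(p: Path):
        return p.material_edges

    if kinds == frozenset({("junction", "exonic", "junction"), ("junction",)}):
        return "cassette"
    if kinds == frozenset({("exonic",), ("junction",)}):
        ex = material(sig[("exonic",)])[0]
        jn = material(sig[("junction",)])[0]
        if ex.span == jn.span:
            return "intron_retention"
        return "complex"
    if kinds == frozenset({("exonic", "junction"), ("junction",)}):
        long_jn = material(sig[("exonic", "junction")])[1]
        short_jn = material(sig[("junction",)])[0]
        if long_jn.to_node == short_jn.to_node:
            return "alt5"
        return "complex"
    if kinds == frozenset({("junction", "exonic"), ("junction",)}):
        long_jn = material(sig[("junction", "exonic")])[0]
        short_jn = material(sig[("junction",)])[0]
        if long_jn.from_node == short_jn.from_node:
            return "alt3"
        return "complex"
    if kinds == frozenset({("junction", "exonic", "junction")}):
        ex1 = material(event.path1)[1].span
        ex2 = material(event.path2)[1].span
        if not ex1.overlaps(ex2):
            return "mutually_exclusive"
        return "complex"
    return "complex"


def event_footprint(event: Event):
    """(A, B, R) interval sets for cross-platform matching.

    A is the footprint of the path with the larger transcriptomic length,
    B the other's; ties break by genomic order of the leftmost coordinate.
    R is the reference-path footprint.
    """
    if not event.path1.edges or not event.path2.edges:
        raise ValueError(f"event {event.event_id} has an empty alternative path")
    k1, k2 = _path_sort_key(event.path1), _path_sort_key(event.path2)
    first, second = (event.path1, event.path2) if k1 <= k2 else (event.path2, event.path1)
    return (first.footprint, second.footprint, event.path_ref.footprint)
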
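"""Per-gene splicing graphs with exon boundaries as nodes.

Each (sub)exonic segment is split into two boundary nodes — where the segment
begins and where it ends in transcription order — joined by an *exonic* edge.
Splice junctions become *junction* edges from the end node of the upstream
exon to the start node of the downstream one; a virtual source and sink tie
up transcript ends with *artificial* edges. Isoforms are source-to-sink paths
and the graph is a DAG under genomic order (reversed for the minus strand).

Graphs are built either from a transcript annotation (every edge then belongs
to at least one isoform) or directly from observed junction/coverage tables,
in which case no isoform map exists and downstream event enumeration works on
graph paths instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

# Effective length of a junction for FPKM: only reads spanning the junction
# with at least `min_anchor` bases on each side observe it.
DEFAULT_READ_LENGTH = 100
DEFAULT_MIN_ANCHOR = 1
DEFAULT_JUNCTION_FPKM = 2.0
DEFAULT_COVERAGE_FPKM = 0.5


def junction_effective_length(
    read_length: int = DEFAULT_READ_LENGTH, min_anchor: int = DEFAULT_MIN_ANCHOR
) -> int:
    return read_length - 2 * min_anchor + 1


def junction_fpkm(count, library_size, effective_length):
    """FPKM of a junction: count × 1e9 / (library_size × effective_length).

    Accepts scalars or numpy arrays.
    """
    library_size = np.asarray(library_size, dtype=float)
    effective_length = np.asarray(effective_length, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    if np.any(effective_length <= 0):
        raise ValueError("effective_length must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (library_size * effective_length)
    return out if out.ndim else float(out)


@dataclass(frozen=True, order=True)
class BoundaryNode:
    """One side of a subexonic segment.

    ``side`` is transcription-oriented: the exonic edge of a segment runs
    start-node → end-node. On the minus strand a start node therefore sits at
    the genomically *larger* coordinate. Virtual source/sink nodes carry
    side="source"/"sink" and position -1.
    """

    chrom: str
    strand: str
    position: int
    side: str  # {"start", "end", "source", "sink"}

    @property
    def is_virtual(self) -> bool:
        return self.side in ("source", "sink")


@dataclass(frozen=True)
class Edge:
    from_node: BoundaryNode
    to_node: BoundaryNode
    kind: str  # {"exonic", "junction", "artificial"}
    span: Optional[GenomicInterval] = None

    @property
    def is_adjacency(self) -> bool:
        """Zero-length junction between abutting segments of one exonic run."""
        return self.kind == "junction" and self.span is None

    @property
    def is_material(self) -> bool:
        """Edges with a genomic footprint and a measurable signal."""
        return self.kind in ("exonic", "junction") and self.span is not None

    @property
    def table_key(self) -> tuple:
        """Key used to join the edge against measurement tables."""
        if self.span is None:
            return (self.kind, self.from_node.position, self.to_node.position)
        return (self.kind, self.span.chrom, self.span.start, self.span.end, self.span.strand)

    def __repr__(self) -> str:  # compact, for debugging and logs
        s = "" if self.span is None else f" {self.span.start}-{self.span.end}"
        return (
            f"<{self.kind}{s} {self.from_node.position}{self.from_node.side[0]}"
            f"->{self.to_node.position}{self.to_node.side[0]}>"
        )


@dataclass
class SplicingGraph:
    gene_id: str
    chrom: str
    strand: str
    nodes: set = field(default_factory=set)
    edges: set = field(default_factory=set)
    isoform_edges: dict = field(default_factory=dict)  # isoform id -> tuple[Edge]

    @property
    def source(self) -> BoundaryNode:
        return BoundaryNode(self.chrom, self.strand, -1, "source")

    @property
    def sink(self) -> BoundaryNode:
        return BoundaryNode(self.chrom, self.strand, -1, "sink")

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.from_node, e.to_node, edge=e)
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_nodes(self) -> list[BoundaryNode]:
        """Nodes in transcription order (genomic order, reversed on −)."""
        sign = -1 if self.strand == "-" else 1
        side_rank = {"source": -2, "end": 0, "start": 1, "sink": 2}

        def key(n: BoundaryNode):
            if n.side == "source":
                return (-np.inf, -2)
            if n.side == "sink":
                return (np.inf, 2)
            # at equal positions the end node precedes the start node
            # (adjacency edges run end -> start at the same coordinate)
            return (sign * n.position, side_rank[n.side])

        return sorted(self.nodes, key=key)

    def out_edges(self, node: BoundaryNode) -> list[Edge]:
        return [e for e in self.edges if e.from_node == node]

    def in_edges(self, node: BoundaryNode) -> list[Edge]:
        return [e for e in self.edges if e.to_node == node]


@dataclass
class GeneAnnotation:
    """Minimal gene model: transcript id → list of exon (start, end) pairs.

    Coordinates are 0-based half-open; exon order within a transcript is
    irrelevant (sorted internally in transcription order).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: Mapping[str, Sequence[tuple[int, int]]]


def _segment_exon(exon: tuple[int, int], boundaries: Sequence[int]) -> list[tuple[int, int]]:
    """Split one exon at every boundary strictly inside it."""
    s, e = exon
    cuts = [b for b in boundaries if s < b < e]
    pts = [s, *cuts, e]
    return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]


def _segment_nodes(chrom: str, strand: str, seg: tuple[int, int]) -> tuple[BoundaryNode, BoundaryNode]:
    """(start-node, end-node) of a segment in transcription order."""
    s, e = seg
    if strand == "-":
        return (
            BoundaryNode(chrom, strand, e, "start"),
            BoundaryNode(chrom, strand, s, "end"),
        )
    return (
        BoundaryNode(chrom, strand, s, "start"),
        BoundaryNode(chrom, strand, e, "end"),
    )


def build_graph_from_gtf(gene: GeneAnnotation) -> SplicingGraph:
    """Build the splicing graph of one annotated gene.

    Overlapping exons from different isoforms are decomposed into disjoint
    subexonic segments at every distinct exon boundary; each segment yields a
    boundary-node pair and an exonic edge, consecutive exons yield junction
    edges, and every transcript becomes one source→sink path recorded in
    ``isoform_edges``.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id}: no transcripts")
    strand = gene.strand if gene.strand in ("+", "-") else "+"
    all_exons: list[tuple[int, int]] = []
    for tx_id, exons in gene.transcripts.items():
        if not exons:
            raise ValueError(f"gene {gene.gene_id}: transcript {tx_id} has no exons")
        for s, e in exons:
            if s >= e:
                raise ValueError(
                    f"gene {gene.gene_id}: transcript {tx_id} exon [{s}, {e}) is empty"
                )
            all_exons.append((int(s), int(e)))

    boundaries = sorted({p for ex in all_exons for p in ex})
    graph = SplicingGraph(gene.gene_id, gene.chrom, strand)
    source, sink = graph.source, graph.sink
    graph.nodes.update((source, sink))

    for tx_id, exons in gene.transcripts.items():
        # transcription order: 5' exon first
        ordered = sorted(exons, key=lambda ex: ex[0], reverse=(strand == "-"))
        chain: list[Edge] = []
        prev_exon: Optional[tuple[int, int]] = None
        prev_end_node: Optional[BoundaryNode] = None
        for exon in ordered:
            segs = _segment_exon(exon, boundaries)
            if strand == "-":
                segs = segs[::-1]
            first_start, _ = _segment_nodes(gene.chrom, strand, segs[0])
            if prev_exon is None:
                chain.append(Edge(source, first_start, "artificial"))
            else:
                if strand == "-":
                    intron = (exon[1], prev_exon[0])
                else:
                    intron = (prev_exon[1], exon[0])
                span = GenomicInterval(gene.chrom, intron[0], intron[1], strand)
                chain.append(Edge(prev_end_node, first_start, "junction", span))
            for i, seg in enumerate(segs):
                n_start, n_end = _segment_nodes(gene.chrom, strand, seg)
                if i > 0:
                    chain.append(Edge(prev_end_node, n_start, "junction"))  # adjacency
                chain.append(
                    Edge(n_start, n_end, "exonic", GenomicInterval(gene.chrom, *seg, strand))
                )
                prev_end_node = n_end
            prev_exon = exon
        chain.append(Edge(prev_end_node, sink, "artificial"))
        graph.isoform_edges[tx_id] = tuple(chain)
        for edge in chain:
            graph.edges.add(edge)
            graph.nodes.update((edge.from_node, edge.to_node))
    return graph


def _sample_columns(df: pd.DataFrame) -> list[str]:
    fixed = {"gene_id", "chrom", "start", "end", "strand"}
    return [c for c in df.columns if c not in fixed]


def build_graph_from_junctions(
    junctions: pd.DataFrame,
    coverage_bins: pd.DataFrame,
    library_sizes: Mapping[str, float],
    min_fpkm: float = DEFAULT_JUNCTION_FPKM,
    min_coverage_fpkm: float = DEFAULT_COVERAGE_FPKM,
    read_length: int = DEFAULT_READ_LENGTH,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    gene_id: str = "data_gene",
) -> SplicingGraph:
    """Build a data-driven splicing graph from junction and coverage tables.

    ``junctions``/``coverage_bins`` carry columns chrom, start, end, strand
    followed by one raw-count column per sample; junction rows give the intron
    interval. A junction is kept if its FPKM reaches ``min_fpkm`` in at least
    one sample; coverage bins are deemed expressed at ``min_coverage_fpkm``.
    The resulting graph has no isoform map.
    """
    if junctions.empty:
        raise ValueError("junction table is empty")
    chrom = str(junctions.iloc[0]["chrom"])
    strand = str(junctions.iloc[0]["strand"])
    if strand not in ("+", "-"):
        strand = "+"
    samples = _sample_columns(junctions)
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    eff_len = junction_effective_length(read_length, min_anchor)

    jx_fpkm = junction_fpkm(junctions[samples].to_numpy(float), libs[None, :], eff_len)
    keep = (jx_fpkm >= min_fpkm).any(axis=1)
    kept_junctions = [
        (int(r.start), int(r.end)) for r, k in zip(junctions.itertuples(), keep) if k
    ]

    expressed: list[tuple[int, int]] = []
    if not coverage_bins.empty:
        cov_samples = _sample_columns(coverage_bins)
        cov_libs = np.array([library_sizes[s] for s in cov_samples], dtype=float)
        lengths = (coverage_bins["end"] - coverage_bins["start"]).to_numpy(float)
        cov_fpkm = junction_fpkm(
            coverage_bins[cov_samples].to_numpy(float), cov_libs[None, :], lengths[:, None]
        )
        cov_keep = (cov_fpkm >= min_coverage_fpkm).any(axis=1)
        for r, k in zip(coverage_bins.itertuples(), cov_keep):
            if k:
                expressed.append((int(r.start), int(r.end)))

    # merge expressed bins into covered runs
    covered: list[list[int]] = []
    for s, e in sorted(expressed):
        if covered and s <= covered[-1][1]:
            covered[-1][1] = max(covered[-1][1], e)
        else:
            covered.append([s, e])

    cut_points = sorted({p for jx in kept_junctions for p in jx})
    graph = SplicingGraph(gene_id, chrom, strand)
    graph.nodes.update((graph.source, graph.sink))

    segments: list[tuple[int, int]] = []
    for s, e in covered:
        pts = [s] + [p for p in cut_points if s < p < e] + [e]
        segments.extend((pts[i], pts[i + 1]) for i in range(len(pts) - 1))

    def covered_at(pos: int, as_end: bool) -> bool:
        # a boundary position is "inside coverage" if some covered run
        # ends (as_end) or starts there, or strictly contains it
        return any(s < pos < e or (as_end and pos == e) or (not as_end and pos == s)
                   for s, e in covered)

    # exonic + adjacency edges
    prev_seg: Optional[tuple[int, int]] = None
    ordered_segments = sorted(segments, reverse=(strand == "-"))
    for seg in ordered_segments:
        n_start, n_end = _segment_nodes(chrom, strand, seg)
        graph.edges.add(Edge(n_start, n_end, "exonic", GenomicInterval(chrom, *seg, strand)))
        graph.nodes.update((n_start, n_end))
        if prev_seg is not None:
            abut = prev_seg[1] == seg[0] if strand == "+" else prev_seg[0] == seg[1]
            if abut:
                _, p_end = _segment_nodes(chrom, strand, prev_seg)
                graph.edges.add(Edge(p_end, n_start, "junction"))
        prev_seg = seg

    for s, e in kept_junctions:
        donor, acceptor = (e, s) if strand == "-" else (s, e)
        for pos, as_end in ((donor, True), (acceptor, False)):
            if not covered_at(pos, as_end):
                logger.warning(
                    "junction boundary %s:%d outside covered regions; "
                    "kept as novel exon boundary", chrom, pos
                )
        d_node = BoundaryNode(chrom, strand, donor, "end")
        a_node = BoundaryNode(chrom, strand, acceptor, "start")
        graph.nodes.update((d_node, a_node))
        graph.edges.add(Edge(d_node, a_node, "junction", GenomicInterval(chrom, s, e, strand)))

    # artificial edges at every terminal boundary
    froms = {e.from_node for e in graph.edges}
    tos = {e.to_node for e in graph.edges}
    for node in sorted(graph.nodes):
        if node.is_virtual:
            continue
        if node not in tos and node in froms:
            graph.edges.add(Edge(graph.source, node, "artificial"))
        if node not in froms and node in tos:
            graph.edges.add(Edge(node, graph.sink, "artificial"))
    return graph
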
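"""File input/output: GTF annotations, measurement tables, result tables.

All tabular interchange is TSV with a comment provenance header; genomic
coordinates are 1-based inclusive in GTF files and 0-based half-open
everywhere else.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .events import Event
from .graph import GeneAnnotation
from .intervals import GenomicInterval
from .match import EventFootprint

logger = logging.getLogger(__name__)

TOOL = "splicescope"


def provenance_header(**params) -> str:
    from . import __version__

    items = "; ".join(f"{k}={v}" for k, v in params.items())
    return f"# {TOOL} v{__version__}" + (f"; {items}" if items else "")


def write_tsv(df: pd.DataFrame, path, index: bool = False, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(**params) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_library_sizes(path) -> dict:
    df = read_tsv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_library_sizes(library_sizes: Mapping[str, float], path, **params) -> None:
    df = pd.DataFrame(
        {"sample": list(library_sizes), "library_size": list(library_sizes.values())}
    )
    write_tsv(df, path, **params)


# ---------------------------------------------------------------------------
# GTF annotations

def read_gtf_genes(path) -> list[GeneAnnotation]:
    """Parse gene models (gene → transcript → exon) from a GTF file.

    Exon features must carry gene_id and transcript_id attributes. GTF
    coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes["gene_id"][0]
        tx_id = exon.attributes["transcript_id"][0]
        g = genes.setdefault(
            gene_id,
            {"chrom": exon.seqid, "strand": exon.strand or "+", "transcripts": {}},
        )
        g["transcripts"].setdefault(tx_id, []).append((exon.start - 1, exon.end))
    return [
        GeneAnnotation(gid, g["chrom"], g["strand"], g["transcripts"])
        for gid, g in genes.items()
    ]


def write_annotation_gtf(genes: Iterable[GeneAnnotation], path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(**params) + "\n")
        for gene in genes:
            for tx_id, exons in gene.transcripts.items():
                for s, e in sorted(exons):
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
                    fh.write(
                        f"{gene.chrom}\t{TOOL}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Event tables

def _join_intervals(ivs: Sequence[GenomicInterval]) -> str:
    return ";".join(f"{iv.start}-{iv.end}" for iv in ivs) or "."


def _parse_intervals(text: str, chrom: str, strand: str) -> tuple:
    if not isinstance(text, str) or text in (".", ""):
        return ()
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return tuple(out)


def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    """Event table: ids, type, strand and semicolon-joined path coordinates.

    The A/B/R columns hold the matching footprints (longer path, shorter
    path, reference) so the table alone supports cross-platform matching.
    """
    from .events import event_footprint

    rows = []
    for ev in events:
        a, b, r = event_footprint(ev)
        rows.append({
            "event_id": ev.event_id, "gene_id": ev.gene_id, "type": ev.type,
            "chrom": ev.chrom, "strand": ev.strand,
            "path1": _join_intervals(ev.path1.footprint),
            "path2": _join_intervals(ev.path2.footprint),
            "ref": _join_intervals(ev.path_ref.footprint),
            "A": _join_intervals(a), "B": _join_intervals(b),
            "R": _join_intervals(r),
        })
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "type", "chrom", "strand",
                 "path1", "path2", "ref", "A", "B", "R"],
    )


def footprints_from_frame(df: pd.DataFrame, platform: str) -> list[EventFootprint]:
    out = []
    for row in df.itertuples():
        out.append(EventFootprint(
            event_id=row.event_id, platform=platform,
            A=_parse_intervals(row.A, row.chrom, row.strand),
            B=_parse_intervals(row.B, row.chrom, row.strand),
            R=_parse_intervals(row.R, row.chrom, row.strand),
        ))
    return out


def write_psi_table(
    psi: pd.DataFrame, results: pd.DataFrame, path, **params
) -> None:
    """Ψ per event × sample with the u, v, ε and ΔΨ columns appended."""
    extra = results.set_index("event_id")[["u", "v", "epsilon", "delta_psi"]]
    write_tsv(psi.join(extra), path, index=True, **params)


# ---------------------------------------------------------------------------
# Event GTF export (genome-browser inspection)

def write_event_gtf(events: Sequence[Event], path, **params) -> None:
    """One transcript-like feature group per event path, for IGV-style browsing.

    Each path role (P1/P2/Ref) becomes a transcript with exon features at
    the path's footprint intervals; attributes carry the event id, type and
    role. Coordinates are written 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write(provenance_header(**params) + "\n")
        for ev in events:
            for role, p in (("P1", ev.path1), ("P2", ev.path2), ("Ref", ev.path_ref)):
                fp = p.footprint
                if not fp:
                    continue
                tx_id = f"{ev.event_id}.{role}"
                attrs = (
                    f'gene_id "{ev.gene_id}"; transcript_id "{tx_id}"; '
                    f'event_id "{ev.event_id}"; event_type "{ev.type}"; '
                    f'path_role "{role}";'
                )
                start = min(iv.start for iv in fp)
                end = max(iv.end for iv in fp)
                fh.write(
                    f"{ev.chrom}\t{TOOL}\ttranscript\t{start + 1}\t{end}\t.\t"
                    f"{ev.strand}\t.\t{attrs}\n"
                )
                for iv in fp:
                    fh.write(
                        f"{ev.chrom}\t{TOOL}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{ev.strand}\t.\t{attrs}\n"
                    )


def read_event_gtf(path) -> dict:
    """Re-parse an exported event GTF into {event_id: {role: interval tuple}}."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if feature != "exon":
                continue
            fields = dict(
                item.strip().split(" ", 1)
                for item in attrs.strip().rstrip(";").split(";")
            )
            eid = fields["event_id"].strip('"')
            role = fields["path_role"].strip('"')
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            out.setdefault(eid, {}).setdefault(role, []).append(iv)
    return {
        eid: {role: tuple(sorted(ivs)) for role, ivs in roles.items()}
        for eid, roles in out.items()
    }
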
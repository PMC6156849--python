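"""End-to-end orchestration: graph → events → filter → Ψ → statistics.

The sequencing pipeline consumes per-gene annotations plus junction/exon-bin
count tables; the array pipeline consumes path-level linear signal matrices.
Both end in the same moderated linear-model test and the opposite-sign +
summarized-p decision rule, so their outputs are directly comparable and
matchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import filters, psi as psi_mod, stats as stats_mod
from .events import Event, enumerate_events
from .graph import (
    GeneAnnotation,
    SplicingGraph,
    build_graph_from_gtf,
    junction_effective_length,
    junction_fpkm,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "event_id", "gene_id", "type", "logfc1", "logfc2", "p1", "p2",
    "p_summary", "direction_ok", "sig_class", "q_value", "delta_psi",
    "u", "v", "epsilon",
]


@dataclass
class AnalysisResult:
    events: list  # retained Event objects
    results: pd.DataFrame  # one row per retained event (RESULT_COLUMNS)
    psi: pd.DataFrame  # event_id × sample Ψ
    pi0: float
    fdr: Optional[stats_mod.FdrResult]


def _edge_tables(
    junctions: pd.DataFrame,
    coverage: pd.DataFrame,
    library_sizes: Mapping[str, float],
    read_length: int,
) -> tuple[dict, dict, list]:
    """Map edge table keys → per-sample counts and FPKM vectors."""
    samples = [c for c in junctions.columns
               if c not in ("gene_id", "chrom", "start", "end", "strand")]
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    eff_len = junction_effective_length(read_length)
    counts: dict[tuple, np.ndarray] = {}
    fpkm: dict[tuple, np.ndarray] = {}
    for row in junctions.itertuples():
        key = ("junction", row.chrom, int(row.start), int(row.end), row.strand)
        c = np.array([getattr(row, s) for s in samples], dtype=float)
        counts[key] = c
        fpkm[key] = junction_fpkm(c, libs, eff_len)
    for row in coverage.itertuples():
        key = ("exonic", row.chrom, int(row.start), int(row.end), row.strand)
        c = np.array([getattr(row, s) for s in samples], dtype=float)
        counts[key] = c
        fpkm[key] = junction_fpkm(c, libs, int(row.end) - int(row.start))
    return counts, fpkm, samples


def _path_vectors(event: Event, table: Mapping[tuple, np.ndarray], n: int, how: str):
    """Per-path signal (mean of member edges) or count (sum) vectors."""
    out = []
    for path in (event.path1, event.path2, event.path_ref):
        edges = path.material_edges
        vecs = [np.asarray(table.get(e.table_key, np.zeros(n)), dtype=float)
                for e in edges]
        if not vecs:
            out.append(np.zeros(n))
        elif how == "mean":
            out.append(psi_mod.summarize_path_signal(np.vstack(vecs)))
        else:
            out.append(np.vstack(vecs).sum(axis=0))
    return out


def _run_stats(
    event_ids: Sequence[str],
    path1_rows: np.ndarray,
    path2_rows: np.ndarray,
    design: stats_mod.DesignSpec,
    weights1: Optional[np.ndarray],
    weights2: Optional[np.ndarray],
    p_method: str,
) -> list:
    fit1 = stats_mod.fit_contrasts(path1_rows, weights1, design)
    fit2 = stats_mod.fit_contrasts(path2_rows, weights2, design)
    # one shared variance prior across all path rows
    all_sigma2 = np.concatenate([fit1.sigma2, fit2.sigma2])
    d0, s0_2 = stats_mod.fit_variance_prior(
        all_sigma2[np.isfinite(all_sigma2) & (all_sigma2 > 0)], fit1.df_residual
    )
    _, p1, _, _ = stats_mod.moderate(
        fit1.coefficients, fit1.stdev_unscaled_rows, fit1.sigma2,
        fit1.df_residual, d0=d0, s0_2=s0_2,
    )
    _, p2, _, _ = stats_mod.moderate(
        fit2.coefficients, fit2.stdev_unscaled_rows, fit2.sigma2,
        fit2.df_residual, d0=d0, s0_2=s0_2,
    )
    return [
        stats_mod.summarize_event(
            eid, float(a), float(b), float(l1), float(l2), method=p_method
        )
        for eid, a, b, l1, l2 in zip(
            event_ids, p1, p2, fit1.coefficients, fit2.coefficients
        )
    ]


def _assemble(
    events: list,
    tests: list,
    psi_rows: dict,
    uv_map: dict,
    delta_map: dict,
    samples: Sequence[str],
) -> AnalysisResult:
    rows = []
    p_summaries = []
    for ev, t in zip(events, tests):
        uv = uv_map[ev.event_id]
        rows.append({
            "event_id": ev.event_id, "gene_id": ev.gene_id, "type": ev.type,
            "logfc1": t.logfc1, "logfc2": t.logfc2, "p1": t.p1, "p2": t.p2,
            "p_summary": t.p_summary, "direction_ok": t.direction_ok,
            "sig_class": t.sig_class, "q_value": np.nan,
            "delta_psi": delta_map.get(ev.event_id, np.nan),
            "u": uv.u, "v": uv.v, "epsilon": uv.epsilon,
        })
        p_summaries.append(t.p_summary)
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    fdr = None
    pi0 = float("nan")
    if len(results) >= 100:
        fdr = stats_mod.estimate_pi0_fdr(np.array(p_summaries))
        results["q_value"] = fdr.q_values
        pi0 = fdr.pi0
    psi_df = pd.DataFrame.from_dict(psi_rows, orient="index", columns=list(samples))
    psi_df.index.name = "event_id"
    return AnalysisResult(events=events, results=results, psi=psi_df, pi0=pi0, fdr=fdr)


def detect_events(genes: Sequence[GeneAnnotation]) -> tuple[list, dict]:
    """Build graphs and enumerate events for a set of annotated genes."""
    events: list[Event] = []
    graphs: dict[str, SplicingGraph] = {}
    for ann in genes:
        graph = build_graph_from_gtf(ann)
        graphs[ann.gene_id] = graph
        events.extend(enumerate_events(graph))
    return events, graphs


def analyze_rnaseq(
    genes: Sequence[GeneAnnotation],
    junctions: pd.DataFrame,
    coverage: pd.DataFrame,
    library_sizes: Mapping[str, float],
    condition: Sequence[str],
    block: Optional[Sequence[str]] = None,
    filter_cfg: Optional[filters.FilterConfig] = None,
    read_length: int = 100,
    p_method: str = "max",
) -> AnalysisResult:
    """Full sequencing analysis from annotation + count tables.

    Path signals for Ψ are mean member-edge FPKM values; path counts for
    the moderated test are summed member-edge counts passed through the
    voom transform under the fitted design.
    """
    filter_cfg = filter_cfg or filters.FilterConfig()
    all_events, _ = detect_events(genes)
    counts, fpkm, samples = _edge_tables(junctions, coverage, library_sizes, read_length)
    n = len(samples)
    events = filters.filter_rnaseq_events(all_events, fpkm, filter_cfg)
    logger.info("retained %d/%d events after the junction filter",
                len(events), len(all_events))
    if not events:
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return AnalysisResult([], empty, pd.DataFrame(), float("nan"), None)

    if block is None:
        block = ["b1"] * n
    design = stats_mod.DesignSpec.from_factors(block, list(condition))

    count1 = np.vstack([_path_vectors(ev, counts, n, "sum")[0] for ev in events])
    count2 = np.vstack([_path_vectors(ev, counts, n, "sum")[1] for ev in events])
    lib_vec = [library_sizes[s] for s in samples]
    stacked = np.vstack([count1, count2])
    y, w = stats_mod.voom_transform(stacked, lib_vec, design.design)
    m = len(events)
    tests = _run_stats(
        [ev.event_id for ev in events],
        y[:m], y[m:], design, w[:m], w[m:], p_method,
    )

    psi_rows, uv_map, delta_map = {}, {}, {}
    for ev in events:
        S1, S2, SR = _path_vectors(ev, fpkm, n, "mean")
        uv = psi_mod.estimate_uv(S1, S2, SR)
        prof = psi_mod.compute_psi(S1, S2, uv, condition=list(condition))
        psi_rows[ev.event_id] = prof.psi
        uv_map[ev.event_id] = uv
        delta_map[ev.event_id] = prof.delta_psi
    return _assemble(events, tests, psi_rows, uv_map, delta_map, samples)


def analyze_array(
    events: Sequence[Event],
    path_signals: Mapping[str, tuple],
    condition: Sequence[str],
    block: Optional[Sequence[str]] = None,
    filter_cfg: Optional[filters.FilterConfig] = None,
    sample_names: Optional[Sequence[str]] = None,
    p_method: str = "max",
) -> AnalysisResult:
    """Array analysis from linear path-signal matrices.

    Signals enter the moderated test as log2(signal + 0.5) with unit
    weights; Ψ estimation uses the linear scale directly.
    """
    filter_cfg = filter_cfg or filters.FilterConfig()
    kept = filters.filter_array_events(list(events), path_signals, filter_cfg)
    logger.info("retained %d/%d array events after the quantile filter",
                len(kept), len(events))
    n = len(list(condition))
    samples = list(sample_names) if sample_names is not None else [
        f"s{i + 1}" for i in range(n)
    ]
    if not kept:
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return AnalysisResult([], empty, pd.DataFrame(), float("nan"), None)
    if block is None:
        block = ["b1"] * n
    design = stats_mod.DesignSpec.from_factors(block, list(condition))

    log1 = np.vstack([np.log2(np.asarray(path_signals[ev.event_id][0]) + 0.5)
                      for ev in kept])
    log2_ = np.vstack([np.log2(np.asarray(path_signals[ev.event_id][1]) + 0.5)
                       for ev in kept])
    tests = _run_stats([ev.event_id for ev in kept], log1, log2_, design,
                       None, None, p_method)

    psi_rows, uv_map, delta_map = {}, {}, {}
    for ev in kept:
        S1, S2, SR = (np.asarray(v, dtype=float) for v in path_signals[ev.event_id])
        uv = psi_mod.estimate_uv(S1, S2, SR)
        prof = psi_mod.compute_psi(S1, S2, uv, condition=list(condition))
        psi_rows[ev.event_id] = prof.psi
        uv_map[ev.event_id] = uv
        delta_map[ev.event_id] = prof.delta_psi
    return _assemble(kept, tests, psi_rows, uv_map, delta_map, samples)


def detection_metrics(result: AnalysisResult, truth: pd.DataFrame) -> dict:
    """Power and false-positive rate of the significance calls vs. truth.

    ``truth`` carries gene_id and a boolean ``differential`` column; cohort
    genes host exactly one event each, so calls map to genes.
    """
    res = result.results.copy()
    res["called"] = res["sig_class"] == "significant"
    by_gene = res.groupby("gene_id")["called"].any()
    merged = truth.set_index("gene_id").join(by_gene, how="left")
    merged["called"] = merged["called"].astype("boolean").fillna(False).astype(bool)
    diff = merged[merged["differential"]]
    null = merged[~merged["differential"]]
    power = float(diff["called"].mean()) if len(diff) else float("nan")
    fpr = float(null["called"].mean()) if len(null) else float("nan")
    return {
        "power": power,
        "fpr": fpr,
        "n_called": int(res["called"].sum()),
        "n_events": int(len(res)),
    }
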
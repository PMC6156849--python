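"""Expression filters that gate events into the analysis.

Sequencing events are kept only when every splice junction on their
alternative paths reaches a junction-coverage threshold (default 2 FPKM) in
enough samples; array events are kept when both alternative paths' signals
exceed an array-wide quantile of the reference-path signal (default the 25%
quantile) in at least one sample. Both retained sets shrink monotonically as
their threshold rises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .events import Event


@dataclass
class FilterConfig:
    rnaseq_junction_fpkm: float = 2.0
    array_quantile: float = 0.25
    require_in_n_samples: int = 1

    def __post_init__(self) -> None:
        if self.rnaseq_junction_fpkm < 0:
            raise ValueError("rnaseq_junction_fpkm must be >= 0")
        if not (0.0 <= self.array_quantile <= 1.0):
            raise ValueError("array_quantile must lie in [0, 1]")
        if self.require_in_n_samples < 1:
            raise ValueError("require_in_n_samples must be >= 1")


def filter_rnaseq_events(
    events: Sequence[Event],
    edge_fpkm: Mapping[tuple, np.ndarray],
    cfg: FilterConfig = FilterConfig(),
) -> list[Event]:
    """Keep events whose alternative-path junctions are all well covered.

    ``edge_fpkm`` maps edge table keys to per-sample FPKM vectors. An event
    is retained iff every splice junction (adjacency edges excluded) of
    Path 1 and Path 2 reaches the FPKM threshold (>=) in at least
    ``require_in_n_samples`` samples.
    """
    kept = []
    for ev in events:
        ok = True
        for path in (ev.path1, ev.path2):
            for e in path.edges:
                if e.kind != "junction" or e.span is None:
                    continue
                fpkm = np.asarray(edge_fpkm.get(e.table_key, [0.0]), dtype=float)
                if np.sum(fpkm >= cfg.rnaseq_junction_fpkm) < cfg.require_in_n_samples:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(ev)
    return kept


def array_signal_threshold(
    reference_signals: np.ndarray, quantile: float = 0.25
) -> float:
    """Array-wide threshold: the given quantile of all reference-path signals.

    Linear-interpolation (type-7) quantile over every reference signal value
    of every event on the array.
    """
    ref = np.asarray(reference_signals, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("empty reference signal matrix")
    return float(np.quantile(ref, quantile))


def filter_array_events(
    events: Sequence[Event],
    path_signals: Mapping[str, tuple],
    cfg: FilterConfig = FilterConfig(),
) -> list[Event]:
    """Keep array events whose alternative paths exceed the quantile threshold.

    ``path_signals`` maps event ids to (S1, S2, SR) per-sample vectors. The
    threshold is computed from all events' reference signals; an event is
    retained iff each alternative path's signal strictly exceeds it in at
    least one sample.
    """
    ids = [ev.event_id for ev in events]
    refs = [np.asarray(path_signals[eid][2], dtype=float) for eid in ids if eid in path_signals]
    if not refs:
        raise ValueError("empty reference signal matrix")
    threshold = array_signal_threshold(np.concatenate(refs), cfg.array_quantile)
    kept = []
    for ev in events:
        sig = path_signals.get(ev.event_id)
        if sig is None:
            continue
        s1, s2 = (np.asarray(sig[0], dtype=float), np.asarray(sig[1], dtype=float))
        if np.any(s1 > threshold) and np.any(s2 > threshold):
            kept.append(ev)
    return kept
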
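"""Cross-platform event matching on genomic footprints.

Each event is reduced to three genomic region sets: A (the longer
alternative path in the transcriptome), B (the shorter) and R (the
reference). Two events from different platforms match when the A regions
are mutually compatible (one contained in the other), the B regions are
compatible, and the references overlap — or the same with A and B roles
crossed, covering ties where the platforms ordered the paths differently.
Matched pairs are then cross-tabulated by significance class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .events import Event, event_footprint
from .intervals import GenomicInterval, merge_intervals, region_subset, regions_overlap

logger = logging.getLogger(__name__)

SIG_CLASSES = ("significant", "inconclusive", "non_significant")


@dataclass
class EventFootprint:
    event_id: str
    platform: str
    A: tuple  # interval set of the longer path
    B: tuple
    R: tuple

    @classmethod
    def from_event(cls, event: Event, platform: str) -> "EventFootprint":
        a, b, r = event_footprint(event)
        return cls(event.event_id, platform, tuple(a), tuple(b), tuple(r))

    @property
    def span(self) -> Optional[GenomicInterval]:
        ivs = merge_intervals([*self.A, *self.B, *self.R])
        if not ivs:
            return None
        return GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end, ivs[0].strand)


@dataclass
class MatchPair:
    event_id_1: str
    event_id_2: str
    rule: str  # {"direct", "swapped"}
    sig_class_1: Optional[str] = None
    sig_class_2: Optional[str] = None


def _compatible(x, y) -> bool:
    """One region contained in the other (mutual-containment disjunction)."""
    return region_subset(x, y) or region_subset(y, x)


def match_footprints(f1: EventFootprint, f2: EventFootprint) -> Optional[str]:
    """Evaluate the matching predicate for one pair of footprints.

    Returns "direct" when A↔A and B↔B are compatible and the references
    overlap, "swapped" when only the crossed A↔B assignment fires, or None.
    """
    if not regions_overlap(f1.R, f2.R):
        return None
    if _compatible(f1.A, f2.A) and _compatible(f1.B, f2.B):
        return "direct"
    if _compatible(f1.A, f2.B) and _compatible(f1.B, f2.A):
        return "swapped"
    return None


def match_events(
    set1: Sequence[EventFootprint],
    set2: Sequence[EventFootprint],
    best_per_event: bool = False,
) -> list[MatchPair]:
    """All matching footprint pairs between two platforms.

    Candidate pairs are pre-filtered by overall span overlap. Many-to-many
    matches are retained unless ``best_per_event``, which keeps, for every
    event of the first set, the pair with maximal reciprocal footprint
    overlap.
    """
    pairs: list[MatchPair] = []
    spans2 = [(f, f.span) for f in set2]
    for f1 in set1:
        s1 = f1.span
        if s1 is None:
            continue
        for f2, s2 in spans2:
            if s2 is None or not s1.overlaps(s2):
                continue
            rule = match_footprints(f1, f2)
            if rule is not None:
                pairs.append(MatchPair(f1.event_id, f2.event_id, rule))
    if best_per_event and pairs:
        by1: dict[str, MatchPair] = {}
        fp1 = {f.event_id: f for f in set1}
        fp2 = {f.event_id: f for f in set2}

        def overlap_score(p: MatchPair) -> int:
            a = merge_intervals([*fp1[p.event_id_1].A, *fp1[p.event_id_1].B])
            b = merge_intervals([*fp2[p.event_id_2].A, *fp2[p.event_id_2].B])
            score = 0
            for x in a:
                for y in b:
                    if x.overlaps(y):
                        score += min(x.end, y.end) - max(x.start, y.start)
            return score

        for p in pairs:
            cur = by1.get(p.event_id_1)
            if cur is None or overlap_score(p) > overlap_score(cur):
                by1[p.event_id_1] = p
        pairs = list(by1.values())
    return pairs


def crosstab_significance(
    pairs: Sequence[MatchPair],
    results1: Mapping[str, str],
    results2: Mapping[str, str],
    all_ids_1: Optional[Sequence[str]] = None,
    all_ids_2: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """3×3 contingency of significance classes over matched pairs.

    ``results*`` map event ids to significance classes. The returned frame
    has platform-1 classes as rows and platform-2 classes as columns, plus
    an ``unmatched`` row/column counting events of either platform with no
    match, and a ``missing`` margin for paired events without a result.
    """
    classes = list(SIG_CLASSES)
    idx = classes + ["unmatched", "missing"]
    table = pd.DataFrame(0, index=idx, columns=idx)
    matched1, matched2 = set(), set()
    for p in pairs:
        c1 = results1.get(p.event_id_1)
        c2 = results2.get(p.event_id_2)
        if c1 is None or c2 is None:
            logger.warning(
                "matched pair (%s, %s) lacks a test result", p.event_id_1, p.event_id_2
            )
        r = c1 if c1 in classes else "missing"
        c = c2 if c2 in classes else "missing"
        table.loc[r, c] += 1
        matched1.add(p.event_id_1)
        matched2.add(p.event_id_2)
    ids1 = set(all_ids_1) if all_ids_1 is not None else set(results1)
    ids2 = set(all_ids_2) if all_ids_2 is not None else set(results2)
    for eid in ids1 - matched1:
        r = results1.get(eid)
        table.loc[r if r in classes else "missing", "unmatched"] += 1
    for eid in ids2 - matched2:
        c = results2.get(eid)
        table.loc["unmatched", c if c in classes else "missing"] += 1
    return table
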
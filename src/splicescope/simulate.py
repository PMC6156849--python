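"""Synthetic data generation for the whole pipeline.

Two layers are simulated, mirroring how the method sees real data:

* **Signal level** — an event's path signals follow the generative model
  S_i = a_i·t_i with multiplicative log-normal noise, where t_1 and t_2 are
  the concentrations of the isoform groups using each alternative path and
  t_R = t_1 + t_2. Known Ψ* = t_1/(t_1+t_2) and affinity fractions
  u* = a_R/a_1, v* = a_R/a_2 make estimator recovery measurable.
* **Read level** — a gene model (exon layout + isoform chains + per-sample
  concentrations in FPKM units) produces junction and exon-bin count tables
  at a stated library size: the expected count of a feature is
  concentration × effective length × library/1e9, with Poisson (default) or
  negative-binomial noise.

All generators are deterministic under an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .graph import GeneAnnotation, junction_effective_length

DEFAULT_READ_LENGTH = 100
#: desk-scale cohort defaults: two conditions × five replicates at the
#: cohort's average sequencing depth (~49 million mapped reads per sample),
#: 30% of events truly differential
COHORT_N_EVENTS = 500
COHORT_N_REPS = 5
COHORT_LIBRARY_SIZE = 4.9e7
COHORT_FRAC_DIFFERENTIAL = 0.3
COHORT_MIN_DELTA_PSI = 0.3
#: gene expression spread: log-normal around 20 FPKM, sd 1.2 on the log scale
COHORT_LOG_FPKM_MEAN = np.log(20.0)
COHORT_LOG_FPKM_SD = 1.2


@dataclass
class SyntheticEvent:
    """Ground truth of one event at the signal level."""

    true_psi: np.ndarray  # Ψ* per sample
    t_total: np.ndarray  # t_R = t1 + t2 per sample
    a1: float = 1.0
    a2: float = 1.0
    aR: float = 1.0
    noise_cv: float = 0.1
    condition: Optional[np.ndarray] = None

    @property
    def t1(self) -> np.ndarray:
        return self.true_psi * self.t_total

    @property
    def t2(self) -> np.ndarray:
        return (1.0 - self.true_psi) * self.t_total

    @property
    def u_true(self) -> float:
        return self.aR / self.a1

    @property
    def v_true(self) -> float:
        return self.aR / self.a2

    @property
    def delta_psi_true(self) -> float:
        if self.condition is None:
            return 0.0
        levels = list(dict.fromkeys(np.asarray(self.condition).tolist()))
        if len(levels) != 2:
            return 0.0
        psi = self.true_psi
        cond = np.asarray(self.condition)
        return float(psi[cond == levels[1]].mean() - psi[cond == levels[0]].mean())


def simulate_signals(event: SyntheticEvent, seed: int):
    """Draw (S1, S2, SR) with multiplicative log-normal noise.

    S_i = a_i·t_i·exp(N(0, σ²)) with σ = noise_cv (the coefficient of
    variation for small σ); the reference signal uses t_R = t1 + t2.
    """
    rng = np.random.default_rng(seed)
    n = len(event.true_psi)
    sigma = float(event.noise_cv)

    def noisy(mean):
        if sigma == 0:
            return np.asarray(mean, dtype=float)
        return mean * np.exp(rng.normal(0.0, sigma, size=n))

    S1 = noisy(event.a1 * event.t1)
    S2 = noisy(event.a2 * event.t2)
    SR = noisy(event.aR * event.t_total)
    return S1, S2, SR


def make_signal_event(
    rng: np.random.Generator,
    n_samples: int = 10,
    delta_psi: float = 0.0,
    noise_cv: float = 0.1,
    uv_range: tuple = (0.7, 1.4),
    t_scale: float = 50.0,
) -> SyntheticEvent:
    """Random event with a two-condition Ψ* profile and random affinities.

    The affinity fractions u*, v* are drawn uniformly from ``uv_range``
    (aR = 1, a1 = 1/u*, a2 = 1/v*). Half the samples sit in each condition;
    baseline Ψ is drawn so Ψ + ΔΨ stays inside [0.05, 0.95].
    """
    lo = 0.05
    hi = 0.95 - abs(delta_psi)
    psi_a = rng.uniform(lo, max(hi, lo + 1e-6))
    psi_b = psi_a + abs(delta_psi)
    n1 = n_samples // 2
    psi = np.concatenate([np.full(n1, psi_a), np.full(n_samples - n1, psi_b)])
    condition = np.array(["c1"] * n1 + ["c2"] * (n_samples - n1))
    u = rng.uniform(*uv_range)
    v = rng.uniform(*uv_range)
    t_total = np.full(n_samples, t_scale, dtype=float)
    return SyntheticEvent(
        true_psi=psi,
        t_total=t_total,
        a1=1.0 / u,
        a2=1.0 / v,
        aR=1.0,
        noise_cv=noise_cv,
        condition=condition,
    )


@dataclass
class SyntheticGene:
    """Gene model for read-level simulation.

    ``isoforms`` maps transcript ids to exon (start, end) chains;
    ``concentrations`` maps transcript ids to per-sample FPKM-scale values.
    """

    gene_id: str
    chrom: str
    strand: str
    isoforms: Mapping[str, Sequence[tuple]]
    concentrations: Mapping[str, np.ndarray]
    read_length: int = DEFAULT_READ_LENGTH

    @property
    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.gene_id, self.chrom, self.strand, dict(self.isoforms))

    @property
    def sample_count(self) -> int:
        return len(next(iter(self.concentrations.values())))


def _segments(gene: SyntheticGene) -> list[tuple]:
    exons = [tuple(e) for tx in gene.isoforms.values() for e in tx]
    boundaries = sorted({p for ex in exons for p in ex})
    segs = set()
    for s, e in exons:
        pts = [s] + [b for b in boundaries if s < b < e] + [e]
        for i in range(len(pts) - 1):
            segs.add((pts[i], pts[i + 1]))
    return sorted(segs)


def simulate_reads_to_counts(
    gene: SyntheticGene,
    library_sizes: Mapping[str, float],
    seed: int,
    noise: str = "poisson",
    dispersion: float = 0.0,
):
    """Junction and exon-bin count tables for one gene.

    The expected junction count is the summed concentration of the isoforms
    containing the junction × junction effective length × library/1e9; bins
    are the gene's subexonic segments with the bin width as effective
    length. ``noise`` is "poisson" or "nb" (gamma-Poisson with the given
    dispersion). Sample order follows ``library_sizes``.
    """
    rng = np.random.default_rng(seed)
    samples = list(library_sizes)
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    eff_len = junction_effective_length(gene.read_length)

    junction_conc: dict[tuple, np.ndarray] = {}
    for tx, exons in gene.isoforms.items():
        conc = np.asarray(gene.concentrations[tx], dtype=float)
        ordered = sorted(exons, key=lambda ex: ex[0], reverse=(gene.strand == "-"))
        for a, b in zip(ordered, ordered[1:]):
            intron = (a[1], b[0]) if gene.strand != "-" else (b[1], a[0])
            junction_conc[intron] = junction_conc.get(intron, 0.0) + conc

    seg_conc: dict[tuple, np.ndarray] = {}
    for seg in _segments(gene):
        total = np.zeros(gene.sample_count)
        for tx, exons in gene.isoforms.items():
            if any(s <= seg[0] and seg[1] <= e for s, e in exons):
                total = total + np.asarray(gene.concentrations[tx], dtype=float)
        seg_conc[seg] = total

    def draw(expected: np.ndarray) -> np.ndarray:
        expected = np.maximum(expected, 0.0)
        if noise == "nb" and dispersion > 0:
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, expected / shape)
            return rng.poisson(lam)
        return rng.poisson(expected)

    def table(conc_map: Mapping[tuple, np.ndarray], length_of) -> pd.DataFrame:
        rows = []
        for (s, e), conc in sorted(conc_map.items()):
            expected = conc * length_of(s, e) * libs / 1e9
            counts = draw(expected)
            rows.append({"chrom": gene.chrom, "start": s, "end": e,
                         "strand": gene.strand,
                         **{smp: int(c) for smp, c in zip(samples, counts)}})
        cols = ["chrom", "start", "end", "strand", *samples]
        return pd.DataFrame(rows, columns=cols)

    junctions = table(junction_conc, lambda s, e: eff_len)
    bins = table(seg_conc, lambda s, e: e - s)
    return junctions, bins


def random_gene(
    rng: np.random.Generator,
    gene_id: str = "g",
    max_exons: int = 6,
    max_isoforms: int = 4,
    chrom: str = "chr1",
) -> GeneAnnotation:
    """Small random gene for enumeration stress tests.

    Exons sit on a fixed skeleton; isoforms take random exon subsets and may
    shift an exon's 5'/3' boundary, producing cassette, alternative-site,
    first/last-exon and complex configurations.
    """
    n_exons = int(rng.integers(2, max_exons + 1))
    n_iso = int(rng.integers(2, max_isoforms + 1))
    strand = rng.choice(["+", "-"])
    base = []
    pos = int(rng.integers(100, 200))
    for _ in range(n_exons):
        length = int(rng.integers(40, 81))
        base.append((pos, pos + length))
        pos += length + int(rng.integers(50, 151))
    transcripts: dict[str, list] = {}
    for i in range(n_iso):
        exons = []
        for s, e in base:
            if rng.random() < 0.7:
                s2 = s + 10 if rng.random() < 0.2 else s
                e2 = e - 10 if rng.random() < 0.2 else e
                exons.append((s2, e2))
        if not exons:
            s, e = base[int(rng.integers(0, n_exons))]
            exons.append((s, e))
        transcripts[f"{gene_id}.t{i + 1}"] = exons
    return GeneAnnotation(gene_id, chrom, str(strand), transcripts)


def cassette_gene(
    gene_id: str,
    offset: int = 0,
    chrom: str = "chr1",
    strand: str = "+",
    exon_len: int = 80,
    intron_len: int = 200,
) -> GeneAnnotation:
    """Three-exon gene with an inclusion and a skipping isoform."""
    e1 = (offset, offset + exon_len)
    e2 = (e1[1] + intron_len, e1[1] + intron_len + exon_len)
    e3 = (e2[1] + intron_len, e2[1] + intron_len + exon_len)
    return GeneAnnotation(
        gene_id, chrom, strand,
        {f"{gene_id}.inc": [e1, e2, e3], f"{gene_id}.skp": [e1, e3]},
    )


@dataclass
class Cohort:
    """A simulated sequencing cohort plus its ground truth."""

    genes: list  # list[SyntheticGene]
    junctions: pd.DataFrame  # combined table with a gene_id column
    coverage: pd.DataFrame
    library_sizes: dict
    condition: np.ndarray
    truth: pd.DataFrame  # gene_id, psi_c1, psi_c2, delta_psi, differential


def simulate_cohort(
    seed: int,
    n_events: int = COHORT_N_EVENTS,
    n_reps: int = COHORT_N_REPS,
    library_size: float = COHORT_LIBRARY_SIZE,
    frac_differential: float = COHORT_FRAC_DIFFERENTIAL,
    min_delta_psi: float = COHORT_MIN_DELTA_PSI,
    noise: str = "poisson",
    dispersion: float = 0.0,
) -> Cohort:
    """Two-condition cassette-exon cohort at a stated library size.

    Each event is one three-exon gene with an inclusion and a skipping
    isoform. Gene expression is log-normal (median ~20 FPKM); a fraction of
    events change Ψ between conditions by at least ``min_delta_psi`` (drawn
    up to 0.6), the rest keep Ψ constant (null events).
    """
    rng = np.random.default_rng(seed)
    samples = [f"c1_r{i + 1}" for i in range(n_reps)] + [
        f"c2_r{i + 1}" for i in range(n_reps)
    ]
    condition = np.array(["c1"] * n_reps + ["c2"] * n_reps)
    library_sizes = {s: float(library_size) for s in samples}

    genes, j_parts, c_parts, truth_rows = [], [], [], []
    for i in range(n_events):
        gene_id = f"g{i + 1:04d}"
        ann = cassette_gene(gene_id, offset=1000 + i * 2000)
        total_fpkm = float(
            np.exp(rng.normal(COHORT_LOG_FPKM_MEAN, COHORT_LOG_FPKM_SD))
        )
        differential = bool(rng.random() < frac_differential)
        psi_c1 = float(rng.uniform(0.15, 0.85))
        if differential:
            delta = float(rng.uniform(min_delta_psi, 0.6))
            lo, hi = 0.05, 0.95
            if psi_c1 + delta <= hi:
                psi_c2 = psi_c1 + delta
            else:
                psi_c2 = max(psi_c1 - delta, lo)
        else:
            psi_c2 = psi_c1
        psi = np.array([psi_c1] * n_reps + [psi_c2] * n_reps)
        conc_inc = psi * total_fpkm
        conc_skp = (1.0 - psi) * total_fpkm
        gene = SyntheticGene(
            gene_id, "chr1", "+",
            isoforms=dict(ann.transcripts),
            concentrations={f"{gene_id}.inc": conc_inc, f"{gene_id}.skp": conc_skp},
        )
        jx, cov = simulate_reads_to_counts(
            gene, library_sizes, seed=int(rng.integers(0, 2**31 - 1)),
            noise=noise, dispersion=dispersion,
        )
        jx.insert(0, "gene_id", gene_id)
        cov.insert(0, "gene_id", gene_id)
        genes.append(gene)
        j_parts.append(jx)
        c_parts.append(cov)
        truth_rows.append({
            "gene_id": gene_id, "psi_c1": psi_c1, "psi_c2": psi_c2,
            "delta_psi": psi_c2 - psi_c1, "differential": differential,
            "total_fpkm": total_fpkm,
        })
    return Cohort(
        genes=genes,
        junctions=pd.concat(j_parts, ignore_index=True),
        coverage=pd.concat(c_parts, ignore_index=True),
        library_sizes=library_sizes,
        condition=condition,
        truth=pd.DataFrame(truth_rows),
    )


def simulate_array_signals_for_cohort(
    cohort: Cohort,
    seed: int,
    noise_cv: float = 0.1,
    uv_range: tuple = (0.8, 1.25),
    scale: float = 1.0,
) -> dict:
    """Array-platform signals sharing the cohort's splicing truth.

    For every cohort gene the same Ψ* profile drives a signal-level event
    with platform-specific affinities; returns (S1, S2, SR) arrays keyed by
    event id (each cohort gene hosts exactly one event, "<gene>.e1").
    """
    rng = np.random.default_rng(seed)
    out = {}
    for gene, row in zip(cohort.genes, cohort.truth.itertuples()):
        n_reps = len(cohort.condition) // 2
        psi = np.array([row.psi_c1] * n_reps + [row.psi_c2] * n_reps)
        u = rng.uniform(*uv_range)
        v = rng.uniform(*uv_range)
        ev = SyntheticEvent(
            true_psi=psi,
            t_total=np.full(len(psi), row.total_fpkm * scale),
            a1=1.0 / u, a2=1.0 / v, aR=1.0,
            noise_cv=noise_cv,
            condition=cohort.condition,
        )
        out[f"{row.gene_id}.e1"] = simulate_signals(
            ev, seed=int(rng.integers(0, 2**31 - 1))
        )
    return out
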
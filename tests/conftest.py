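import numpy as np
import pytest

from splicescope.graph import GeneAnnotation, build_graph_from_gtf
from splicescope.events import enumerate_events
from splicescope.simulate import cassette_gene, simulate_cohort


@pytest.fixture(scope="session")
def cassette_graph():
    """Three-exon gene (inclusion + skipping isoform), plus strand."""
    return build_graph_from_gtf(cassette_gene("g1"))


@pytest.fixture(scope="session")
def cassette_event(cassette_graph):
    events = enumerate_events(cassette_graph)
    assert len(events) == 1
    return events[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-event sequencing cohort shared by pipeline-level tests."""
    return simulate_cohort(seed=101, n_events=150)


def make_gene(gene_id, strand, transcripts, chrom="chr1"):
    return GeneAnnotation(gene_id, chrom, strand, transcripts)
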
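import numpy as np
import pytest

from divscreen.config import PipelineConfig
from divscreen.records import VariantSite
from divscreen.simulate import SimulationParams, simulate_allele_counts, simulate_unigenes
from divscreen.snp_screen import dedup_longest_isoform


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_site(tid="t1", pos=0, ref="A", alt="G", a=(50, 50), b=(100, 0), qual=60.0):
    return VariantSite(
        transcript_id=tid, position=pos, ref_allele=ref, alt_allele=alt,
        counts_by_species={"A": a, "B": b}, quality=qual,
    )


@pytest.fixture
def small_dataset():
    """A small seeded catalog + planted variants + truth table."""
    params = SimulationParams(
        n_unigenes=40, n_shared_snps=80, n_specific_snps=40, n_fixed_snps=12,
        n_fixed_unigenes=4, depth_distribution=(500.0, 20.0), rng_seed=11,
    )
    rng = np.random.default_rng(params.rng_seed)
    transcripts = simulate_unigenes(params, rng)
    catalog = dedup_longest_isoform(transcripts)
    sites, truth = simulate_allele_counts(catalog, params, rng)
    return params, transcripts, catalog, sites, truth
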
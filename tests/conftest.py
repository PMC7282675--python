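import numpy as np
import pytest

from metdrive import SimConfig, generate, run_pipeline, simulate_cohort
from metdrive.core import GeneModel, GenomicInterval


@pytest.fixture(scope="session")
def nf_config():
    """Noise-free, expectation-mode study conditions for exact recovery."""
    return SimConfig(seed=3, caller_fp_rate=0.0, caller_fn_rate=0.0, count_model="expected")


@pytest.fixture(scope="session")
def nf_run(nf_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("nf_run")
    result = simulate_cohort(nf_config, out)
    return out, result


@pytest.fixture(scope="session")
def nf_pipeline(nf_run, tmp_path_factory):
    run_dir, result = nf_run
    out = tmp_path_factory.mktemp("nf_out")
    report = run_pipeline(run_dir, out)
    return result, report, out


@pytest.fixture(scope="session")
def noisy_result():
    """Default (binomial, caller-noise) cohort, in memory."""
    return generate(SimConfig(seed=11))


def make_gene(
    symbol="toy",
    chrom="chrT",
    strand="+",
    exon_seqs=("ATGGCTAAA",),
    exon_starts=(100,),
    family=None,
):
    exons = [
        GenomicInterval(chrom, s, s + len(seq)) for s, seq in zip(exon_starts, exon_seqs)
    ]
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end)
    return GeneModel(
        gene_symbol=symbol,
        family_id=family,
        strand=strand,
        span=span,
        exons=exons,
        exon_seqs=list(exon_seqs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
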
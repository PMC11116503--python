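import numpy as np
import pytest

from rnasm.features import FeatureExtractor
from rnasm.filters import FilterResources
from rnasm.synth import make_benchmark


@pytest.fixture(scope="session")
def bench(tmp_path_factory):
    """Default synthetic benchmark: 1,000 truth-labelled sites, all classes."""
    outdir = tmp_path_factory.mktemp("bench")
    return make_benchmark(123, outdir, n_sites=1000)


@pytest.fixture(scope="session")
def bench_resources(bench):
    return FilterResources(germline=bench.germline, editing=bench.editing,
                           gene_models=bench.gene_models, genome=bench.genome)


@pytest.fixture(scope="session")
def bench_features(bench, bench_resources):
    X = FeatureExtractor(bench_resources, tpm=bench.tpm).matrix(
        bench.candidates, bench.evidence)
    return X, bench.labels()


@pytest.fixture(scope="session")
def tiny_fasta(tmp_path_factory):
    """A small hand-written FASTA for exact-context tests."""
    d = tmp_path_factory.mktemp("tinyfa")
    p = d / "tiny.fa"
    seq1 = "ACGT" * 50
    seq2 = "G" * 120
    seq3 = "AT" * 60
    p.write_text(f">c1\n{seq1}\n>c2\n{seq2}\n>c3\n{seq3}\n")
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
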
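import numpy as np
import pandas as pd
import pytest

from plantmeth.calls import CALL_COLUMNS
from plantmeth.simulate import SimConfig, simulate_study


def make_calls(rows):
    """Build a call table from (chrom, pos, strand, context, meth, cov) tuples."""
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@pytest.fixture
def calls_factory():
    return make_calls


def random_calls(rng, n=200, chrom="chr1", span=10_000, cov_mean=12):
    """Random but valid call table for property-style checks."""
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))
    cov = rng.poisson(cov_mean, size=n) + 1
    meth = rng.binomial(cov, rng.uniform(0, 1, size=n))
    # context is a property of the reference position, not of the library
    context = np.array(["CG", "CHG", "CHH"])[pos % 3]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": np.where(pos % 2 == 0, "+", "-"),
            "context": context,
            "methylated": meth,
            "coverage": cov,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across module tests (the full-size
    defaults are exercised by the acceptance tests)."""
    cfg = SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=800_000,
        n_genes=64,
        n_tes=100,
        n_planted_dmrs=30,
        n_planted_dmvs=8,
        n_degs=16,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    from plantmeth.pipeline import write_default_config
    from plantmeth.simulate import write_study

    outdir = tmp_path_factory.mktemp("study")
    write_study(small_study, outdir)
    write_default_config(
        outdir, outdir / "run_config.yaml",
        small_study.config.tissues, small_study.config.n_replicates,
    )
    return outdir
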
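import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cellprs as cp

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sumstats(rows, trait="toy", n_total=1000):
    """Build a SummaryStats from (snp, chr, bp, a1, a2, beta, se, p, maf, info)."""
    df = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA",
                                     "SE", "P", "MAF", "INFO"])
    return cp.SummaryStats.from_frame(trait, n_total, df)


@pytest.fixture(scope="session")
def small_arch():
    return cp.SimArchitecture(
        n_snps=600, n_genes=120, ld_blocks=[(3, 0.9)] * 40,
        n_low_maf=10, n_low_info=10, n_apoe=8, n_mhc=8,
        n_multi_gene=8, n_intergenic=16,
    )


@pytest.fixture(scope="session")
def small_study(small_arch):
    """One modest synthetic study shared by read-only tests."""
    return cp.simulate_study(small_arch, n_exposure=4000, n_outcome=4000,
                             n_ref=1200, seed=7)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    cfg = cp.RunConfig(rng_seed=7, n_perm=200)
    return cp.run_pipeline(
        small_study.exposure, small_study.outcome_combined, small_study.ld_ref,
        small_study.genes, small_study.cell_sets, cfg,
        outcome_discovery=small_study.outcome_discovery,
        outcome_replication=small_study.outcome_replication,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
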
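import numpy as np
import pandas as pd
import pytest

from methsig import BetaMatrix, SimulationConfig, simulate_paired_cohort


@pytest.fixture(scope="session")
def small_paired():
    """20 pairs x 300 probes, 2 cancer types, planted effects at defaults."""
    cfg = SimulationConfig(
        n_pairs=20, n_probes=300, n_cancer_types=2, seed=101
    )
    return simulate_paired_cohort(cfg)


@pytest.fixture()
def tiny_matrix():
    """Hand-built 3-probe, 2-pair matrix with a missing entry."""
    values = pd.DataFrame(
        {
            "P1-T": [0.8, 0.2, 0.5],
            "P1-N": [0.3, 0.2, np.nan],
            "P2-T": [0.7, 0.4, 0.6],
            "P2-N": [0.2, 0.4, 0.4],
        },
        index=["cgA", "cgB", "cgC"],
    )
    samples = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P2"],
            "tissue_type": ["tumor", "normal", "tumor", "normal"],
            "cancer_type": ["CT1", "CT1", "CT1", "CT1"],
            "purity": [0.9, np.nan, 0.8, np.nan],
        },
        index=pd.Index(["P1-T", "P1-N", "P2-T", "P2-N"], name="sample_id"),
    )
    return BetaMatrix(values, samples)


def make_annotation(probe_ids, **overrides):
    """Fully autosomal, SNP-free annotation; override columns per test."""
    n = len(probe_ids)
    ann = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chrom": ["chr1"] * n,
            "pos": np.arange(1, n + 1),
            "island_relation": ["island"] * n,
            "region": ["TSS"] * n,
            "gene": ["G1"] * n,
            "snp_flag": [False] * n,
        }
    )
    for k, v in overrides.items():
        ann[k] = v
    return ann
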
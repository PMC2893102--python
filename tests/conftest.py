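import numpy as np
import pandas as pd
import pytest

from cnexpress.copy_number import CopyNumberProfile


def make_profile(chroms, positions, log2_matrix, segmented=None, sample_prefix="s"):
    """Assemble a CopyNumberProfile from parallel lists (test helper)."""
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(len(positions))],
            "chrom": chroms,
            "pos": positions,
        }
    )
    log2 = np.atleast_2d(np.asarray(log2_matrix, float))
    if log2.shape[0] != len(positions):
        log2 = log2.T
    cols = [f"{sample_prefix}{j}" for j in range(log2.shape[1])]
    ratios = pd.DataFrame(log2, index=snps["snp_id"].values, columns=cols)
    seg = None
    if segmented is not None:
        seg = np.atleast_2d(np.asarray(segmented, float))
        if seg.shape[0] != len(positions):
            seg = seg.T
        seg = pd.DataFrame(seg, index=snps["snp_id"].values, columns=cols)
    return CopyNumberProfile(snps=snps, log2_ratios=ratios, segmented=seg)


@pytest.fixture(scope="session")
def small_cohort():
    """Discovery cohort shared across tests: layout, noisy profile, truth."""
    from cnexpress import synthetic_data as syn

    layout = syn.simulate_layout(2, 400, 60, seed=42)
    profile, truth = syn.simulate_copy_number(layout, 12, noise_sd=0.1, seed=43)
    return layout, profile, truth


@pytest.fixture(scope="session")
def testing_cohort():
    """Case/control cohort with survival, shared across enrichment/survival tests."""
    from cnexpress import synthetic_data as syn

    ids = [f"t{i:05d}" for i in range(120)]
    risk = ids[:8]
    clin, expr = syn.simulate_clinical(
        130, 40, ids, risk, hr_per_unit=1.8, censor_rate=0.01, seed=7
    )
    return clin, expr, ids, risk
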
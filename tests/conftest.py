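"""Shared fixtures: small simulated trials and published-table fixtures."""

import numpy as np
import pandas as pd
import pytest

import metsel
from metsel.synthetic import SimulationSpec, TraitSim

# one FRY-like trait at the published component magnitudes
FRY_LIKE = TraitSim(
    name="FRY", mean=24.22,
    var_g=(0.1720 * 24.22) ** 2,       # 17.354
    var_e=2.0 * (0.1720 * 24.22) ** 2,
    var_gxe=20.55,
    var_eps=(0.1670 * 24.22) ** 2,     # 16.360
)


@pytest.fixture(scope="session")
def small_balanced():
    """Balanced 10 x 8 x 2 single-trait MET with zero block offsets."""
    spec = SimulationSpec(g=10, e=8, b=2, seed=11, block_sd_scale=0.0,
                          traits=(FRY_LIKE,))
    dataset, effects = metsel.simulate_met(spec)
    return dataset, effects


@pytest.fixture(scope="session")
def small_fit(small_balanced):
    dataset, _ = small_balanced
    return metsel.fit_random_model(dataset, "FRY")


@pytest.fixture(scope="session")
def full_scale_fit():
    """One 22 x 47 x 3 trial at published-magnitude components, fitted."""
    spec = SimulationSpec(seed=42, traits=(FRY_LIKE,))
    dataset, effects = metsel.simulate_met(spec)
    fit = metsel.fit_random_model(dataset, "FRY")
    return dataset, effects, fit


@pytest.fixture
def toy_dataset():
    """3 genotypes x 2 environments x 2 blocks, one trait, hand-checkable."""
    rows = []
    vals = iter([10, 12, 11, 13, 20, 22, 21, 23, 30, 32, 31, 33])
    for g in ["G1", "G2", "G3"]:
        for e in ["E1", "E2"]:
            for b in ["B1", "B2"]:
                rows.append({"genotype": g, "environment": e, "block": b,
                             "yield": next(vals)})
    return metsel.METDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# published factor-analysis table for the regression-deviation statistic
# (loadings after varimax, eigenvalues of the 7-trait correlation matrix)
# ---------------------------------------------------------------------------

TABLE3_SDI2_LOADINGS = pd.DataFrame(
    {
        "FA1": [-0.70, -0.96, 0.10, -0.90, -0.64, -0.78, -0.05],
        "FA2": [-0.65, 0.01, -0.97, 0.12, -0.15, -0.59, -0.12],
        "FA3": [0.03, -0.20, 0.11, 0.34, -0.57, -0.17, 0.95],
    },
    index=["FRY", "ShY", "HI", "PH", "DMC", "DRY", "PIA"],
)
TABLE3_SDI2_EIGENVALUES = np.array([3.64, 1.55, 1.27])


@pytest.fixture(scope="session")
def correlated_mps_matrix():
    """Synthetic genotypes x traits MPS-like matrix with a 3-block
    correlation structure, rescaled to [0, 100]."""
    rng = np.random.default_rng(99)
    q = 22
    f = rng.normal(size=(q, 3))
    load = np.array([
        [0.9, 0.1, 0.0],   # yield-like block
        [0.8, 0.2, 0.1],
        [0.85, 0.0, 0.1],
        [0.1, 0.9, 0.0],   # canopy-like block
        [0.0, 0.8, 0.2],
        [0.1, 0.1, 0.9],   # quality-like block
        [0.0, 0.2, 0.85],
    ])
    X = f @ load.T + 0.3 * rng.normal(size=(q, 7))
    cols = ["FRY", "ShY", "DRY", "PH", "HI", "DMC", "PIA"]
    df = pd.DataFrame(X, columns=cols,
                      index=[f"G{i+1:02d}" for i in range(q)])
    return df.apply(lambda c: metsel.rescale(c, True))
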
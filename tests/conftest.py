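import numpy as np
import pandas as pd
import pytest

import pleiomr as pm


def make_summary(n=20, seed=0, effect_allele="A", other_allele="G"):
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.05, n)
    se = rng.uniform(0.01, 0.03, n)
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "chrom": "1",
        "pos": 100 * np.arange(1, n + 1),
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "beta": beta,
        "se": se,
        "n": 10_000,
    })
    df["z"] = df["beta"] / df["se"]
    return df


def make_pairs(p=20, L=4, seed=0, beta1=0.2):
    """Small synthetic pair table consistent with the model (identity LD)."""
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0, 0.05, p)
    s_g = np.full(p, 0.005)
    s_G = np.full(p, 0.005)
    Gamma = beta1 * gamma + rng.normal(0, 0.01, p)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(p)],
        "chrom": "1",
        "pos": 1000 * np.arange(p),
        "effect_allele": "A",
        "other_allele": "G",
        "gamma_hat": gamma + rng.normal(0, s_g),
        "s_gamma": s_g,
        "Gamma_hat": Gamma + rng.normal(0, s_G),
        "s_Gamma": s_G,
        "block_index": np.arange(p) % L,
    }).sort_values("block_index").reset_index(drop=True)


@pytest.fixture(scope="session")
def chp_study():
    """Moderate-size study with strong correlated pleiotropy (shared)."""
    cfg = pm.SimConfig(n_x=15_000, n_y=15_000, n_r=2_000, p=500, L=50,
                       h2_theta=0.02, h2_alpha=0.1, rho_alpha_gamma=0.2,
                       beta1=0.1, seed=42)
    return pm.simulate_study(cfg)


@pytest.fixture(scope="session")
def chp_fit(chp_study):
    return pm.run_mcmc(chp_study.pairs, chp_study.ld, n_iter=2000,
                       burn_in=1000, seed=7)
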
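"""Synthetic GWAS study generator.

Generates individual-level genotypes and traits under a polygenic
structural model with a heritable shared confounder, runs single-variant
association scans in two non-overlapping cohorts, and returns harmonized
summary statistics together with the generating ground truth.

The standard scenario draws, per instrument k,

    x = G gamma + U psi_x + e_x,
    y = beta1 x + G alpha + G theta + U psi_y + e_y,

with (gamma_k, alpha_k) bivariate normal (correlation rho_alpha_gamma) on
a sparse, block-aligned support for alpha (correlated pleiotropy), dense
i.i.d. theta (uncorrelated pleiotropy), and q confounders U whose
coefficient pairs (psi_x, psi_y) are correlated at 0.8.  Genotypes are
AR(1)-correlated within LD blocks (blocks independent), thresholded to
dosages {0,1,2} by Hardy-Weinberg category probabilities at a minor
allele frequency drawn uniformly from [0.05, 0.5].

Effect vectors are scaled *empirically*: each genetic component is
rescaled on the simulated genotypes so its realized variance fraction
hits the target, and residual noise tops the trait variance up to one.
The generator therefore controls variance fractions, not raw effect
scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigurationError
from .ld import BlockLD, empirical_corr, shrink_corr


@dataclass
class SimConfig:
    """Standard-scenario parameters (defaults are the study conditions)."""

    n_x: int = 50_000
    n_y: int = 50_000
    n_r: int = 4_000
    p: int = 1_000
    L: int = 100
    r: float = 0.4
    maf_range: tuple = (0.05, 0.5)
    q: int = 50
    h2_gamma: float = 0.1     # var(G_x gamma)/var(x): instrument heritability of exposure
    h2_theta: float = 0.05    # var(G_y theta)/var(y): uncorrelated pleiotropy
    h2_alpha: float = 0.05    # var(G_y alpha)/var(y): correlated pleiotropy
    rho_alpha_gamma: float = 0.2
    beta1: float = 0.0
    chp_sparsity: float = 0.10
    psi_corr: float = 0.8
    confounder_share: float = 0.3  # share of the non-genetic remainder taken by U*psi
    overlap_frac: float = 0.0      # fraction of the outcome cohort shared with exposure cohort
    lam: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r < 1.0:
            raise ConfigurationError(f"AR(1) correlation must be in [0, 1), got {self.r}")
        if self.p % self.L:
            raise ConfigurationError("p must be divisible by L")
        if self.h2_gamma < 0 or self.h2_theta < 0 or self.h2_alpha < 0:
            raise ConfigurationError("heritability fractions must be >= 0")
        if self.h2_theta + self.h2_alpha + self.beta1 ** 2 >= 1.0:
            raise ConfigurationError("outcome variance budget exceeds 1")

    @property
    def block_size(self) -> int:
        return self.p // self.L


@dataclass
class ReverseConfig:
    """Reverse-causation design: y = beta1*x + G theta + e, sparse gamma."""

    n_x: int = 50_000
    n_y: int = 50_000
    n_r: int = 4_000
    p: int = 2_000
    L: int = 200
    r: float = 0.4
    maf_range: tuple = (0.05, 0.5)
    h2_x: float = 0.3
    h2_y: float = 0.25
    causal_share: float = 0.2     # fraction of h2_y explained by the causal path
    gamma_sparsity: float = 0.05
    lam: float = 0.85
    seed: int = 0

    @property
    def block_size(self) -> int:
        return self.p // self.L

    @property
    def beta1(self) -> float:
        # var(beta1 * G_y gamma)/var(y) = causal_share*h2_y with var(G gamma)=h2_x
        return float(np.sqrt(self.causal_share * self.h2_y / self.h2_x))


@dataclass
class SimTruth:
    """Generator ground truth for downstream evaluation."""

    gamma: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    eta_true: np.ndarray          # per-block CHP labels
    beta1_true: float
    realized_h2: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh)


@dataclass
class SimulatedStudy:
    """Bundle of everything a fit needs plus the generating truth."""

    pairs: pd.DataFrame
    ld: list
    truth: SimTruth
    exposure: pd.DataFrame
    outcome: pd.DataFrame


def _variant_meta(p: int):
    ids = np.array([f"v{k:05d}" for k in range(p)])
    pos = 500 + 1000 * np.arange(p)
    return ids, pos


def simulate_genotypes(n: int, p: int, block_size: int, r: float,
                       maf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-latent genotype dosages {0,1,2}, blocks mutually independent.

    The latent Gaussian is cut at Phi^-1((1-f)^2) and Phi^-1(1-f^2) so the
    dosage categories have Hardy-Weinberg probabilities ((1-f)^2, 2f(1-f), f^2).
    """
    if not 0.0 <= r < 1.0:
        raise ConfigurationError(f"AR(1) correlation must be in [0, 1), got {r}")
    t0 = stats.norm.ppf((1.0 - maf) ** 2).astype(np.float32)
    t1 = stats.norm.ppf(1.0 - maf ** 2).astype(np.float32)
    G = np.empty((n, p), dtype=np.float32)
    s = np.float32(np.sqrt(1.0 - r * r))
    for start in range(0, p, block_size):
        m = min(block_size, p - start)
        eps = rng.standard_normal((n, m), dtype=np.float32)
        z = eps
        for k in range(1, m):
            z[:, k] = np.float32(r) * z[:, k - 1] + s * eps[:, k]
        cols = slice(start, start + m)
        np.add(z > t0[cols], z > t1[cols], out=G[:, cols], dtype=np.float32,
               casting="unsafe")
    return G


def gwas_scan(G: np.ndarray, trait: np.ndarray, variant_ids=None,
              pos=None) -> pd.DataFrame:
    """Per-variant simple linear regression of trait on dosage.

    Closed form: beta = cov(g, y)/var(g); se from the residual variance of
    the two-parameter fit with n-2 degrees of freedom.
    """
    G = np.asarray(G)
    y = np.asarray(trait, dtype=np.float64)
    n, p = G.shape
    if n < 10:
        raise ConfigurationError("need at least 10 samples for a scan")
    yc = y - y.mean()
    gm = G.mean(axis=0, dtype=np.float64)
    den = np.einsum("ij,ij->j", G, G, dtype=np.float64) - n * gm ** 2
    if (den <= 0).any():
        raise ConfigurationError("constant genotype column in scan input")
    if G.dtype == np.float32:
        num = (yc.astype(np.float32) @ G).astype(np.float64)
    else:
        num = yc @ G
    beta = num / den
    sst = float(yc @ yc)
    resid_var = np.maximum(sst / den - beta ** 2, 0.0) * den / (n - 2)
    se = np.sqrt(np.maximum(resid_var / den, 1e-300))
    if variant_ids is None:
        variant_ids, pos = _variant_meta(p)
    df = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": "1",
        "pos": pos,
        "effect_allele": "A",
        "other_allele": "G",
        "beta": beta,
        "se": se,
        "n": n,
    })
    df["z"] = df["beta"] / df["se"]
    return df


def _matvec(G: np.ndarray, v: np.ndarray) -> np.ndarray:
    """G @ v without upcasting a float32 genotype matrix to float64."""
    if G.dtype == np.float32:
        return (G @ v.astype(np.float32)).astype(np.float64)
    return G @ v


def _scale_to(component: np.ndarray, target_var: float):
    """Scale factor making the empirical variance of ``component`` hit target."""
    v = float(np.var(component))
    if target_var == 0.0 or v == 0.0:
        return 0.0
    return float(np.sqrt(target_var / v))


def simulate_effects(config: SimConfig, G_x: np.ndarray, G_y: np.ndarray,
                     rng: np.random.Generator) -> SimTruth:
    """Draw and empirically scale (gamma, alpha, theta); alpha block-aligned.

    Raw (gamma_k, alpha_k) are bivariate normal with correlation
    rho_alpha_gamma on the CHP support (whole blocks totalling
    round(chp_sparsity*p) instruments); gamma alone elsewhere; theta dense.
    Vectors are rescaled so realized variance fractions on the simulated
    genotypes hit the h2 targets (trait variances are brought to ~1 by the
    residuals downstream).
    """
    p, L, bs = config.p, config.L, config.block_size
    # whole-block support: round(chp_sparsity*L) blocks = round(chp_sparsity*p)
    # instruments when p is a multiple of L
    n_chp_blocks = int(round(config.chp_sparsity * L))
    if config.h2_alpha > 0 and n_chp_blocks == 0:
        raise ConfigurationError("chp_sparsity too small for this block count")

    eta_true = np.zeros(L, dtype=bool)
    if config.h2_alpha > 0 and n_chp_blocks > 0:
        eta_true[rng.choice(L, size=n_chp_blocks, replace=False)] = True
    support = np.repeat(eta_true, bs)

    rho = config.rho_alpha_gamma
    gamma = rng.standard_normal(p)
    alpha = np.zeros(p)
    if support.any():
        z = rng.standard_normal(int(support.sum()))
        alpha[support] = rho * gamma[support] + np.sqrt(1.0 - rho ** 2) * z
    theta = rng.standard_normal(p)

    gamma *= _scale_to(_matvec(G_x, gamma), config.h2_gamma)
    if support.any():
        alpha *= _scale_to(_matvec(G_y, alpha), config.h2_alpha)
    else:
        alpha[:] = 0.0
    theta *= _scale_to(_matvec(G_y, theta), config.h2_theta)
    return SimTruth(gamma, alpha, theta, eta_true, config.beta1)


def simulate_traits(config: SimConfig, truth: SimTruth, G_x: np.ndarray,
                    G_y: np.ndarray, rng: np.random.Generator):
    """Exposure in both cohorts and outcome in the outcome cohort.

    Confounder coefficient pairs (psi_xj, psi_yj) are i.i.d. bivariate
    normal with correlation ``psi_corr``, normalised by 1/sqrt(q) and then
    globally rescaled so the confounder component takes
    ``confounder_share`` of the non-genetic variance remainder; residuals
    bring each trait's total variance to ~1.
    """
    n_x, n_y, q = G_x.shape[0], G_y.shape[0], config.q
    c = config.psi_corr
    psi = rng.multivariate_normal([0, 0], [[1, c], [c, 1]], size=q) / np.sqrt(q)
    psi_x, psi_y = psi[:, 0], psi[:, 1]
    U_x = rng.standard_normal((n_x, q))
    U_y = rng.standard_normal((n_y, q))

    gx = _matvec(G_x, truth.gamma)
    gy = _matvec(G_y, truth.gamma)

    conf_x_target = config.confounder_share * max(1.0 - config.h2_gamma, 0.0)
    cx = _scale_to(U_x @ psi_x, conf_x_target)
    ux_x = cx * (U_x @ psi_x)
    ux_y = cx * (U_y @ psi_x)
    resid_x = max(1.0 - config.h2_gamma - conf_x_target, 1e-12)
    x_x = gx + ux_x + rng.standard_normal(n_x) * np.sqrt(resid_x)
    x_y = gy + ux_y + rng.standard_normal(n_y) * np.sqrt(resid_x)

    ay = _matvec(G_y, truth.alpha)
    ty = _matvec(G_y, truth.theta)
    signal = config.beta1 * x_y + ay + ty
    v_sig = float(np.var(signal))
    remainder = 1.0 - v_sig
    if remainder <= 0:
        raise ConfigurationError("infeasible outcome variance budget")
    conf_y_target = config.confounder_share * remainder
    cy = _scale_to(U_y @ psi_y, conf_y_target)
    # preserve corr(psi_x, psi_y): cohort-y confounder value uses the same U_y rows
    uy_y = cy * (U_y @ psi_y)
    resid_y = remainder - conf_y_target
    y = signal + uy_y + rng.standard_normal(n_y) * np.sqrt(resid_y)

    truth.realized_h2 = {
        "exposure_h2": float(np.var(gx) / np.var(x_x)),
        "uhp_h2": float(np.var(ty) / np.var(y)),
        "chp_h2": float(np.var(ay) / np.var(y)),
        "causal_share_outcome": float(np.var(config.beta1 * gy) / np.var(y)),
    }
    return x_x, x_y, y


def _pool_traits(config: SimConfig, truth: SimTruth, G: np.ndarray,
                 rng: np.random.Generator):
    """Exposure and outcome for every individual of a single pooled cohort."""
    n, q = G.shape[0], config.q
    c = config.psi_corr
    psi = rng.multivariate_normal([0, 0], [[1, c], [c, 1]], size=q) / np.sqrt(q)
    U = rng.standard_normal((n, q))
    gx = _matvec(G, truth.gamma)
    conf_x_target = config.confounder_share * max(1.0 - config.h2_gamma, 0.0)
    cx = _scale_to(U @ psi[:, 0], conf_x_target)
    resid_x = max(1.0 - config.h2_gamma - conf_x_target, 1e-12)
    x = gx + cx * (U @ psi[:, 0]) + rng.standard_normal(n) * np.sqrt(resid_x)
    signal = config.beta1 * x + _matvec(G, truth.alpha) + _matvec(G, truth.theta)
    remainder = 1.0 - float(np.var(signal))
    if remainder <= 0:
        raise ConfigurationError("infeasible outcome variance budget")
    conf_y_target = config.confounder_share * remainder
    cy = _scale_to(U @ psi[:, 1], conf_y_target)
    y = (signal + cy * (U @ psi[:, 1])
         + rng.standard_normal(n) * np.sqrt(remainder - conf_y_target))
    return x, y


def _reference_ld(G_r: np.ndarray, pairs: pd.DataFrame, lam: float) -> list[BlockLD]:
    out = []
    for b, sub in pairs.groupby("block_index", sort=True):
        idx = sub.index.to_numpy()
        R = shrink_corr(empirical_corr(G_r[:, idx]), lam)
        out.append(BlockLD(int(b), sub["variant_id"].tolist(), R, lam))
    return out


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """End-to-end standard scenario: genotypes, traits, scans, LD, truth."""
    rng = np.random.default_rng(config.seed)
    maf = rng.uniform(*config.maf_range, size=config.p)
    bs = config.block_size

    n_ov = int(round(config.overlap_frac * config.n_y))
    if n_ov == 0:
        G_x = simulate_genotypes(config.n_x, config.p, bs, config.r, maf, rng)
        G_y = simulate_genotypes(config.n_y, config.p, bs, config.r, maf, rng)
        truth = simulate_effects(config, G_x, G_y, rng)
        x_x, x_y, y = simulate_traits(config, truth, G_x, G_y, rng)
    else:
        # one pool; the exposure and outcome cohorts share n_ov individuals,
        # so the scan errors of the two traits become correlated (rho_e > 0)
        n_t = config.n_x + config.n_y - n_ov
        G = simulate_genotypes(n_t, config.p, bs, config.r, maf, rng)
        rows_x = slice(0, config.n_x)
        rows_y = slice(config.n_x - n_ov, n_t)
        truth = simulate_effects(config, G[rows_x], G[rows_y], rng)
        x_all, y_all = _pool_traits(config, truth, G, rng)
        G_x, x_x = G[rows_x], x_all[rows_x]
        G_y, y = G[rows_y], y_all[rows_y]
        truth.realized_h2 = {
            "exposure_h2": float(np.var(_matvec(G_x, truth.gamma)) / np.var(x_x)),
            "uhp_h2": float(np.var(_matvec(G_y, truth.theta)) / np.var(y)),
            "chp_h2": float(np.var(_matvec(G_y, truth.alpha)) / np.var(y)),
            "causal_share_outcome": float(
                np.var(config.beta1 * _matvec(G_y, truth.gamma)) / np.var(y)),
        }

    G_r = simulate_genotypes(config.n_r, config.p, bs, config.r, maf, rng)

    vids, pos = _variant_meta(config.p)
    exposure = gwas_scan(G_x, x_x, vids, pos)
    outcome = gwas_scan(G_y, y, vids, pos)

    pairs = pd.DataFrame({
        "variant_id": vids,
        "chrom": "1",
        "pos": pos,
        "effect_allele": "A",
        "other_allele": "G",
        "gamma_hat": exposure["beta"],
        "s_gamma": exposure["se"],
        "Gamma_hat": outcome["beta"],
        "s_Gamma": outcome["se"],
        "block_index": np.arange(config.p) // bs,
    })
    ld = _reference_ld(G_r, pairs, config.lam)
    return SimulatedStudy(pairs, ld, truth, exposure, outcome)


def simulate_reverse_scenario(config: ReverseConfig):
    """Reverse-causation design: returns both orientations plus truth.

    Trait A causes trait B (beta1 = sqrt(causal_share*h2_y/h2_x)).  The
    forward study treats A as exposure; the reverse study treats B as
    exposure with A as outcome (same scans, roles swapped).
    """
    rng = np.random.default_rng(config.seed)
    p, L, bs = config.p, config.L, config.block_size
    maf = rng.uniform(*config.maf_range, size=p)

    G_x = simulate_genotypes(config.n_x, p, bs, config.r, maf, rng)
    G_y = simulate_genotypes(config.n_y, p, bs, config.r, maf, rng)

    n_blocks = max(int(round(config.gamma_sparsity * L)), 1)
    sup_blocks = rng.choice(L, size=n_blocks, replace=False)
    support = np.zeros(p, dtype=bool)
    support[np.concatenate([np.arange(b * bs, (b + 1) * bs) for b in sup_blocks])] = True

    gamma = np.zeros(p)
    gamma[support] = rng.standard_normal(int(support.sum()))
    theta = rng.standard_normal(p)

    gamma *= _scale_to(_matvec(G_x, gamma), config.h2_x)
    theta *= _scale_to(_matvec(G_y, theta), config.h2_y * (1.0 - config.causal_share))

    beta1 = config.beta1
    resid_x = max(1.0 - config.h2_x, 1e-12)
    x_x = _matvec(G_x, gamma) + rng.standard_normal(config.n_x) * np.sqrt(resid_x)
    x_y = _matvec(G_y, gamma) + rng.standard_normal(config.n_y) * np.sqrt(resid_x)
    signal = beta1 * x_y + _matvec(G_y, theta)
    resid_y = 1.0 - float(np.var(signal))
    if resid_y <= 0:
        raise ConfigurationError("infeasible outcome variance budget")
    y = signal + rng.standard_normal(config.n_y) * np.sqrt(resid_y)

    G_r = simulate_genotypes(config.n_r, p, bs, config.r, maf, rng)
    vids, pos = _variant_meta(p)
    scan_a = gwas_scan(G_x, x_x, vids, pos)   # trait A (causal exposure)
    scan_b = gwas_scan(G_y, y, vids, pos)     # trait B (outcome)

    def _pairs(expo, outc):
        return pd.DataFrame({
            "variant_id": vids, "chrom": "1", "pos": pos,
            "effect_allele": "A", "other_allele": "G",
            "gamma_hat": expo["beta"], "s_gamma": expo["se"],
            "Gamma_hat": outc["beta"], "s_Gamma": outc["se"],
            "block_index": np.arange(p) // bs,
        })

    forward = _pairs(scan_a, scan_b)
    reverse = _pairs(scan_b, scan_a)
    ld = _reference_ld(G_r, forward, config.lam)

    truth = SimTruth(gamma, np.zeros(p), theta,
                     np.zeros(L, dtype=bool), beta1)
    gx = _matvec(G_x, gamma)
    gy = _matvec(G_y, gamma)
    truth.realized_h2 = {
        "exposure_h2": float(np.var(gx) / np.var(x_x)),
        "outcome_h2": float(np.var(beta1 * gy + _matvec(G_y, theta)) / np.var(y)),
        "causal_share_outcome": float(np.var(beta1 * gy) / np.var(y)),
    }
    truth.realized_h2["causal_share_of_h2y"] = (
        truth.realized_h2["causal_share_outcome"] / truth.realized_h2["outcome_h2"])
    return forward, reverse, ld, truth
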
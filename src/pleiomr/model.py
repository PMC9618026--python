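"""Bayesian hierarchical MR model with block-level correlated-pleiotropy labels.

The observed marginal effect estimates of p instruments on exposure and
outcome, (gamma_hat, Gamma_hat), are modelled jointly around latent true
marginal effects (gamma, Gamma) with a block-diagonal LD correlation R
and a 2x2 sample-overlap correlation R_e = [[1, rho_e], [rho_e, 1]]:

    (gamma_hat; Gamma_hat) ~ N( (S_g R S_g^-1 gamma ; S_G R S_G^-1 Gamma),
                                diag(S_g, S_G) (R_e (x) R) diag(S_g, S_G) ).

Each LD block l carries a latent label eta_l.  Within a no-pleiotropy
block (eta_l = 0) the outcome effects follow Gamma_lk ~ N(beta1*gamma_lk,
xi^2*tau1^2); within a correlated-pleiotropy block (eta_l = 1) they
follow N(beta2*gamma_lk, tau2^2) with beta2 = beta1 + delta absorbing the
confounding slope and tau2^2 > xi^2*tau1^2 absorbing the extra
instrument-specific pleiotropic variance.  beta1 is the causal effect of
interest, estimated from the blocks currently labelled clean; xi^2 is a
parameter-expansion scale that improves mixing in low signal-to-noise
regimes.  Conjugate priors: gamma_lk ~ N(0, sigma_gamma^2), inverse-gamma
on the variances, eta_l ~ Bernoulli(omega), omega ~ Beta(a, b) with the
sparse default (2, L), and Pr(xi^2) proportional to 1/xi^2.

All full conditionals are Gaussian / inverse-gamma / Beta / Bernoulli and
are derived in docs/methods.md; the Gibbs sampler updates, in order, the
per-block (gamma, Gamma) jointly, the block labels eta, beta1, beta2, the
variances, omega, and finally applies the label-identification rule
(swap the two components whenever tau2^2 < xi^2*tau1^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .io import ConfigurationError
from .ld import BlockLD, identity_ld, singleton_blocks

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10
_VAR_CAP = 1e6


# --------------------------------------------------------------------------
# hyperpriors and state containers

@dataclass
class Hyperpriors:
    """Inverse-gamma shape/scale pairs and the Beta prior for omega."""

    a_gamma: float = 1e-3
    b_gamma: float = 1e-3
    a_tau1: float = 1e-3
    b_tau1: float = 1e-3
    a_tau2: float = 1e-3
    b_tau2: float = 1e-3
    omega_prior_mode: str = "default"   # "default": Beta(2, L); "flat": Beta(1, 1)
    a_omega: float | None = None        # explicit override of the Beta parameters
    b_omega: float | None = None
    sigma_beta2: float = 100.0          # weak N(0, sigma_beta2) prior on beta1, beta2

    def omega_beta(self, L: int) -> tuple[float, float]:
        if self.a_omega is not None and self.b_omega is not None:
            return float(self.a_omega), float(self.b_omega)
        if self.omega_prior_mode == "flat":
            return 1.0, 1.0
        return 2.0, float(L)


@dataclass
class ModelState:
    """One Gibbs iteration's value of every latent quantity and parameter."""

    beta1: float
    beta2: float
    gamma: np.ndarray          # latent true marginal IV-to-exposure effects (p,)
    Gamma: np.ndarray          # latent true IV-to-outcome effects (p,)
    eta: np.ndarray            # block labels (L,), 0/1
    sigma_gamma2: float
    tau1_2: float
    tau2_2: float
    xi2: float
    omega: float
    rho_e: float
    relabel_count: int = 0


@dataclass
class PosteriorSummary:
    """MCMC-derived estimates and per-block pleiotropy probabilities."""

    beta1_hat: float
    beta1_sd: float
    beta1_ci: tuple
    p_value: float
    delta_hat: float
    pr_eta: np.ndarray
    chp_blocks: np.ndarray
    ess_beta1: float
    n_kept: int
    relabel_frac: float
    variant_ids: np.ndarray = None
    block_of_iv: np.ndarray = None
    chains: dict = field(default_factory=dict)


def decompose_chp(rho_alpha_gamma: float, sigma_alpha0: float,
                  sigma_gamma: float) -> tuple[float, float]:
    """Split a correlated pleiotropic effect into shared and specific parts.

    alpha_k = delta*gamma_k + alpha_tilde_k with delta =
    rho*sigma_alpha0/sigma_gamma and sd(alpha_tilde) =
    sqrt(1-rho^2)*sigma_alpha0.
    """
    if sigma_alpha0 <= 0 or sigma_gamma <= 0:
        raise ConfigurationError("scale parameters must be positive")
    if abs(rho_alpha_gamma) > 1:
        raise ConfigurationError("|rho| must be <= 1")
    delta = rho_alpha_gamma * sigma_alpha0 / sigma_gamma
    sigma_alpha_tilde = np.sqrt(1.0 - rho_alpha_gamma ** 2) * sigma_alpha0
    return float(delta), float(sigma_alpha_tilde)


# --------------------------------------------------------------------------
# block data preparation (stacked per block size for batched linear algebra)

def kron_precision(R: np.ndarray, rho_e: float) -> np.ndarray:
    """Precision contribution of one block's likelihood in z-score space.

    For z = (z_gamma; z_Gamma) ~ N((R u; R v), R_e (x) R) the posterior
    precision contribution of w = (u; v) is

        M' (R_e^-1 (x) R^-1) M = 1/(1-rho^2) [[R, -rho*R], [-rho*R, R]]

    with M = blockdiag(R, R); at rho_e = 0 this is blockdiag(R, R): the
    no-overlap model of the two independent multivariate likelihoods.
    """
    if not -1.0 < rho_e < 1.0:
        raise ConfigurationError(f"rho_e must be in (-1, 1), got {rho_e}")
    pre = 1.0 / (1.0 - rho_e ** 2)
    m = R.shape[0]
    Q = np.zeros((2 * m, 2 * m))
    Q[:m, :m] = pre * R
    Q[m:, m:] = pre * R
    Q[:m, m:] = -pre * rho_e * R
    Q[m:, :m] = -pre * rho_e * R
    return Q


class _SizeClass:
    """All blocks sharing one size, stacked for batched updates."""

    def __init__(self, m, block_ids, iv_idx, s_gamma, s_Gamma, R, rho_e,
                 z_gamma, z_Gamma):
        self.m = m
        self.block_ids = block_ids            # (B,)
        self.iv_idx = iv_idx                  # (B, m) into flat IV arrays
        self.s_gamma = s_gamma                # (B, m)
        self.s_Gamma = s_Gamma
        B = len(block_ids)
        pre = 1.0 / (1.0 - rho_e ** 2)
        self.Q = np.zeros((B, 2 * m, 2 * m))
        self.Q[:, :m, :m] = pre * R
        self.Q[:, m:, m:] = pre * R
        self.Q[:, :m, m:] = -pre * rho_e * R
        self.Q[:, m:, :m] = -pre * rho_e * R
        self.rhs = pre * np.concatenate(
            [z_gamma - rho_e * z_Gamma, z_Gamma - rho_e * z_gamma], axis=1)


class _BlockData:
    """Pairs + LD reorganised into stacked per-size-class arrays."""

    def __init__(self, pairs: pd.DataFrame, ld: list[BlockLD], rho_e: float):
        if not -1.0 < rho_e < 1.0:
            raise ConfigurationError(f"rho_e must be in (-1, 1), got {rho_e}")
        pairs = pairs.sort_values(["block_index"], kind="stable").reset_index(drop=True)
        self.pairs = pairs
        self.rho_e = float(rho_e)
        self.p = len(pairs)
        blocks = {int(b): sub.index.to_numpy()
                  for b, sub in pairs.groupby("block_index", sort=True)}
        self.block_labels = np.array(sorted(blocks))
        self.L = len(self.block_labels)
        ld_map = {int(blk.block_index): blk for blk in ld}
        missing = [b for b in blocks if b not in ld_map]
        if missing:
            raise ConfigurationError(f"blocks missing an LD matrix: {missing[:5]}")

        self.block_of_iv = np.empty(self.p, dtype=int)  # position in 0..L-1
        for j, b in enumerate(self.block_labels):
            self.block_of_iv[blocks[b]] = j

        self.gamma_hat = pairs["gamma_hat"].to_numpy(dtype=float)
        self.s_gamma_flat = pairs["s_gamma"].to_numpy(dtype=float)
        self.Gamma_hat = pairs["Gamma_hat"].to_numpy(dtype=float)
        self.s_Gamma_flat = pairs["s_Gamma"].to_numpy(dtype=float)
        if (self.s_gamma_flat <= 0).any() or (self.s_Gamma_flat <= 0).any():
            raise ConfigurationError("standard errors must be positive")
        zg = self.gamma_hat / self.s_gamma_flat
        zG = self.Gamma_hat / self.s_Gamma_flat

        by_size: dict[int, list] = {}
        for j, b in enumerate(self.block_labels):
            idx = blocks[b]
            R = ld_map[b].R
            if R.shape != (len(idx), len(idx)):
                raise ConfigurationError(
                    f"LD matrix of block {b} has shape {R.shape}, "
                    f"expected {(len(idx), len(idx))}")
            by_size.setdefault(len(idx), []).append((j, idx, R))

        self.classes = []
        for m in sorted(by_size):
            entries = by_size[m]
            bids = np.array([e[0] for e in entries])
            iv_idx = np.stack([e[1] for e in entries])
            R = np.stack([_chol_certify(e[2], e[0]) for e in entries])
            self.classes.append(_SizeClass(
                m, bids, iv_idx,
                self.s_gamma_flat[iv_idx], self.s_Gamma_flat[iv_idx],
                R, rho_e, zg[iv_idx], zG[iv_idx]))


def _chol_certify(R: np.ndarray, block: int) -> np.ndarray:
    """Positive-definiteness certificate, with a single jittered retry."""
    try:
        np.linalg.cholesky(R)
        return R
    except np.linalg.LinAlgError:
        Rj = R + 1e-8 * np.eye(R.shape[0])
        try:
            np.linalg.cholesky(Rj)
            logger.warning("block %d LD matrix jittered by 1e-8*I", block)
            return Rj
        except np.linalg.LinAlgError as e:
            raise ConfigurationError(
                f"block {block} LD matrix not positive definite") from e


# --------------------------------------------------------------------------
# Gibbs sampler

def init_state(data: _BlockData, hyper: Hyperpriors, rho_e: float,
               fixed: dict | None = None) -> ModelState:
    """Deterministic initialisation: latents at observed effects,
    variances from method-of-moments, labels all clean."""
    fixed = fixed or {}
    var_g = max(float(np.var(data.gamma_hat)) - float(np.mean(data.s_gamma_flat ** 2)), 1e-8)
    var_G = max(float(np.var(data.Gamma_hat)) - float(np.mean(data.s_Gamma_flat ** 2)), 1e-8)
    a_om, b_om = hyper.omega_beta(data.L)
    state = ModelState(
        beta1=0.0, beta2=0.0,
        gamma=data.gamma_hat.copy(), Gamma=data.Gamma_hat.copy(),
        eta=np.zeros(data.L, dtype=np.int8),
        sigma_gamma2=var_g, tau1_2=var_G, tau2_2=2.0 * var_G,
        xi2=1.0, omega=a_om / (a_om + b_om), rho_e=rho_e)
    for k, v in fixed.items():
        if not hasattr(state, k):
            raise ConfigurationError(f"unknown fixed parameter {k!r}")
        setattr(state, k, np.asarray(v) if k in ("eta",) else float(v))
    return state


def _class_precision(cls: _SizeClass, b_vec: np.ndarray, t2_vec: np.ndarray,
                     sigma_gamma2: float) -> np.ndarray:
    """Posterior precision of the stacked (u, v) = (gamma/s_g, Gamma/s_G).

    Likelihood part Q plus the Gaussian prior: u ~ N(0, sg2*S_g^-2) and
    v | u ~ N(b*S_G^-1*S_g*u, t2*S_G^-2).
    """
    m = cls.m
    P = cls.Q.copy()
    di = np.arange(m)
    P[:, di, di] += cls.s_gamma ** 2 * (
        1.0 / sigma_gamma2 + (b_vec ** 2 / t2_vec)[:, None])
    P[:, m + di, m + di] += cls.s_Gamma ** 2 / t2_vec[:, None]
    cross = -(b_vec / t2_vec)[:, None] * cls.s_gamma * cls.s_Gamma
    P[:, di, m + di] += cross
    P[:, m + di, di] += cross
    return P


def beta_conditional_moments(gamma: np.ndarray, Gamma: np.ndarray,
                             resid_var: float, sigma_beta2: float):
    """Normal full-conditional moments of a slope given its group's latents.

    Gamma_k ~ N(beta*gamma_k, resid_var) with prior beta ~ N(0, sigma_beta2);
    as resid_var -> 0 the mean tends to the weighted slope
    sum(gamma*Gamma)/sum(gamma^2) (the fixed-effect IVW form under equal
    outcome standard errors).
    """
    prec = float(gamma @ gamma) / resid_var + 1.0 / sigma_beta2
    mean = (float(gamma @ Gamma) / resid_var) / prec
    return mean, 1.0 / prec


def _sample_invgamma(rng, shape, scale):
    """One inverse-gamma draw, clamped to a numerically safe range."""
    g = rng.gamma(shape)
    return float(np.clip(scale / max(g, 1e-300), _VAR_FLOOR, _VAR_CAP))


def gibbs_sweep(state: ModelState, data: _BlockData, hyper: Hyperpriors,
                rng: np.random.Generator, fixed: frozenset = frozenset(),
                relabel_enabled: bool = True) -> ModelState:
    """One full-conditional sweep over every latent quantity (in place)."""
    eta = state.eta
    b1, b2 = state.beta1, state.beta2
    var0 = state.xi2 * state.tau1_2          # eta=0 residual variance
    var1 = state.tau2_2

    # ---- per-block (gamma, Gamma) joint multivariate-normal update
    for cls in data.classes:
        m, B = cls.m, len(cls.block_ids)
        e = eta[cls.block_ids].astype(bool)
        b_vec = np.where(e, b2, b1)
        t2_vec = np.where(e, var1, var0)
        P = _class_precision(cls, b_vec, t2_vec, state.sigma_gamma2)
        try:
            Lc = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            P[:, np.arange(2 * m), np.arange(2 * m)] += 1e-8
            Lc = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, cls.rhs[..., None])[..., 0]
        z = rng.standard_normal((B, 2 * m))
        noise = np.linalg.solve(np.swapaxes(Lc, 1, 2), z[..., None])[..., 0]
        w = mean + noise
        state.gamma[cls.iv_idx] = cls.s_gamma * w[:, :m]
        state.Gamma[cls.iv_idx] = cls.s_Gamma * w[:, m:]

    # ---- block labels eta (Bernoulli)
    if "eta" not in fixed:
        logodds = np.full(data.L, np.log(state.omega) - np.log1p(-state.omega))
        for cls in data.classes:
            g = state.gamma[cls.iv_idx]
            G = state.Gamma[cls.iv_idx]
            r1 = G - b1 * g
            r2 = G - b2 * g
            ll0 = -0.5 * (cls.m * np.log(2 * np.pi * var0)
                          + (r1 ** 2).sum(axis=1) / var0)
            ll1 = -0.5 * (cls.m * np.log(2 * np.pi * var1)
                          + (r2 ** 2).sum(axis=1) / var1)
            logodds[cls.block_ids] += ll1 - ll0
        state.eta = (rng.random(data.L) < expit(logodds)).astype(np.int8)

    eta_iv = state.eta[data.block_of_iv].astype(bool)
    g0, G0 = state.gamma[~eta_iv], state.Gamma[~eta_iv]
    g1, G1 = state.gamma[eta_iv], state.Gamma[eta_iv]

    # ---- beta1 from clean blocks, beta2 from pleiotropic blocks (normal)
    if "beta1" not in fixed:
        mean, var = beta_conditional_moments(
            g0, G0, state.xi2 * state.tau1_2, hyper.sigma_beta2)
        state.beta1 = mean + rng.standard_normal() * np.sqrt(var)
    if "beta2" not in fixed:
        mean, var = beta_conditional_moments(
            g1, G1, state.tau2_2, hyper.sigma_beta2)
        state.beta2 = mean + rng.standard_normal() * np.sqrt(var)

    # ---- variances (inverse-gamma) and omega (Beta)
    n0, n1 = len(g0), len(g1)
    ssr0 = float(np.sum((G0 - state.beta1 * g0) ** 2))
    ssr1 = float(np.sum((G1 - state.beta2 * g1) ** 2))
    if "tau1_2" not in fixed:
        state.tau1_2 = _sample_invgamma(
            rng, hyper.a_tau1 + 0.5 * n0,
            hyper.b_tau1 + 0.5 * ssr0 / state.xi2)
    if "tau2_2" not in fixed:
        state.tau2_2 = _sample_invgamma(
            rng, hyper.a_tau2 + 0.5 * n1, hyper.b_tau2 + 0.5 * ssr1)
    if "sigma_gamma2" not in fixed:
        state.sigma_gamma2 = _sample_invgamma(
            rng, hyper.a_gamma + 0.5 * data.p,
            hyper.b_gamma + 0.5 * float(state.gamma @ state.gamma))
    if "xi2" not in fixed and n0 > 0:
        # improper prior Pr(xi^2) ~ 1/xi^2 gives IG(n0/2, ssr0/(2*tau1^2))
        state.xi2 = _sample_invgamma(rng, 0.5 * n0, 0.5 * ssr0 / state.tau1_2)
    if "omega" not in fixed:
        a_om, b_om = hyper.omega_beta(data.L)
        k = int(state.eta.sum())
        state.omega = float(np.clip(
            rng.beta(a_om + k, b_om + data.L - k), 1e-12, 1 - 1e-12))

    if relabel_enabled:
        relabel(state)
    return state


def relabel(state: ModelState) -> ModelState:
    """Label-identification: the high-variance component is the pleiotropic one.

    If tau2^2 < xi^2*tau1^2 the two mixture components have swapped roles;
    exchange (beta1, beta2), move xi^2*tau1^2 <-> tau2^2 (resetting xi^2 to 1),
    complement every block label and map omega to 1-omega.
    """
    if state.tau2_2 < state.xi2 * state.tau1_2:
        state.beta1, state.beta2 = state.beta2, state.beta1
        old_var0 = state.xi2 * state.tau1_2
        state.tau1_2 = state.tau2_2
        state.tau2_2 = old_var0
        state.xi2 = 1.0
        state.eta = (1 - state.eta).astype(np.int8)
        state.omega = 1.0 - state.omega
        state.relabel_count += 1
    return state


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    s = 0.0
    for k in range(1, n):
        if acf[k] + (acf[k + 1] if k + 1 < n else 0.0) < 0:
            break
        s += acf[k]
    return float(np.clip(n / (1.0 + 2.0 * s), 1.0, n))


def run_mcmc(pairs: pd.DataFrame, ld: list[BlockLD],
             hyper: Hyperpriors | None = None, rho_e: float = 0.0,
             n_iter: int = 5000, burn_in: int = 2000, thin: int = 1,
             seed: int | None = None, fixed: dict | None = None,
             relabel_enabled: bool = True,
             chp_threshold: float = 0.8) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise the posterior.

    ``fixed`` pins parameters (by ModelState field name) at given values
    and skips their updates; used for oracle checks and degenerate runs.
    """
    if not (n_iter > burn_in >= 0):
        raise ConfigurationError("need n_iter > burn_in >= 0")
    hyper = hyper or Hyperpriors()
    data = _BlockData(pairs, ld, rho_e)
    state = init_state(data, hyper, rho_e, fixed)
    fixed_keys = frozenset((fixed or {}).keys())
    rng = np.random.default_rng(seed)

    n_kept = (n_iter - burn_in + thin - 1) // thin
    chains = {k: np.empty(n_kept) for k in
              ("beta1", "beta2", "tau1_2", "tau2_2", "sigma_gamma2",
               "xi2", "omega")}
    eta_sum = np.zeros(data.L)
    kept = 0
    relabels_before = 0
    for it in range(n_iter):
        gibbs_sweep(state, data, hyper, rng, fixed_keys, relabel_enabled)
        if not np.isfinite(state.beta1):
            raise RuntimeError(f"non-finite chain value at iteration {it}")
        if (it + 1) % 1000 == 0:
            logger.debug("iteration %d/%d: beta1=%.4f, %d pleiotropic block(s), "
                         "%d relabel(s)", it + 1, n_iter, state.beta1,
                         int(state.eta.sum()), state.relabel_count)
        if it == burn_in - 1:
            relabels_before = state.relabel_count
        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in chains:
                chains[k][kept] = getattr(state, k)
            eta_sum += state.eta
            kept += 1

    b1 = chains["beta1"]
    beta1_hat = float(b1.mean())
    beta1_sd = float(b1.std(ddof=1))
    ci = tuple(np.percentile(b1, [2.5, 97.5]))
    p_value = float(2.0 * stats.norm.sf(abs(beta1_hat) / max(beta1_sd, 1e-300)))
    pr_eta = eta_sum / kept
    summary = PosteriorSummary(
        beta1_hat=beta1_hat, beta1_sd=beta1_sd, beta1_ci=ci, p_value=p_value,
        delta_hat=float((chains["beta2"] - b1).mean()),
        pr_eta=pr_eta,
        chp_blocks=np.where(pr_eta > chp_threshold)[0],
        ess_beta1=_ess(b1), n_kept=kept,
        relabel_frac=(state.relabel_count - relabels_before) / max(n_iter - burn_in, 1),
        variant_ids=data.pairs["variant_id"].to_numpy(),
        block_of_iv=data.block_of_iv,
        chains=chains)
    logger.info("MCMC done: beta1=%.4f (sd %.4f), ESS %.0f, relabel frac %.3f",
                beta1_hat, beta1_sd, summary.ess_beta1, summary.relabel_frac)
    return summary


def fit_independent(pairs: pd.DataFrame, hyper: Hyperpriors | None = None,
                    seed: int | None = None, **kwargs) -> PosteriorSummary:
    """Independent-instrument analysis: identity LD, one IV per block, rho_e=0.

    Exactly :func:`run_mcmc` on singleton blocks; the per-IV label eta_k
    is recovered as the block-size-1 special case.
    """
    single = singleton_blocks(pairs)
    return run_mcmc(single, identity_ld(single), hyper=hyper, rho_e=0.0,
                    seed=seed, **kwargs)


def classify_chp(summary: PosteriorSummary, threshold: float = 0.8):
    """Blocks called pleiotropic at Pr(eta_l=1 | data) > threshold.

    Returns (block indices, per-IV DataFrame); the per-IV pleiotropy
    strength is -log10(1 - Pr) of the instrument's block, capped at 16.
    """
    blocks = np.where(summary.pr_eta > threshold)[0]
    pr_iv = summary.pr_eta[summary.block_of_iv]
    strength = np.minimum(-np.log10(np.maximum(1.0 - pr_iv, 1e-16)), 16.0)
    table = pd.DataFrame({
        "variant_id": summary.variant_ids,
        "block_index": summary.block_of_iv,
        "pr_eta": pr_iv,
        "chp_strength": strength,
        "is_chp": pr_iv > threshold,
    })
    return blocks, table


# --------------------------------------------------------------------------
# estimator facade

class CorrelatedPleiotropyMR(BaseEstimator):
    """Two-sample MR estimator with block-level pleiotropy classification.

    Parameters follow the sampler defaults; ``fit`` takes a harmonized
    pair table (one row per instrument, ``block_index`` assigned) and an
    optional list of per-block LD matrices (identity LD when omitted).

    Attributes (after fit): ``beta1_``, ``beta1_sd_``, ``beta1_ci_``,
    ``p_value_``, ``delta_``, ``pr_eta_``, ``chp_blocks_``, ``summary_``.
    """

    def __init__(self, n_iter: int = 5000, burn_in: int = 2000, thin: int = 1,
                 rho_e: float = 0.0, omega_prior: str = "default",
                 chp_threshold: float = 0.8,
                 hyper: Hyperpriors | None = None,
                 random_state: int | None = None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.rho_e = rho_e
        self.omega_prior = omega_prior
        self.chp_threshold = chp_threshold
        self.hyper = hyper
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, ld: list[BlockLD] | None = None):
        hyper = self.hyper or Hyperpriors(omega_prior_mode=self.omega_prior)
        if ld is None:
            ld = identity_ld(X)
        summary = run_mcmc(X, ld, hyper=hyper, rho_e=self.rho_e,
                           n_iter=self.n_iter, burn_in=self.burn_in,
                           thin=self.thin, seed=self.random_state,
                           chp_threshold=self.chp_threshold)
        self.summary_ = summary
        self.beta1_ = summary.beta1_hat
        self.beta1_sd_ = summary.beta1_sd
        self.beta1_ci_ = summary.beta1_ci
        self.p_value_ = summary.p_value
        self.delta_ = summary.delta_hat
        self.pr_eta_ = summary.pr_eta
        self.chp_blocks_ = summary.chp_blocks
        return self
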
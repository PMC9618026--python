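"""Desk-scale simulation experiments: calibration, power, discovery FDR, ROC.

Each experiment simulates replicate GWAS studies with the generator,
fits the model, and aggregates decision rates with binomial uncertainty.
Replicates use disjoint seed streams spawned from one root seed so every
cell is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import InputError
from .model import CorrelatedPleiotropyMR, Hyperpriors, run_mcmc
from .simulate import SimConfig, ReverseConfig, simulate_study, simulate_reverse_scenario


@dataclass
class ExperimentGrid:
    """Scenario sweep for type-I / power experiments."""

    base: SimConfig = field(default_factory=SimConfig)
    beta1_values: tuple = (0.0, 0.1)
    n_reps: int = 50
    alpha_level: float = 0.05
    n_iter: int = 2000
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise InputError("n_reps must be >= 1")
        if not 0.0 < self.alpha_level <= 1.0:
            raise InputError("alpha_level must be in (0, 1]")


def _binomial_ci(k: int, n: int) -> tuple:
    lo, hi = stats.binom.interval(0.95, n, max(k, 1e-9) / n)
    return (lo / n, hi / n)


def _replicate_seeds(root: int, n: int, stream: int) -> list[int]:
    """Disjoint per-replicate seeds; separate streams never collide."""
    ss = np.random.SeedSequence([root, stream])
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_type1_power(grid: ExperimentGrid, fit_kwargs: dict | None = None) -> dict:
    """Rejection rate per beta1 cell: type-I error when beta1=0, else power."""
    fit_kwargs = fit_kwargs or {}
    report = {"alpha_level": grid.alpha_level, "n_reps": grid.n_reps,
              "cells": [], "failures": 0}
    for stream, beta1 in enumerate(grid.beta1_values):
        seeds = _replicate_seeds(grid.seed, grid.n_reps, stream)
        pvals, estimates = [], []
        for s in seeds:
            cfg_kw = {**asdict(grid.base), "beta1": beta1, "seed": s}
            cfg_kw["maf_range"] = tuple(cfg_kw["maf_range"])
            try:
                study = simulate_study(SimConfig(**cfg_kw))
                fit = run_mcmc(study.pairs, study.ld, n_iter=grid.n_iter,
                               burn_in=grid.burn_in, seed=s, **fit_kwargs)
            except Exception:  # replicate failure: logged, excluded, counted
                report["failures"] += 1
                continue
            pvals.append(fit.p_value)
            estimates.append(fit.beta1_hat)
        pvals = np.array(pvals)
        k = int((pvals < grid.alpha_level).sum())
        rate = k / len(pvals)
        report["cells"].append({
            "beta1": beta1,
            "kind": "type1" if beta1 == 0 else "power",
            "rate": rate,
            "rate_ci": _binomial_ci(k, len(pvals)),
            "mean_estimate": float(np.mean(estimates)),
            "pvalues": pvals.tolist(),
        })
    return report


def bayesian_fdr(pr_eta, level: float = 0.1):
    """Posterior-probability discovery set controlling the Bayesian FDR.

    Sort blocks by descending Pr(eta=1); include greedily while the
    running mean of (1 - Pr) over the included set stays <= level.  The
    running mean is the estimated false discovery proportion of the set,
    so the estimator never exceeds the level by construction.

    Returns (selected block indices, estimated FDR of the set).
    """
    pr = np.asarray(pr_eta, dtype=float)
    if ((pr < 0) | (pr > 1)).any():
        raise InputError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-pr, kind="stable")
    run = np.cumsum(1.0 - pr[order]) / np.arange(1, len(pr) + 1)
    ok = np.where(run <= level)[0]
    if len(ok) == 0:
        return np.array([], dtype=int), 0.0
    k = ok.max() + 1
    return np.sort(order[:k]), float(run[k - 1])


def empirical_fdp(selected: np.ndarray, eta_true: np.ndarray) -> float:
    """Realized false discovery proportion against truth labels (0 if empty)."""
    if len(selected) == 0:
        return 0.0
    return float((~np.asarray(eta_true, dtype=bool)[selected]).mean())


def run_reverse_roc(config: ReverseConfig, n_reps: int = 20,
                    n_iter: int = 2000, burn_in: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Causal-direction ROC on the reverse-causation design.

    Per replicate, fit the forward (truly causal) and reverse orientation;
    the ROC traces, over a p-value threshold sweep, the fraction of
    forward fits rejected (true positives) against reverse fits rejected
    (false positives).
    """
    seeds = _replicate_seeds(seed, n_reps, 7)
    p_fwd, p_rev = [], []
    for s in seeds:
        kw = asdict(config)
        kw["seed"] = s
        kw["maf_range"] = tuple(kw["maf_range"])
        fwd, rev, ld, _ = simulate_reverse_scenario(ReverseConfig(**kw))
        fit_f = run_mcmc(fwd, ld, n_iter=n_iter, burn_in=burn_in, seed=s)
        fit_r = run_mcmc(rev, ld, n_iter=n_iter, burn_in=burn_in, seed=s + 1)
        p_fwd.append(fit_f.p_value)
        p_rev.append(fit_r.p_value)
    p_fwd, p_rev = np.array(p_fwd), np.array(p_rev)
    thresholds = np.unique(np.concatenate([[0.0], p_fwd, p_rev, [1.0]]))
    rows = [{"threshold": float(t),
             "tpr": float((p_fwd <= t).mean()),
             "fpr": float((p_rev <= t).mean())} for t in thresholds]
    df = pd.DataFrame(rows)
    df.attrs["p_forward"] = p_fwd
    df.attrs["p_reverse"] = p_rev
    # Mann-Whitney AUC: probability a forward p-value beats a reverse one
    df.attrs["auc"] = float(
        (p_fwd[:, None] < p_rev[None, :]).mean()
        + 0.5 * (p_fwd[:, None] == p_rev[None, :]).mean())
    return df


def ivw_baseline(pairs: pd.DataFrame):
    """Fixed-effect inverse-variance-weighted estimate (independent IVs).

    beta = sum(g*G/sG^2)/sum(g^2/sG^2), se = 1/sqrt(sum(g^2/sG^2)).
    """
    if len(pairs) < 2:
        raise InputError("IVW needs at least 2 instruments")
    g = pairs["gamma_hat"].to_numpy(dtype=float)
    G = pairs["Gamma_hat"].to_numpy(dtype=float)
    w = 1.0 / pairs["s_Gamma"].to_numpy(dtype=float) ** 2
    denom = float(np.sum(g * g * w))
    beta = float(np.sum(g * G * w)) / denom
    se = 1.0 / np.sqrt(denom)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


class InverseVarianceWeightedMR(BaseEstimator):
    """Fixed-effect IVW comparator with the same fit surface as the main model."""

    def fit(self, X: pd.DataFrame, y=None):
        self.beta_, self.se_, self.p_value_ = ivw_baseline(X)
        return self
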
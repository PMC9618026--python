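"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR takes two tables of per-variant marginal effect estimates:
one for the exposure trait (gamma_hat, s_gamma) and one for the outcome
(Gamma_hat, s_Gamma).  Before any modelling the tables must be aligned to
a common effect allele, pruned of ambiguous (palindromic) variants, and
restricted to instruments passing an exposure-association threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column names of a validated summary table
SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta", "se", "n", "z"]

#: fixed column order of a harmonized pair table
PAIR_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "gamma_hat", "s_gamma", "Gamma_hat", "s_Gamma", "block_index"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InputError(ValueError):
    """Invalid or empty input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, bad parameter values)."""


@dataclass(frozen=True)
class OverlapEstimate:
    """Correlation of summary-statistic errors induced by overlapping GWAS samples."""

    rho_e: float
    n_null_variants: int


def read_summary(path, column_map: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read and validate one GWAS summary-statistics table.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header; gzip handled transparently.
    column_map : dict, optional
        Maps canonical names (``variant_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``n``)
        to the file's column names.
    sep : str, optional
        Field separator; autodetected when omitted.

    Returns
    -------
    pandas.DataFrame
        Validated table with canonical columns plus ``z = beta/se``.
        Rows with missing/non-finite beta or se, or se <= 0, are dropped
        (logged).  Duplicate variant ids keep the smallest exposure p-value.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")
    if "n" not in df.columns:
        df["n"] = np.nan

    df = df[mandatory + ["n"]].copy()
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    n0 = len(df)
    keep = np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
    df = df.loc[keep].copy()
    if n0 - len(df):
        logger.info("dropped %d rows with missing/invalid beta or se", n0 - len(df))
    if df.empty:
        raise InputError("no valid rows in summary table")

    df["z"] = df["beta"] / df["se"]
    dups = df["variant_id"].duplicated(keep=False)
    if dups.any():
        # keep the record with the larger |z| (smaller exposure p-value)
        df = (df.assign(_absz=df["z"].abs())
                .sort_values("_absz", ascending=False)
                .drop_duplicates("variant_id")
                .drop(columns="_absz"))
        logger.info("resolved duplicate variant ids, kept most significant record")
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_summary(df: pd.DataFrame, path) -> None:
    """Write a validated summary table as TSV (round-trips with read_summary)."""
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a1.map(_COMPLEMENT).fillna("?") == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic: bool = True) -> pd.DataFrame:
    """Align two summary tables to the exposure's effect allele.

    Resolves the four allele-matching cases (same, swapped, strand-flipped,
    strand-flipped + swapped); swapped cases flip the sign of the outcome
    effect.  Palindromic variants (A/T, C/G) are dropped by default since
    strand cannot be resolved without allele frequencies.  Variants whose
    alleles cannot be matched under any of the four cases are dropped.

    Returns the harmonized pair table (``block_index`` initialised to -1).
    """
    m = exposure.merge(outcome, on="variant_id", suffixes=("_x", "_y"))
    if m.empty:
        raise InputError("no shared variants between exposure and outcome tables")

    a1, a2 = m["effect_allele_x"], m["other_allele_x"]
    b1, b2 = m["effect_allele_y"], m["other_allele_y"]
    c1, c2 = b1.map(_COMPLEMENT).fillna("?"), b2.map(_COMPLEMENT).fillna("?")

    same = (b1 == a1) & (b2 == a2)
    swap = (b1 == a2) & (b2 == a1)
    flip_same = (c1 == a1) & (c2 == a2)
    flip_swap = (c1 == a2) & (c2 == a1)

    matched = same | swap | flip_same | flip_swap
    sign = np.where(swap | (flip_swap & ~same), -1.0, 1.0)

    if drop_palindromic:
        matched &= ~_is_palindromic(a1, a2)

    n_drop = int((~matched).sum())
    if n_drop:
        logger.info("harmonize: dropped %d unmatched/palindromic variants", n_drop)

    out = pd.DataFrame({
        "variant_id": m["variant_id"],
        "chrom": m["chrom_x"].astype(str),
        "pos": m["pos_x"],
        "effect_allele": a1,
        "other_allele": a2,
        "gamma_hat": m["beta_x"],
        "s_gamma": m["se_x"],
        "Gamma_hat": sign * m["beta_y"],
        "s_Gamma": m["se_y"],
        "block_index": -1,
    }).loc[matched].reset_index(drop=True)
    if out.empty:
        raise InputError("no variants survived harmonization")
    return out


def select_ivs(pairs: pd.DataFrame, p_threshold: float = 5e-4) -> pd.DataFrame:
    """Retain instruments whose exposure association passes ``p_threshold``.

    Two-sided normal p-value 2*Phi(-|gamma_hat/s_gamma|) <= p_threshold.
    """
    z = np.abs(pairs["gamma_hat"] / pairs["s_gamma"])
    pval = 2.0 * stats.norm.sf(z)
    kept = pairs.loc[pval <= p_threshold].reset_index(drop=True)
    if kept.empty:
        raise InputError(f"no instruments pass the exposure p-value threshold {p_threshold}")
    return kept


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write a harmonized pair table as TSV with the fixed column order."""
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    """Read a harmonized pair table written by :func:`write_pairs`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"pair table missing column(s): {missing}")
    return df


def estimate_overlap_rho(exposure: pd.DataFrame, outcome: pd.DataFrame,
                         z_null_max: float = 2.0,
                         partition=None,
                         min_null: int = 100) -> OverlapEstimate:
    """Estimate the sample-overlap correlation rho_e from null variants.

    Pearson correlation of the two traits' z-scores over shared variants
    with |z| < ``z_null_max`` in *both* traits (variants with no detectable
    association to either trait), pruned to at most one variant per LD
    block when a :class:`~pleiomr.ld.BlockPartition` is supplied.  Fewer
    than ``min_null`` null variants triggers a warning and a rho_e = 0
    fallback.  Symmetric in its two arguments.
    """
    m = exposure.merge(outcome, on="variant_id", suffixes=("_x", "_y"))
    null = m.loc[(m["z_x"].abs() < z_null_max) & (m["z_y"].abs() < z_null_max)]
    if partition is not None and not null.empty:
        blocks = partition.assign(null["chrom_x"].astype(str).to_numpy(),
                                  null["pos_x"].to_numpy())
        null = null.loc[~pd.Series(blocks, index=null.index).duplicated()]
    n = len(null)
    if n < min_null:
        logger.warning("only %d null variants (<%d); falling back to rho_e = 0",
                       n, min_null)
        return OverlapEstimate(0.0, n)
    rho = float(np.corrcoef(null["z_x"], null["z_y"])[0, 1])
    return OverlapEstimate(float(np.clip(rho, -1.0, 1.0)), n)
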
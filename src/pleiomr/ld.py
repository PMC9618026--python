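"""LD blocks and per-block shrinkage correlation matrices.

Instruments are partitioned into approximately independent genomic blocks
(LDetect-style intervals, BED dialect: 0-based half-open).  Within each
block the correlation matrix of the instruments is estimated from a
reference panel of genotype dosages and regularised with a convex
shrinkage towards the identity,

    R_hat = lambda * R_emp + (1 - lambda) * I,

which guarantees eigenvalues >= 1 - lambda for lambda < 1.  The full
genome-wide matrix is never materialised: all downstream algebra is
block-diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockPartition:
    """Ordered, non-overlapping genomic intervals (chrom, start, end)."""

    intervals: pd.DataFrame  # columns chrom, start, end; sorted

    def __len__(self) -> int:
        return len(self.intervals)

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map positions to interval indices (half-open [start, end)).

        A position outside every interval on its chromosome is assigned
        to the nearest interval (distance to the closest edge) and logged.
        Positions on chromosomes absent from the partition raise InputError.
        """
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        out = np.full(len(pos), -1, dtype=int)
        n_outside = 0
        for c, sub in self.intervals.groupby("chrom", sort=False):
            mask = chrom == str(c)
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = sub.index.to_numpy()
            p = pos[mask]
            j = np.searchsorted(starts, p, side="right") - 1
            inside = (j >= 0) & (p < ends[np.clip(j, 0, None)])
            res = np.empty(len(p), dtype=int)
            res[inside] = idx[j[inside]]
            if (~inside).any():
                # nearest interval by edge distance
                for i in np.where(~inside)[0]:
                    d = np.where(p[i] < starts, starts - p[i],
                                 np.where(p[i] >= ends, p[i] - ends + 1, 0))
                    res[i] = idx[int(np.argmin(d))]
                n_outside += int((~inside).sum())
            out[mask] = res
        if (out < 0).any():
            bad = set(np.unique(chrom[out < 0]))
            raise InputError(f"chromosome(s) {sorted(bad)} absent from block partition")
        if n_outside:
            logger.info("%d variants outside all intervals assigned to nearest block",
                        n_outside)
        return out


@dataclass
class BlockLD:
    """Shrunk correlation matrix for the instruments of one block."""

    block_index: int
    variant_ids: list = field(default_factory=list)
    R: np.ndarray = None
    lam: float = 0.85

    def __post_init__(self):
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=float)


def read_blocks(path) -> BlockPartition:
    """Read a 3-column interval file (chrom, start, end), header optional."""
    first = pd.read_csv(path, sep=r"\s+", nrows=1, header=None)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None,
                     usecols=[0, 1, 2])
    df.columns = ["chrom", "start", "end"]
    if df.empty:
        raise InputError("empty block file")
    df["chrom"] = df["chrom"].astype(str)
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    for c, sub in df.groupby("chrom"):
        bad = sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]
        if bad.any():
            i = int(np.argmax(bad))
            raise InputError(
                f"overlapping intervals on chromosome {c}: "
                f"{tuple(sub.iloc[i][['start', 'end']])} and "
                f"{tuple(sub.iloc[i + 1][['start', 'end']])}")
    return BlockPartition(df)


def assign_blocks(pairs: pd.DataFrame, partition: BlockPartition) -> pd.DataFrame:
    """Populate ``block_index`` (contiguous 0..L-1 over non-empty blocks).

    Instruments are position-sorted within blocks; empty blocks are removed.
    """
    pairs = pairs.sort_values(["chrom", "pos"]).reset_index(drop=True)
    raw = partition.assign(pairs["chrom"].to_numpy(dtype=str),
                           pairs["pos"].to_numpy())
    pairs = pairs.copy()
    codes, _ = pd.factorize(raw, sort=True)
    pairs["block_index"] = codes
    return pairs.sort_values(["block_index", "pos"]).reset_index(drop=True)


def empirical_corr(genotypes: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of dosage columns (n_samples x p_l)."""
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise InputError("need a 2-d genotype matrix with >= 2 samples")
    sd = g.std(axis=0)
    if (sd == 0).any():
        k = int(np.argmax(sd == 0))
        raise InputError(f"constant genotype column at index {k}")
    return np.corrcoef(g, rowvar=False).reshape(g.shape[1], g.shape[1])


def shrink_corr(R_emp: np.ndarray, lam: float = 0.85) -> np.ndarray:
    """Shrink a correlation matrix towards the identity: lam*R + (1-lam)*I."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError(f"shrinkage weight must be in [0, 1], got {lam}")
    R_emp = np.asarray(R_emp, dtype=float)
    return lam * R_emp + (1.0 - lam) * np.eye(R_emp.shape[0])


def blocks_from_reference(pairs: pd.DataFrame, dosages: pd.DataFrame,
                          lam: float = 0.85) -> list[BlockLD]:
    """Build per-block shrunk LD matrices from reference dosages.

    ``dosages``: DataFrame of reference genotypes keyed by variant_id
    (columns = variants).  Instruments absent from the reference are not
    allowed here; drop them upstream (logged).
    """
    out = []
    for b, sub in pairs.groupby("block_index", sort=True):
        vids = sub["variant_id"].tolist()
        missing = [v for v in vids if v not in dosages.columns]
        if missing:
            raise InputError(f"variants missing from reference panel: {missing[:5]}")
        g = dosages[vids].to_numpy()
        out.append(BlockLD(int(b), vids, shrink_corr(empirical_corr(g), lam), lam))
    return out


def read_precomputed_ld(path, pairs: pd.DataFrame) -> list[BlockLD]:
    """Load precomputed per-block correlation matrices from JSON.

    Format: {"<block_index>": {"variant_ids": [...], "R": [[...], ...]}}.
    Matrices are reordered to match the pair table's within-block variant
    order; blocks present in the pairs but absent from the file raise.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for b, sub in pairs.groupby("block_index", sort=True):
        key = str(int(b))
        if key not in raw:
            raise InputError(f"block {b} missing from precomputed LD file")
        entry = raw[key]
        order = {v: i for i, v in enumerate(entry["variant_ids"])}
        vids = sub["variant_id"].tolist()
        missing = [v for v in vids if v not in order]
        if missing:
            raise InputError(f"variants missing from precomputed LD for "
                             f"block {b}: {missing[:5]}")
        idx = [order[v] for v in vids]
        R = np.asarray(entry["R"], dtype=float)[np.ix_(idx, idx)]
        out.append(BlockLD(int(b), vids, R, float(entry.get("lambda", 1.0))))
    return out


def write_precomputed_ld(ld: list[BlockLD], path) -> None:
    """Serialise per-block LD matrices to the JSON format of
    :func:`read_precomputed_ld`."""
    import json

    raw = {str(b.block_index): {"variant_ids": list(b.variant_ids),
                                "R": b.R.tolist(), "lambda": b.lam}
           for b in ld}
    with open(path, "w") as fh:
        json.dump(raw, fh)


def identity_ld(pairs: pd.DataFrame) -> list[BlockLD]:
    """Identity LD per block (independent-instrument analysis)."""
    out = []
    for b, sub in pairs.groupby("block_index", sort=True):
        vids = sub["variant_id"].tolist()
        out.append(BlockLD(int(b), vids, np.eye(len(vids)), 0.0))
    return out


def singleton_blocks(pairs: pd.DataFrame) -> pd.DataFrame:
    """Re-block so every instrument is its own block (one IV per block)."""
    pairs = pairs.reset_index(drop=True).copy()
    pairs["block_index"] = np.arange(len(pairs))
    return pairs


def check_positive_definite(ld: list[BlockLD]) -> None:
    """Cholesky certificate for every block; raises on failure."""
    for blk in ld:
        try:
            np.linalg.cholesky(blk.R)
        except np.linalg.LinAlgError as e:
            raise InputError(f"block {blk.block_index} LD matrix not positive "
                             f"definite") from e
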
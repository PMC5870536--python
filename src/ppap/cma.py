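"""Correlated mutation analysis over alignment columns.

Compensatory mutations leave a statistical footprint: the residue
distributions of two functionally coupled positions co-vary across a family.
Mutual information (MI) between columns measures that coupling; the average
product correction (APC) removes the background component shared by
promiscuously "informative" columns, giving MIp = MI - APC.  Highly
correlated position pairs are those whose MIp Z-score (standardized over all
i < j pairs) exceeds a threshold, 3.0 by default.

Conventions: natural logarithm throughout; frequencies are unsmoothed
empirical frequencies; the column alphabet is whatever symbols are observed
at that column (amino acids, the gap character, and 'X'); the Z-score uses
the population standard deviation over all pairs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .alignment_areas import AA20, GAP, UNKNOWN, FilteredAlignment

logger = logging.getLogger(__name__)

#: Symbol alphabet used for column encoding (gap and X are observed symbols).
MI_ALPHABET = AA20 + GAP + UNKNOWN
_SYM_INDEX = {s: i for i, s in enumerate(MI_ALPHABET)}

DEFAULT_Z_THRESHOLD = 3.0


def mutual_information(column_i: Sequence[str], column_j: Sequence[str]) -> float:
    """MI between two alignment columns (natural log, unsmoothed).

    ``MI = sum_X sum_Y p_ij(X,Y) ln[p_ij(X,Y) / (p_i(X) p_j(Y))]`` over the
    symbols observed in each column; zero-probability terms are skipped.
    """
    if len(column_i) != len(column_j):
        raise ValueError(
            f"column length mismatch: {len(column_i)} vs {len(column_j)}"
        )
    n = len(column_i)
    if n < 2:
        raise ValueError("columns must contain >= 2 symbols")
    pi = Counter(column_i)
    pj = Counter(column_j)
    pij = Counter(zip(column_i, column_j))
    mi = 0.0
    for (x, y), c in pij.items():
        p_xy = c / n
        mi += p_xy * np.log(p_xy * n * n / (pi[x] * pj[y]))
    return max(mi, 0.0)


def _encode(rows: Sequence[str]) -> np.ndarray:
    enc = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    for s, row in enumerate(rows):
        for j, ch in enumerate(row):
            try:
                enc[s, j] = _SYM_INDEX[ch]
            except KeyError:
                raise ValueError(f"invalid symbol {ch!r} in alignment row") from None
    return enc


def mi_matrix(rows: Sequence[str]) -> np.ndarray:
    """Symmetric MI matrix over all column pairs (diagonal set to 0).

    Vectorized via one-hot joint counts; equal to calling
    :func:`mutual_information` on every pair.
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    enc = _encode(rows)
    n_seqs, n_cols = enc.shape
    k = len(MI_ALPHABET)
    onehot = np.zeros((n_seqs, n_cols, k), dtype=np.float32)
    s_idx = np.repeat(np.arange(n_seqs), n_cols)
    c_idx = np.tile(np.arange(n_cols), n_seqs)
    onehot[s_idx, c_idx, enc.ravel()] = 1.0

    marg = onehot.sum(axis=0).astype(np.float64) / n_seqs  # (n_cols, k)
    h_col = -xlogy(marg, marg).sum(axis=1)  # column entropies

    mi = np.zeros((n_cols, n_cols))
    flat = onehot.reshape(n_seqs, n_cols * k)
    for i in range(n_cols):
        # joint counts of column i with every column j
        joint = (onehot[:, i, :].T @ flat).reshape(k, n_cols, k).astype(np.float64) / n_seqs
        h_joint = -xlogy(joint, joint).sum(axis=(0, 2))
        mi[i] = h_col[i] + h_col - h_joint
    np.fill_diagonal(mi, 0.0)
    mi = np.maximum((mi + mi.T) / 2.0, 0.0)
    return mi


@dataclass(frozen=True)
class PairStatistics:
    """MI/MIp matrices with the row means and overall mean behind APC."""

    n_cols: int
    mi: np.ndarray
    mip: np.ndarray
    row_means: np.ndarray
    overall_mean: float


def compute_mip(mi: np.ndarray) -> PairStatistics:
    """Average-product-corrected MI.

    ``APC(i,j) = mean_i(MI) * mean_j(MI) / overall_mean`` with means taken
    excluding the diagonal; ``MIp = MI - APC``.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if mi.ndim != 2 or mi.shape[1] != n:
        raise ValueError("MI matrix must be square")
    if n < 3:
        raise ValueError("need >= 3 columns for APC")
    if not np.allclose(mi, mi.T):
        raise ValueError("MI matrix must be symmetric")
    if (mi < -1e-12).any():
        raise ValueError("MI matrix must be non-negative")
    mi = mi.copy()
    np.fill_diagonal(mi, 0.0)
    row_means = mi.sum(axis=1) / (n - 1)
    iu = np.triu_indices(n, k=1)
    overall_mean = float(mi[iu].mean())
    if overall_mean == 0.0:
        raise ValueError("overall mean MI is zero; no signal to correct")
    apc = np.outer(row_means, row_means) / overall_mean
    mip = mi - apc
    np.fill_diagonal(mip, 0.0)
    return PairStatistics(
        n_cols=n, mi=mi, mip=mip, row_means=row_means, overall_mean=overall_mean
    )


@dataclass(frozen=True)
class ZScores:
    """Standardized MIp over all i < j pairs (population SD)."""

    z: np.ndarray
    mu: float
    sd: float


def pair_zscores(stats: PairStatistics) -> ZScores:
    """``Z(i,j) = (MIp(i,j) - mu) / SD`` with mu, SD over all pairs i < j."""
    n = stats.n_cols
    iu = np.triu_indices(n, k=1)
    values = stats.mip[iu]
    if values.size < 2:
        raise ValueError("need >= 2 distinct pairs")
    mu = float(values.mean())
    sd = float(values.std())  # population SD over the finite set of pairs
    if sd == 0.0:
        raise ValueError("MIp is constant over all pairs; Z-scores undefined")
    z = (stats.mip - mu) / sd
    np.fill_diagonal(z, 0.0)
    return ZScores(z=z, mu=mu, sd=sd)


@dataclass(frozen=True)
class PairSelection:
    """High-MIp position pairs (filtered-column coordinates, i < j)."""

    pairs: tuple[tuple[int, int], ...]
    threshold_z: float
    mu: float
    sd: float

    @property
    def C(self) -> int:
        return len(self.pairs)

    def to_records(self, stats: PairStatistics | None = None,
                   zscores: ZScores | None = None) -> list[dict]:
        out = []
        for i, j in self.pairs:
            rec: dict = {"i": i, "j": j}
            if stats is not None:
                rec["mi"] = float(stats.mi[i, j])
                rec["mip"] = float(stats.mip[i, j])
            if zscores is not None:
                rec["z"] = float(zscores.z[i, j])
            out.append(rec)
        return out


def select_correlated_pairs(
    zscores: ZScores, threshold: float = DEFAULT_Z_THRESHOLD
) -> PairSelection:
    """Pairs (i < j) with Z strictly above ``threshold``."""
    if not np.isfinite(threshold):
        if threshold > 0:
            raise ValueError("threshold must be finite or -inf")
    n = zscores.z.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = zscores.z[iu] > threshold
    pairs = tuple(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    if not pairs:
        raise ValueError(
            f"no pairs exceed Z > {threshold}; lower the threshold or check "
            "that the alignment carries covariation signal"
        )
    return PairSelection(pairs=pairs, threshold_z=float(threshold),
                         mu=zscores.mu, sd=zscores.sd)


def correlated_pairs(
    filtered: FilteredAlignment | Sequence[str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[PairSelection, PairStatistics, ZScores]:
    """Full CMA pipeline on a (filtered) alignment's rows."""
    rows = filtered.alignment.rows if isinstance(filtered, FilteredAlignment) else tuple(filtered)
    stats = compute_mip(mi_matrix(rows))
    zs = pair_zscores(stats)
    return select_correlated_pairs(zs, z_threshold), stats, zs
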
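"""Correlation models and the correlation score S_cor.

A correlation model of one reaction type stores, over the high-MIp position
pairs selected by :mod:`ppap.cma`, the single-position residue counts
``n_i(X)`` and pair counts ``n_ij(X, Y)`` tallied from that type's filtered
alignment.  A query aligned into the same column space is scored as

    S_cor = (1/C) * sum_{(i,j) in A} ln[ p_ij(Xq, Yq) / (p_i(Xq) p_j(Yq)) ]

where A is the selected pair set, C = |A| standardizes models with different
pair counts, and frequencies are additively smoothed:

    p_i(X)     = (n_i(X) + alpha) / (N + alpha * d_s)
    p_ij(X, Y) = (n_ij(X, Y) + beta) / (N + beta * d_p)

with alpha = 1/21, d_s = 21 (20 amino acids + gap), d_p = 21^2, and
beta = alpha^2 / (N + 2 * alpha * d_s).  beta is derived so that a pair of
residues never observed at (i, j) — singly or jointly — has ratio exactly 1
and therefore contributes exactly 0 to the score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment_areas import AA20, GAP, UNKNOWN, FilteredAlignment
from .cma import PairSelection

logger = logging.getLogger(__name__)

#: Smoothing alphabet: the 20 standard amino acids plus the gap symbol.
CORR_ALPHABET = AA20 + GAP
D_SINGLE = len(CORR_ALPHABET)  # 21
D_PAIR = D_SINGLE ** 2  # 441
_SYM_INDEX = {s: i for i, s in enumerate(CORR_ALPHABET)}


@dataclass(frozen=True)
class SmoothingParams:
    alpha: float
    beta: float
    N: int
    d_s: int = D_SINGLE
    d_p: int = D_PAIR


def smoothing_params(N: int) -> SmoothingParams:
    """Pseudocount weights for a training set of N sequences."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    alpha = 1.0 / D_SINGLE
    beta = alpha ** 2 / (N + 2 * alpha * D_SINGLE)
    return SmoothingParams(alpha=alpha, beta=beta, N=N)


def _sym_code(symbol: str) -> int | None:
    """Alphabet index, or None for 'X' (an unobserved residue)."""
    if symbol == UNKNOWN:
        return None
    code = _SYM_INDEX.get(symbol)
    if code is None:
        raise ValueError(f"symbol {symbol!r} outside the 21-letter alphabet")
    return code


@dataclass
class CorrelationModel:
    """Smoothed single/pair frequency tables over selected position pairs.

    Positions are filtered-column coordinates; ``kept_columns`` maps them
    back to the original alignment columns so aligned query rows can be
    projected.
    """

    reaction_type: str | None
    pairs: tuple[tuple[int, int], ...]
    N: int
    single_counts: dict[int, np.ndarray]  # position -> (21,) counts
    pair_counts: dict[tuple[int, int], np.ndarray]  # (i, j) -> (21, 21) counts
    smoothing: SmoothingParams
    kept_columns: tuple[int, ...] = ()
    threshold_z: float = float("nan")

    @property
    def C(self) -> int:
        return len(self.pairs)

    # -- smoothed frequencies ------------------------------------------------

    def p_single(self, position: int, symbol: str) -> float:
        if position not in self.single_counts:
            raise ValueError(f"position {position} not in model")
        code = _sym_code(symbol)
        n = 0.0 if code is None else float(self.single_counts[position][code])
        a = self.smoothing.alpha
        return (n + a) / (self.N + a * self.smoothing.d_s)

    def p_pair(self, pair: tuple[int, int], symbol_x: str, symbol_y: str) -> float:
        if pair not in self.pair_counts:
            raise ValueError(f"pair {pair} not in model")
        cx, cy = _sym_code(symbol_x), _sym_code(symbol_y)
        if cx is None or cy is None:
            n = 0.0
        else:
            n = float(self.pair_counts[pair][cx, cy])
        b = self.smoothing.beta
        return (n + b) / (self.N + b * self.smoothing.d_p)

    # -- scoring -------------------------------------------------------------

    def score(self, filtered_row: str) -> float:
        """S_cor of a query row given in filtered-column coordinates."""
        needed = max(max(p) for p in self.pairs)
        if len(filtered_row) <= needed:
            missing = [j for i, j in self.pairs if j >= len(filtered_row)]
            raise ValueError(
                f"query row of length {len(filtered_row)} is missing selected "
                f"pair columns (up to index {needed}; {len(missing)} pairs hit)"
            )
        total = 0.0
        for i, j in self.pairs:
            x, y = filtered_row[i], filtered_row[j]
            total += math.log(
                self.p_pair((i, j), x, y)
                / (self.p_single(i, x) * self.p_single(j, y))
            )
        return total / self.C

    def score_full_row(self, full_row: str) -> float:
        """S_cor of a row given in original-alignment coordinates."""
        if not self.kept_columns:
            raise ValueError("model has no kept_columns map; use score()")
        return self.score("".join(full_row[c] for c in self.kept_columns))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        def sparse(vec: np.ndarray) -> dict[str, float]:
            return {
                CORR_ALPHABET[k]: float(v)
                for k, v in enumerate(vec.ravel()) if v
            } if vec.ndim == 1 else {
                f"{CORR_ALPHABET[a]}{CORR_ALPHABET[b]}": float(vec[a, b])
                for a in range(D_SINGLE) for b in range(D_SINGLE) if vec[a, b]
            }

        return {
            "reaction_type": self.reaction_type,
            "N": self.N,
            "threshold_z": self.threshold_z,
            "kept_columns": list(self.kept_columns),
            "pairs": [list(p) for p in self.pairs],
            "single_counts": {str(p): sparse(v) for p, v in self.single_counts.items()},
            "pair_counts": {f"{i},{j}": sparse(v) for (i, j), v in self.pair_counts.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CorrelationModel":
        single = {}
        for p, tab in d["single_counts"].items():
            vec = np.zeros(D_SINGLE)
            for sym, v in tab.items():
                vec[_SYM_INDEX[sym]] = v
            single[int(p)] = vec
        pairs_c = {}
        for key, tab in d["pair_counts"].items():
            i, j = (int(x) for x in key.split(","))
            mat = np.zeros((D_SINGLE, D_SINGLE))
            for sym2, v in tab.items():
                mat[_SYM_INDEX[sym2[0]], _SYM_INDEX[sym2[1]]] = v
            pairs_c[(i, j)] = mat
        return cls(
            reaction_type=d["reaction_type"],
            pairs=tuple((int(a), int(b)) for a, b in d["pairs"]),
            N=int(d["N"]),
            single_counts=single,
            pair_counts=pairs_c,
            smoothing=smoothing_params(int(d["N"])),
            kept_columns=tuple(d.get("kept_columns", ())),
            threshold_z=float(d.get("threshold_z", float("nan"))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CorrelationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_correlation_model(
    filtered: FilteredAlignment,
    pair_selection: PairSelection,
    reaction_type: str | None = None,
) -> CorrelationModel:
    """Tabulate single/pair counts for the selected pairs.

    'X' residues are skipped in the tallies (they contribute to N but to no
    symbol class), so an all-standard alignment satisfies
    ``sum_X n_i(X) = N`` exactly at every position.
    """
    rows = filtered.alignment.rows
    n_cols = filtered.n_cols
    for i, j in pair_selection.pairs:
        if not (0 <= i < j < n_cols):
            raise ValueError(
                f"pair ({i}, {j}) outside the filtered column space "
                f"(n_cols={n_cols}); mismatched column spaces?"
            )
    N = len(rows)
    positions = sorted({p for ij in pair_selection.pairs for p in ij})
    single = {p: np.zeros(D_SINGLE) for p in positions}
    pairs = {ij: np.zeros((D_SINGLE, D_SINGLE)) for ij in pair_selection.pairs}
    saw_unknown = False
    for row in rows:
        codes = {}
        for p in positions:
            c = _sym_code(row[p])
            codes[p] = c
            if c is None:
                saw_unknown = True
            else:
                single[p][c] += 1.0
        for i, j in pair_selection.pairs:
            ci, cj = codes[i], codes[j]
            if ci is not None and cj is not None:
                pairs[(i, j)][ci, cj] += 1.0
    if saw_unknown:
        logger.warning("training rows contain 'X'; those symbols were skipped "
                       "in frequency tallies")
    return CorrelationModel(
        reaction_type=reaction_type,
        pairs=pair_selection.pairs,
        N=N,
        single_counts=single,
        pair_counts=pairs,
        smoothing=smoothing_params(N),
        kept_columns=filtered.kept_columns,
        threshold_z=pair_selection.threshold_z,
    )


def smoothed_frequencies(model, position_or_pair, symbol_or_pair) -> float:
    """Smoothed p_i(X) or p_ij(X, Y) depending on the argument shapes."""
    if isinstance(position_or_pair, tuple):
        x, y = symbol_or_pair
        return model.p_pair(tuple(position_or_pair), x, y)
    return model.p_single(position_or_pair, symbol_or_pair)


def correlation_score(model: CorrelationModel, aligned_query_row: str) -> float:
    """S_cor of a query row (filtered coordinates if the length matches the
    filtered space, otherwise original coordinates via ``kept_columns``)."""
    if model.kept_columns and len(aligned_query_row) > model.kept_columns[-1] \
            and len(aligned_query_row) != len(model.kept_columns):
        return model.score_full_row(aligned_query_row)
    return model.score(aligned_query_row)
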
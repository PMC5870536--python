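"""Six-feature score vectors, binary LDA classifiers and the cascaded call.

For each query, six similarity features are assembled: the clamped profile
scores against the R-4-A, R-4-C and R-2-X Area profiles, and the correlation
scores S_cor against the three reaction types' correlation models.  The
features are standardized with statistics from the training matrix, three
binary Fisher-LDA classifiers (one per target type, target-vs-rest, priors
proportional to class sizes) are fit on them, and a cascade applies the
classifiers in the fixed order R-4-A -> R-4-C -> R-2-X: the first "yes"
determines the call, and a query rejected by all three is called "other".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment_areas import (
    Alignment,
    ColumnIndexSet,
    FilteredAlignment,
    ProteinSequence,
    aligned_query_row,
    extract_area_segments,
    filter_columns,
)
from .cma import DEFAULT_Z_THRESHOLD, PairSelection, correlated_pairs
from .corrscore import CorrelationModel, build_correlation_model
from .phmm import TARGET_TYPE_ORDER, ProfileModel, build_area_profile

logger = logging.getLogger(__name__)

OTHER_LABEL = "other"
DEFAULT_AREA_COMBO = ("Area1", "Area3", "Area4")

FEATURE_NAMES = ("hmm_a", "hmm_c", "hmm_x", "cor_a", "cor_c", "cor_x")


@dataclass(frozen=True)
class PipelineConfig:
    """Model-building and scoring settings (defaults as used throughout)."""

    area_combo: tuple[str, ...] = DEFAULT_AREA_COMBO
    z_threshold: float = DEFAULT_Z_THRESHOLD
    max_gap_fraction: float = 0.8
    backend: str = "auto"  # profile engine: auto | pyhmmer | builtin
    aligner: str = "builtin"  # query addition: builtin | mafft | auto | truth

    def to_dict(self) -> dict:
        return {
            "area_combo": list(self.area_combo),
            "z_threshold": self.z_threshold,
            "max_gap_fraction": self.max_gap_fraction,
            "backend": self.backend,
            "aligner": self.aligner,
        }


@dataclass(frozen=True)
class ScoreVector:
    """hmm_*: clamped profile scores; cor_*: correlation scores."""

    hmm_a: float
    hmm_c: float
    hmm_x: float
    cor_a: float
    cor_c: float
    cor_x: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("score vector contains non-finite values")
        if min(self.hmm_a, self.hmm_c, self.hmm_x) < 0:
            raise ValueError("clamped profile scores must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.hmm_a, self.hmm_c, self.hmm_x,
                         self.cor_a, self.cor_c, self.cor_x])

    @classmethod
    def from_parts(cls, hmm: Mapping[str, float], cor: Mapping[str, float]) -> "ScoreVector":
        a, c, x = TARGET_TYPE_ORDER
        return cls(hmm[a], hmm[c], hmm[x], cor[a], cor[c], cor[x])


@dataclass(frozen=True)
class Standardizer:
    """Per-feature mean/SD (population) from the training matrix."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Standardizer":
        matrix = np.asarray(matrix, dtype=float)
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance feature(s) at indices {bad.tolist()}; "
                "cannot standardize"
            )
        return cls(mean=mean, sd=sd)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardizer":
        return cls(mean=np.array(d["mean"]), sd=np.array(d["sd"]))


@dataclass(frozen=True)
class LdaClassifier:
    """Binary hyperplane in standardized feature space: yes iff w.v + b > 0."""

    target_type: str
    weights: np.ndarray
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def decision_value(self, std_vector: np.ndarray) -> float:
        return float(self.weights @ np.asarray(std_vector, dtype=float)
                     + self.intercept)

    def predict(self, std_vector: np.ndarray) -> bool:
        return self.decision_value(std_vector) > 0

    def to_dict(self) -> dict:
        return {
            "target_type": self.target_type,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LdaClassifier":
        return cls(
            target_type=d["target_type"],
            weights=np.array(d["weights"]),
            intercept=float(d["intercept"]),
            training_meta=dict(d.get("training_meta", {})),
        )


def fit_binary_lda(
    score_matrix: np.ndarray,
    is_target_labels: Sequence[bool],
    target_type: str = "",
    training_meta: dict | None = None,
) -> LdaClassifier:
    """Two-class Fisher LDA with priors proportional to class sizes.

    ``score_matrix`` must already be standardized.  Weights are
    ``S_pooled^-1 (mu_target - mu_rest)``; the intercept places the boundary
    at the prior-adjusted midpoint of the projected class means.  A singular
    pooled covariance triggers a ridge-regularized fallback
    (lambda = 1e-6 * trace / n_features) with a logged warning.
    """
    X = np.asarray(score_matrix, dtype=float)
    y = np.asarray(is_target_labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("score_matrix and labels must have matching lengths")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"need >= 2 samples per class, got target={n1}, rest={n0}"
        )
    X1, X0 = X[y], X[~y]
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    scatter = ((X1 - mu1).T @ (X1 - mu1)) + ((X0 - mu0).T @ (X0 - mu0))
    pooled = scatter / (n1 + n0 - 2)
    p = X.shape[1]
    diff = mu1 - mu0
    try:
        if np.linalg.cond(pooled) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned pooled covariance")
        w = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        lam = 1e-6 * np.trace(pooled) / p
        logger.warning(
            "singular pooled covariance for %s; ridge fallback (lambda=%.3e)",
            target_type or "classifier", lam,
        )
        w = np.linalg.solve(pooled + lam * np.eye(p), diff)
    b = -0.5 * float(w @ (mu1 + mu0)) + np.log(n1 / n0)
    meta = dict(training_meta or {})
    meta.setdefault("n_target", n1)
    meta.setdefault("n_rest", n0)
    return LdaClassifier(target_type=target_type, weights=w,
                         intercept=float(b), training_meta=meta)


@dataclass(frozen=True)
class Prediction:
    """Cascade output: the final four-way call plus per-classifier detail."""

    final_label: str
    per_classifier: dict  # target_type -> {"yes": bool, "value": float}
    score_vector: ScoreVector

    def to_record(self) -> dict:
        rec = {"final_label": self.final_label}
        for t, d in self.per_classifier.items():
            rec[f"{t}_yes"] = d["yes"]
            rec[f"{t}_value"] = d["value"]
        for name, v in zip(FEATURE_NAMES, self.score_vector.as_array()):
            rec[name] = float(v)
        return rec


def apply_cascade(
    classifiers: Mapping[str, LdaClassifier],
    score_vector: ScoreVector,
    standardizer: Standardizer,
    order: Sequence[str] = TARGET_TYPE_ORDER,
) -> Prediction:
    """Apply the three binary classifiers in fixed order; first yes wins.

    All three binary outcomes are always evaluated and recorded.  A vector
    rejected by every classifier is labeled "other".
    """
    missing = [t for t in order if t not in classifiers]
    if missing:
        raise ValueError(f"missing classifier(s) for {missing}")
    v = standardizer.transform(score_vector.as_array()[None, :])[0]
    per = {}
    final = OTHER_LABEL
    for t in order:
        val = classifiers[t].decision_value(v)
        yes = val > 0
        per[t] = {"yes": yes, "value": val}
        if yes and final == OTHER_LABEL:
            final = t
    n_yes = sum(d["yes"] for d in per.values())
    if n_yes > 1:
        logger.info("cascade: %d classifiers said yes; fixed order kept %s",
                    n_yes, final)
    return Prediction(final_label=final, per_classifier=per,
                      score_vector=score_vector)


# ---------------------------------------------------------------------------
# Per-type model resources and score-vector assembly
# ---------------------------------------------------------------------------

def ids_hash(ids: Sequence[str]) -> str:
    return hashlib.sha256(json.dumps(sorted(ids)).encode()).hexdigest()


@dataclass
class TypeResources:
    """Everything one reaction type contributes to the score vector."""

    reaction_type: str
    alignment: Alignment  # this type's training rows
    area_columns: ColumnIndexSet
    area_combo: tuple[str, ...]
    profile: ProfileModel
    filtered: FilteredAlignment
    selection: PairSelection
    corr: CorrelationModel

    @property
    def training_ids(self) -> tuple[str, ...]:
        return self.alignment.ids

    @property
    def provenance_hash(self) -> str:
        return ids_hash(self.alignment.ids)

    def segment_of_row(self, full_row: str) -> str:
        cols = self.area_columns.combined(self.area_combo)
        return "".join(full_row[c] for c in cols)

    def corr_score_of_row(self, full_row: str) -> float:
        return self.corr.score(self.filtered.project_row(full_row))


def build_type_resources(
    type_alignment: Alignment,
    area_columns: ColumnIndexSet,
    reaction_type: str,
    config: PipelineConfig = PipelineConfig(),
) -> TypeResources:
    """Build profile + correlation model for one reaction type's alignment."""
    area_aln = extract_area_segments(type_alignment, area_columns, config.area_combo)
    profile = build_area_profile(area_aln, reaction_type, config.area_combo,
                                 backend=config.backend)
    filtered = filter_columns(type_alignment, config.max_gap_fraction)
    selection, _, _ = correlated_pairs(filtered, config.z_threshold)
    corr = build_correlation_model(filtered, selection, reaction_type)
    return TypeResources(
        reaction_type=reaction_type,
        alignment=type_alignment,
        area_columns=area_columns,
        area_combo=tuple(config.area_combo),
        profile=profile,
        filtered=filtered,
        selection=selection,
        corr=corr,
    )


def assemble_score_vector(
    query: ProteinSequence,
    resources: Mapping[str, TypeResources],
    aligner: str = "builtin",
    query_rows: Mapping[str, str] | None = None,
) -> ScoreVector:
    """The six similarity features of one query.

    The query is aligned into each type's alignment independently (or, when
    ``query_rows`` provides pre-aligned rows in each type's column space,
    those are used directly — e.g. rows of a truth alignment).
    """
    hmm: dict[str, float] = {}
    cor: dict[str, float] = {}
    for t in TARGET_TYPE_ORDER:
        if t not in resources:
            raise ValueError(f"missing model resources for {t}")
        res = resources[t]
        try:
            if query_rows is not None and t in query_rows:
                row = query_rows[t]
            else:
                row = aligned_query_row(query, res.alignment, method=aligner)
            segment = res.segment_of_row(row)
            if not segment.replace("-", ""):
                logger.warning(
                    "query %s covers none of the %s Area columns; profile "
                    "score set to 0 (low coverage)", query.id, t,
                )
                hmm[t] = 0.0
            else:
                hmm[t] = res.profile.score(segment).clamped
            cor[t] = res.corr_score_of_row(row)
        except Exception as exc:
            raise RuntimeError(f"scoring query {query.id!r} against {t} failed: {exc}") from exc
    return ScoreVector.from_parts(hmm, cor)


def train_cascade(
    score_vectors: Sequence[ScoreVector],
    group_labels: Sequence[str],
    training_ids: Sequence[str] | None = None,
) -> tuple[Standardizer, dict[str, LdaClassifier]]:
    """Standardizer + the three binary classifiers from training scores."""
    matrix = np.vstack([v.as_array() for v in score_vectors])
    standardizer = Standardizer.fit(matrix)
    std = standardizer.transform(matrix)
    groups = np.asarray(group_labels)
    meta = {}
    if training_ids is not None:
        meta = {"training_ids": sorted(training_ids),
                "ids_hash": ids_hash(list(training_ids))}
    classifiers = {}
    for t in TARGET_TYPE_ORDER:
        classifiers[t] = fit_binary_lda(std, groups == t, target_type=t,
                                        training_meta=dict(meta))
    return standardizer, classifiers
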
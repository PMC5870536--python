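"""Cross-validation harnesses and PCA reporting.

Leave-one-out cross-validation (LOOCV) rebuilds, for every held-out
sequence, all per-type alignments, profiles, correlation models,
standardizer and LDA classifiers without it, then predicts it.  Repeated
random sub-sampling validation (RRSV) draws, per reaction type, a training
set of ceil(n/2) sequences (the decimal is rounded up), tests on the rest,
and averages accuracy over repetitions.

The only fold-level shortcut is a cache: a held-out sequence belongs to
exactly one reaction type, so the other types' profiles and correlation
models — which never contained it — are reused across folds.  This is
verified equivalent to the naive full rebuild in the test suite, and every
fold's artifacts are audited for leakage through their training-id
provenance hashes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_areas import (
    Alignment,
    AreaMap,
    ProteinSequence,
    map_reference_positions,
)
from .classify import (
    OTHER_LABEL,
    PipelineConfig,
    ScoreVector,
    TypeResources,
    assemble_score_vector,
    apply_cascade,
    build_type_resources,
    ids_hash,
    train_cascade,
)
from .phmm import TARGET_TYPE_ORDER

logger = logging.getLogger(__name__)


class LeakageError(AssertionError):
    """A held-out sequence appeared in a fold artifact."""


@dataclass
class LabeledDataset:
    """Labeled sequences sharing one alignment coordinate system.

    ``master`` holds one gapped row per labeled sequence plus a non-labeled
    anchor row (``anchor_id``) that serves as the AreaMap reference, so the
    Area-to-column mapping never depends on a held-out sequence.  ``lda_ids``
    lists the sequences used when fitting the LDA classifiers; sequences
    outside it (e.g. reaction types deliberately held out of fitting) are
    still predicted and must come out "other".
    """

    master: Alignment
    labels: dict
    area_map: AreaMap
    anchor_id: str
    target_types: tuple = TARGET_TYPE_ORDER
    lda_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.anchor_id not in self.master:
            raise ValueError(f"anchor {self.anchor_id!r} not in master alignment")
        if self.anchor_id in self.labels:
            raise ValueError("anchor row must not carry a label")
        for sid in self.labels:
            if sid not in self.master:
                raise ValueError(f"labeled id {sid!r} not in master alignment")
        if not self.lda_ids:
            self.lda_ids = tuple(self.labeled_ids)
        for t in self.target_types:
            if len(self.type_ids(t)) < 2:
                raise ValueError(f"target type {t} has < 2 sequences")

    @property
    def labeled_ids(self) -> list[str]:
        return [i for i in self.master.ids if i in self.labels]

    def group(self, seq_id: str) -> str:
        lab = self.labels[seq_id]
        return lab if lab in self.target_types else OTHER_LABEL

    def type_ids(self, label: str) -> list[str]:
        return [i for i in self.labeled_ids if self.labels[i] == label]

    def family_labels(self) -> list[str]:
        seen = []
        for i in self.labeled_ids:
            if self.labels[i] not in seen:
                seen.append(self.labels[i])
        return seen

    def sequence(self, seq_id: str) -> ProteinSequence:
        return ProteinSequence(seq_id, self.master.row(seq_id).replace("-", ""))

    def type_alignment(self, label: str, exclude: str | None = None) -> Alignment:
        ids = [i for i in self.type_ids(label) if i != exclude]
        if len(ids) < 2:
            raise ValueError(
                f"type {label} reduced below 2 sequences after excluding "
                f"{exclude!r}"
            )
        return self.master.subset(ids, family_label=label)


@dataclass
class FoldRecord:
    test_id: str
    true_label: str
    true_group: str
    predicted: str
    classifier_calls: dict  # target type -> {"yes": bool, "value": float}
    provenance: dict  # artifact name -> ids hash
    rep: int | None = None

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "true_label": self.true_label,
            "true_group": self.true_group,
            "predicted": self.predicted,
            "classifier_calls": {
                t: {"yes": bool(d["yes"]), "value": round(float(d["value"]), 10)}
                for t, d in self.classifier_calls.items()
            },
            "provenance": self.provenance,
            "rep": self.rep,
        }


@dataclass
class AccuracyReport:
    """Per-fold records with per-type and overall accuracy tallies."""

    mode: str
    config: dict
    records: list
    extra: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_correct(self) -> int:
        return sum(r.predicted == r.true_group for r in self.records)

    @property
    def accuracy(self) -> float:
        """Overall accuracy; for RRSV, the mean of per-repetition accuracies."""
        if self.mode == "rrsv":
            return float(np.mean(self.extra["per_rep_accuracy"]))
        return self.n_correct / self.n_total

    def per_group(self) -> dict:
        out: dict[str, list[int]] = {}
        for r in self.records:
            c = out.setdefault(r.true_group, [0, 0])
            c[1] += 1
            c[0] += r.predicted == r.true_group
        return {g: (c[0], c[1]) for g, c in out.items()}

    def records_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {"test_id": r.test_id, "true_label": r.true_label,
                 "true_group": r.true_group, "predicted": r.predicted,
                 "rep": r.rep}
            for t, call in r.classifier_calls.items():
                d[f"{t}_yes"] = call["yes"]
            rows.append(d)
        return pd.DataFrame(rows)

    def classifier_table(self) -> pd.DataFrame:
        """Per-true-type tallies of each binary classifier and the cascade."""
        df = self.records_dataframe()
        out = []
        for lab, sub in df.groupby("true_label", sort=False):
            row = {"true": lab, "n": len(sub)}
            for t in TARGET_TYPE_ORDER:
                row[f"{t}_yes"] = int(sub[f"{t}_yes"].sum())
                row[f"{t}_no"] = int(len(sub) - sub[f"{t}_yes"].sum())
            row["cascade_correct"] = int((sub.predicted == sub.true_group).sum())
            out.append(row)
        return pd.DataFrame(out)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "config": self.config,
            "accuracy": self.accuracy,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "per_group": {g: list(v) for g, v in sorted(self.per_group().items())},
            "extra": self.extra,
            "records": [r.to_dict() for r in self.records],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True,
                                         indent=1) + "\n")


# ---------------------------------------------------------------------------
# Scoring helpers shared by both harnesses
# ---------------------------------------------------------------------------

def _component_scores(
    res: TypeResources, dataset: LabeledDataset, ids: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """(clamped profile score, S_cor) of each master row against one type."""
    segments = {i: res.segment_of_row(dataset.master.row(i)) for i in ids}
    hmm = res.profile.score_many(segments)
    return {
        i: (hmm[i].clamped, res.corr_score_of_row(dataset.master.row(i)))
        for i in ids
    }


def _vector_from_components(
    comp: Mapping[str, Mapping[str, tuple[float, float]]], seq_id: str
) -> ScoreVector:
    hmm = {t: comp[t][seq_id][0] for t in TARGET_TYPE_ORDER}
    cor = {t: comp[t][seq_id][1] for t in TARGET_TYPE_ORDER}
    return ScoreVector.from_parts(hmm, cor)


def _predict_query(
    dataset: LabeledDataset,
    seq_id: str,
    resources: Mapping[str, TypeResources],
    classifiers,
    standardizer,
    config: PipelineConfig,
):
    query = dataset.sequence(seq_id)
    if config.aligner == "truth":
        row = dataset.master.row(seq_id)
        query_rows = {t: row for t in TARGET_TYPE_ORDER}
        vec = assemble_score_vector(query, resources, query_rows=query_rows)
    else:
        vec = assemble_score_vector(query, resources, aligner=config.aligner)
    return apply_cascade(classifiers, vec, standardizer)


def _audit_fold(test_id: str, resources: Mapping[str, TypeResources],
                lda_train_ids: Sequence[str]) -> dict:
    """Assert the held-out id is absent from every fold artifact."""
    provenance = {}
    for t, res in resources.items():
        if test_id in res.training_ids:
            raise LeakageError(
                f"held-out {test_id!r} found in {t} model training set"
            )
        provenance[f"model_{t}"] = res.provenance_hash
    if test_id in lda_train_ids:
        raise LeakageError(f"held-out {test_id!r} found in LDA training set")
    provenance["lda"] = ids_hash(list(lda_train_ids))
    return provenance


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def loocv(
    dataset: LabeledDataset,
    config: PipelineConfig = PipelineConfig(),
    use_cache: bool = True,
) -> AccuracyReport:
    """Leave-one-out cross-validation of the full cascade.

    Every labeled sequence is held out exactly once; the fold's models are
    built without it and the cascade's call is compared with its group
    (its reaction type, or "other" for non-target types).
    """
    ids = dataset.labeled_ids
    if len(ids) < 2:
        raise ValueError("LOOCV needs >= 2 labeled sequences")
    area_columns = map_reference_positions(dataset.master, dataset.area_map)

    def build(t: str, exclude: str | None) -> TypeResources:
        return build_type_resources(
            dataset.type_alignment(t, exclude=exclude), area_columns, t, config
        )

    full_res = {t: build(t, None) for t in dataset.target_types}
    full_comp = {t: _component_scores(full_res[t], dataset, ids)
                 for t in dataset.target_types}

    records = []
    for e in ids:
        test_type = dataset.labels[e] if dataset.labels[e] in dataset.target_types else None
        if use_cache:
            resources = dict(full_res)
            comp = dict(full_comp)
            if test_type is not None:
                res_e = build(test_type, e)
                resources[test_type] = res_e
                comp[test_type] = _component_scores(res_e, dataset, ids)
        else:
            resources = {t: build(t, e) for t in dataset.target_types}
            comp = {t: _component_scores(resources[t], dataset, ids)
                    for t in dataset.target_types}
        train_ids = [i for i in dataset.lda_ids if i != e]
        provenance = _audit_fold(e, resources, train_ids)
        vectors = [_vector_from_components(comp, i) for i in train_ids]
        groups = [dataset.group(i) for i in train_ids]
        standardizer, classifiers = train_cascade(vectors, groups, train_ids)
        pred = _predict_query(dataset, e, resources, classifiers,
                              standardizer, config)
        records.append(FoldRecord(
            test_id=e,
            true_label=dataset.labels[e],
            true_group=dataset.group(e),
            predicted=pred.final_label,
            classifier_calls=pred.per_classifier,
            provenance=provenance,
        ))
    report = AccuracyReport(mode="loocv", config=config.to_dict(), records=records)
    logger.info("LOOCV: %d/%d correct (%.3f)", report.n_correct,
                report.n_total, report.accuracy)
    return report


# ---------------------------------------------------------------------------
# RRSV
# ---------------------------------------------------------------------------

def rrsv_train_size(n: int, fraction: float = 0.5) -> int:
    """Training-set size for a type of n sequences: the decimal rounds up."""
    return math.ceil(n * fraction)


def rrsv(
    dataset: LabeledDataset,
    fraction: float = 0.5,
    reps: int = 10,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> AccuracyReport:
    """Repeated random sub-sampling validation, stratified by reaction type.

    Per repetition and per type, ceil(fraction * n) sequences train the
    models and the remainder are tested; models (including pair selection)
    are rebuilt per repetition.  Fully reproducible from ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    area_columns = map_reference_positions(dataset.master, dataset.area_map)
    records = []
    per_rep_accuracy = []
    train_sizes: dict[str, int] = {}
    for rep in range(reps):
        rng = np.random.default_rng([int(seed), rep])
        train_by_label: dict[str, list[str]] = {}
        test_ids: list[str] = []
        for label in dataset.family_labels():
            fam = dataset.type_ids(label)
            k = rrsv_train_size(len(fam), fraction)
            train_sizes[label] = k
            perm = rng.permutation(len(fam))
            train_by_label[label] = [fam[i] for i in perm[:k]]
            rest = [fam[i] for i in perm[k:]]
            if not rest:
                logger.info("type %s has n=%d; train=%d leaves no test "
                            "sequences this repetition", label, len(fam), k)
            test_ids.extend(rest)

        resources = {}
        for t in dataset.target_types:
            ids_t = train_by_label[t]
            if len(ids_t) < 2:
                raise ValueError(f"type {t} has < 2 training sequences")
            resources[t] = build_type_resources(
                dataset.master.subset(ids_t, family_label=t),
                area_columns, t, config,
            )
        lda_train = [i for lab in dataset.family_labels()
                     for i in train_by_label[lab] if i in dataset.lda_ids]
        comp = {t: _component_scores(resources[t], dataset, lda_train)
                for t in dataset.target_types}
        vectors = [_vector_from_components(comp, i) for i in lda_train]
        groups = [dataset.group(i) for i in lda_train]
        standardizer, classifiers = train_cascade(vectors, groups, lda_train)

        n_correct = 0
        for e in sorted(test_ids, key=dataset.master.index):
            provenance = _audit_fold(e, resources, lda_train)
            pred = _predict_query(dataset, e, resources, classifiers,
                                  standardizer, config)
            ok = pred.final_label == dataset.group(e)
            n_correct += ok
            records.append(FoldRecord(
                test_id=e,
                true_label=dataset.labels[e],
                true_group=dataset.group(e),
                predicted=pred.final_label,
                classifier_calls=pred.per_classifier,
                provenance=provenance,
                rep=rep,
            ))
        per_rep_accuracy.append(n_correct / len(test_ids))
    report = AccuracyReport(
        mode="rrsv",
        config={**config.to_dict(), "fraction": fraction, "reps": reps,
                "seed": int(seed)},
        records=records,
        extra={"per_rep_accuracy": per_rep_accuracy,
               "train_sizes": train_sizes},
    )
    logger.info("RRSV: mean accuracy %.3f over %d reps", report.accuracy, reps)
    return report


# ---------------------------------------------------------------------------
# PCA reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaReport:
    loadings: np.ndarray  # (n_kept_features, n_components)
    variance_fractions: np.ndarray
    feature_names: tuple
    dropped_features: tuple


def pca_report(
    score_matrix: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> PcaReport:
    """Eigen-decomposition of the feature covariance of (standardized) scores.

    Variance fractions sum to 1; each component's sign is fixed so that its
    largest-magnitude loading is positive.  Zero-variance features are
    dropped with a warning.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 score vectors")
    p = X.shape[1]
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(p)
    )
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        logger.warning("dropping zero-variance feature(s): %s", dropped)
    X = X[:, keep]
    X = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    fractions = var / var.sum()
    loadings = vt.T
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    return PcaReport(
        loadings=loadings,
        variance_fractions=fractions,
        feature_names=tuple(n for n, kk in zip(names, keep) if kk),
        dropped_features=dropped,
    )
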
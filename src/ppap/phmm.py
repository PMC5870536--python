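"""Profile models over Area segment alignments and best-profile prediction.

One profile is built per reaction type from the concatenated Area segments of
that type's alignment (default combination: Area 1 + 3 + 4).  Query segments
are scored against each profile; a raw bit score below zero, or no
significant match at all, is clamped to zero.  The engine is pluggable:

* ``"pyhmmer"`` — HMMER3 profile HMMs built and searched in-process
  (deterministic at a fixed builder seed);
* ``"builtin"`` — a pure position-specific scoring model (log-odds of
  match-state emissions with Laplace smoothing, no insert/delete states),
  so the pipeline runs with no profile engine at all.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment_areas import AA20, GAP, Alignment

logger = logging.getLogger(__name__)

#: Canonical ordering of the target reaction types; also the tie-break order.
TARGET_TYPE_ORDER = ("R-4-A", "R-4-C", "R-2-X")

#: Sentinel returned by best_profile_label when every profile scores zero.
UNCLASSIFIED = "UNCLASSIFIED"

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


@dataclass(frozen=True)
class HmmScore:
    """A raw profile bit score and its clamped (>= 0) form.

    ``raw`` is ``None`` when the engine reports no significant match
    (NO_MATCH); ``clamped`` is then 0, as it is for any negative raw score.
    """

    raw: float | None

    @property
    def clamped(self) -> float:
        if self.raw is None or self.raw < 0:
            return 0.0
        return float(self.raw)

    @property
    def no_match(self) -> bool:
        return self.raw is None


def _pyhmmer_runtime():
    from pyhmmer import easel, plan7

    abc = easel.Alphabet.amino()
    return easel, plan7, abc, plan7.Background(abc)


class _PyhmmerBackend:
    """HMMER3 engine adapter (build from MSA, score by search)."""

    name = "pyhmmer"

    def __init__(self, alignment: Alignment, model_name: str, seed: int = 42):
        easel, plan7, abc, bg = _pyhmmer_runtime()
        seqs = [
            easel.TextSequence(name=sid.encode(), sequence=row)
            for sid, row in zip(alignment.ids, alignment.rows)
        ]
        msa = easel.TextMSA(name=model_name.encode(), sequences=seqs)
        builder = plan7.Builder(abc, seed=seed)
        self._hmm, _, _ = builder.build_msa(msa.digitize(abc), bg)
        self._abc, self._bg = abc, bg
        self._easel, self._plan7 = easel, plan7

    def score_many(self, segments: Mapping[str, str]) -> dict[str, HmmScore]:
        if not segments:
            return {}
        block = self._easel.DigitalSequenceBlock(
            self._abc,
            [
                self._easel.TextSequence(
                    name=str(i).encode(), sequence=seg
                ).digitize(self._abc)
                for i, seg in enumerate(segments.values())
            ],
        )
        # Filters disabled: the clamping rule, not an E-value gate, decides
        # what counts as "no score".
        pipeline = self._plan7.Pipeline(
            self._abc, self._bg, bias_filter=False,
            F1=1.0, F2=1.0, F3=1.0, E=1e6, seed=42,
        )
        hits = pipeline.search_hmm(self._hmm, block)
        by_index: dict[int, float] = {}
        for hit in hits:
            name = hit.name.decode() if isinstance(hit.name, bytes) else hit.name
            by_index[int(name)] = float(hit.score)
        return {
            key: HmmScore(by_index.get(i))
            for i, key in enumerate(segments.keys())
        }

    def serialize(self) -> str:
        buf = io.BytesIO()
        self._hmm.write(buf, binary=False)
        return buf.getvalue().decode()


class _BuiltinBackend:
    """Gapless position-specific scoring (log2-odds, Laplace-smoothed)."""

    name = "builtin"

    def __init__(self, alignment: Alignment, model_name: str):
        counts = np.zeros((alignment.n_cols, 20))
        for row in alignment.rows:
            for j, ch in enumerate(row):
                k = _AA_INDEX.get(ch)
                if k is not None:
                    counts[j, k] += 1.0
        probs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 20.0)
        self.log_odds = np.log2(probs * 20.0)  # background: uniform 1/20
        self.model_name = model_name

    def _score_at(self, residues: str, offset: int) -> float:
        total = 0.0
        L = self.log_odds.shape[0]
        for i, ch in enumerate(residues):
            j = offset + i
            if 0 <= j < L:
                k = _AA_INDEX.get(ch)
                if k is not None:
                    total += self.log_odds[j, k]
        return total

    def score_many(self, segments: Mapping[str, str]) -> dict[str, HmmScore]:
        L = self.log_odds.shape[0]
        out = {}
        for key, seg in segments.items():
            m = len(seg)
            span = abs(L - m)
            if m <= L:
                best = max(self._score_at(seg, off) for off in range(span + 1))
            else:
                best = max(self._score_at(seg[off:off + L], 0) for off in range(span + 1))
            out[key] = HmmScore(best)
        return out

    def serialize(self) -> str:
        return json.dumps(
            {"model_name": self.model_name, "log_odds": self.log_odds.tolist()}
        )


@dataclass
class ProfileModel:
    """A reaction-type profile over a concatenated Area alignment."""

    reaction_type: str
    area_combo: tuple[str, ...]
    backend_name: str
    training_ids: tuple[str, ...]
    _backend: object = field(repr=False)

    def score(self, query_segment: str) -> HmmScore:
        return self.score_many({"query": query_segment})["query"]

    def score_many(self, segments: Mapping[str, str]) -> dict[str, HmmScore]:
        clean = {}
        for key, seg in segments.items():
            seg = seg.replace(GAP, "")
            if not seg:
                raise ValueError(f"empty query segment for {key!r}")
            clean[key] = seg
        return self._backend.score_many(clean)

    def serialized(self) -> str:
        """Engine-native text serialization of the profile."""
        return self._backend.serialize()

    def metadata(self) -> dict:
        return {
            "reaction_type": self.reaction_type,
            "area_combo": list(self.area_combo),
            "backend": self.backend_name,
            "training_ids": sorted(self.training_ids),
        }


def resolve_backend(backend: str = "auto") -> str:
    if backend == "auto":
        try:
            import pyhmmer  # noqa: F401

            return "pyhmmer"
        except ImportError:  # pragma: no cover - pyhmmer is a dependency
            return "builtin"
    if backend not in ("pyhmmer", "builtin"):
        raise ValueError(f"unknown profile backend {backend!r}")
    return backend


def build_area_profile(
    area_alignment: Alignment,
    reaction_type: str,
    area_combo: Sequence[str],
    backend: str = "auto",
) -> ProfileModel:
    """Build a profile from a (concatenated) Area alignment.

    Deterministic given identical input and engine version.  A single-row
    alignment is rejected: a one-sequence profile is undefined for this
    pipeline.
    """
    if area_alignment.n_rows < 2:
        raise ValueError(
            f"profile for {reaction_type} needs >= 2 training sequences, "
            f"got {area_alignment.n_rows}"
        )
    backend = resolve_backend(backend)
    name = f"{reaction_type}|{'+'.join(area_combo)}"
    if backend == "pyhmmer":
        engine = _PyhmmerBackend(area_alignment, name)
    else:
        engine = _BuiltinBackend(area_alignment, name)
    return ProfileModel(
        reaction_type=reaction_type,
        area_combo=tuple(area_combo),
        backend_name=backend,
        training_ids=tuple(area_alignment.ids),
        _backend=engine,
    )


def score_with_profile(profile: ProfileModel, query_segment: str) -> HmmScore:
    """Score one query segment; NO_MATCH and negative scores clamp to 0."""
    return profile.score(query_segment)


def best_profile_label(
    profiles: Sequence[ProfileModel],
    query_segments: str | Mapping[str, str],
) -> str:
    """Reaction type of the highest-scoring profile.

    ``query_segments`` is either a single segment string used for every
    profile (the default Area combination is shared), or a mapping from
    reaction type to segment.  Ties are broken by the fixed order
    R-4-A < R-4-C < R-2-X (then lexicographic) with a logged warning; if all
    clamped scores are zero the sentinel :data:`UNCLASSIFIED` is returned.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to predict")
    types = [p.reaction_type for p in profiles]
    if len(set(types)) != len(types):
        raise ValueError("profiles must have distinct reaction types")

    def segment_for(p: ProfileModel) -> str:
        if isinstance(query_segments, str):
            return query_segments
        return query_segments[p.reaction_type]

    scores = {p.reaction_type: p.score(segment_for(p)).clamped for p in profiles}
    if all(v == 0.0 for v in scores.values()):
        return UNCLASSIFIED
    best = max(scores.values())
    winners = [t for t, v in scores.items() if v == best]
    if len(winners) > 1:
        logger.warning("tied best profile scores among %s; fixed-order tie-break",
                       winners)

    def order_key(t: str):
        try:
            return (0, TARGET_TYPE_ORDER.index(t))
        except ValueError:
            return (1, t)

    return min(winners, key=order_key)
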
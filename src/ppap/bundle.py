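"""Trained model bundles: build once, save, reload, predict.

A bundle holds the combined labeled alignment, the AreaMap, the pipeline
configuration, the per-type model resources and the trained cascade.  On
disk it is a directory of plain-text artifacts; profiles and correlation
models are rebuilt deterministically from the stored alignment at load time
(profile builds are byte-reproducible at the pinned engine seed), while the
fitted standardizer and LDA hyperplanes are stored verbatim.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment_areas import Alignment, AreaMap, ProteinSequence, map_reference_positions
from .classify import (
    FEATURE_NAMES,
    LdaClassifier,
    PipelineConfig,
    Prediction,
    Standardizer,
    TypeResources,
    assemble_score_vector,
    apply_cascade,
    build_type_resources,
    ids_hash,
    train_cascade,
)
from .evaluate import LabeledDataset, _component_scores, _vector_from_components
from .phmm import TARGET_TYPE_ORDER

logger = logging.getLogger(__name__)


@dataclass
class PpapModel:
    """A trained four-way reaction-type predictor."""

    dataset: LabeledDataset
    config: PipelineConfig
    resources: dict  # reaction type -> TypeResources
    standardizer: Standardizer
    classifiers: dict  # reaction type -> LdaClassifier
    provenance: dict

    @classmethod
    def train(cls, dataset: LabeledDataset,
              config: PipelineConfig = PipelineConfig()) -> "PpapModel":
        area_columns = map_reference_positions(dataset.master, dataset.area_map)
        resources = {
            t: build_type_resources(dataset.type_alignment(t), area_columns,
                                    t, config)
            for t in dataset.target_types
        }
        lda_ids = list(dataset.lda_ids)
        comp = {t: _component_scores(resources[t], dataset, lda_ids)
                for t in dataset.target_types}
        vectors = [_vector_from_components(comp, i) for i in lda_ids]
        groups = [dataset.group(i) for i in lda_ids]
        standardizer, classifiers = train_cascade(vectors, groups, lda_ids)
        provenance = {
            "lda": ids_hash(lda_ids),
            **{f"model_{t}": resources[t].provenance_hash
               for t in dataset.target_types},
        }
        return cls(dataset=dataset, config=config, resources=resources,
                   standardizer=standardizer, classifiers=classifiers,
                   provenance=provenance)

    def predict(self, query: ProteinSequence) -> Prediction:
        vec = assemble_score_vector(query, self.resources,
                                    aligner=self.config.aligner)
        return apply_cascade(self.classifiers, vec, self.standardizer)

    def predict_many(self, queries: Sequence[ProteinSequence]) -> pd.DataFrame:
        rows = []
        for q in queries:
            pred = self.predict(q)
            std = self.standardizer.transform(
                pred.score_vector.as_array()[None, :]
            )[0]
            row = {"query_id": q.id, "final_label": pred.final_label}
            for t in TARGET_TYPE_ORDER:
                row[f"{t}_yes"] = pred.per_classifier[t]["yes"]
            for name, raw, s in zip(FEATURE_NAMES,
                                    pred.score_vector.as_array(), std):
                row[name] = float(raw)
                row[f"{name}_std"] = float(s)
            rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence ---------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.master.to_fasta(out / "master.aln.fa")
        self.dataset.area_map.to_json(out / "area_map.json")
        labels = pd.DataFrame(
            [{"id": i, "reaction_type": self.dataset.labels[i],
              "in_lda_fit": i in self.dataset.lda_ids}
             for i in self.dataset.labeled_ids]
        )
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        (out / "model.json").write_text(json.dumps({
            "config": self.config.to_dict(),
            "target_types": list(self.dataset.target_types),
            "standardizer": self.standardizer.to_dict(),
            "classifiers": {t: c.to_dict() for t, c in self.classifiers.items()},
            "provenance": self.provenance,
        }, indent=1) + "\n")
        profiles = out / "profiles"
        profiles.mkdir(exist_ok=True)
        for t, res in self.resources.items():
            (profiles / f"{t}.profile.txt").write_text(res.profile.serialized())
            res.corr.save(profiles / f"{t}.corr.json")
            (profiles / f"{t}.meta.json").write_text(
                json.dumps(res.profile.metadata(), indent=1) + "\n"
            )

    @classmethod
    def load(cls, in_dir: str | Path) -> "PpapModel":
        src = Path(in_dir)
        meta = json.loads((src / "model.json").read_text())
        config = PipelineConfig(
            area_combo=tuple(meta["config"]["area_combo"]),
            z_threshold=meta["config"]["z_threshold"],
            max_gap_fraction=meta["config"]["max_gap_fraction"],
            backend=meta["config"]["backend"],
            aligner=meta["config"]["aligner"],
        )
        master = Alignment.from_fasta(src / "master.aln.fa")
        area_map = AreaMap.from_json(src / "area_map.json")
        labels_df = pd.read_csv(src / "labels.tsv", sep="\t")
        labels = dict(zip(labels_df["id"], labels_df["reaction_type"]))
        lda_ids = tuple(labels_df[labels_df["in_lda_fit"]]["id"])
        dataset = LabeledDataset(
            master=master, labels=labels, area_map=area_map,
            anchor_id=area_map.reference_id,
            target_types=tuple(meta["target_types"]), lda_ids=lda_ids,
        )
        area_columns = map_reference_positions(master, area_map)
        resources = {
            t: build_type_resources(dataset.type_alignment(t), area_columns,
                                    t, config)
            for t in dataset.target_types
        }
        model = cls(
            dataset=dataset, config=config, resources=resources,
            standardizer=Standardizer.from_dict(meta["standardizer"]),
            classifiers={t: LdaClassifier.from_dict(c)
                         for t, c in meta["classifiers"].items()},
            provenance=meta["provenance"],
        )
        for t, res in resources.items():
            if res.provenance_hash != meta["provenance"][f"model_{t}"]:
                raise ValueError(
                    f"provenance mismatch for {t}: bundle was built from a "
                    "different training set"
                )
        return model
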
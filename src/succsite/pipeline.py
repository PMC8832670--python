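"""End-to-end training and prediction, and the model file format.

The trained model is a small, human-readable JSON document (a few hundred
numbers): the per-position chi-square scan, the difference table, the
selected features, the feature discretizations and the rule/decision table.
Everything prediction needs is stored, so a saved model reproduces its
fit-time decisions exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chidt import ChiDTClassifier, Condition, Rule, RuleTable
from .encoding import (
    DifferenceTable,
    KeyPositionModel,
    build_difference_table,
    encode_features,
    select_key_positions,
)
from .fragments import AMINO_ACIDS, DEFAULT_FLANK, SiteFragment
from .selection import SelectionResult, select_features

MODEL_SCHEMA = 1


@dataclass(frozen=True)
class RunConfig:
    """Knobs shared by the training pipeline and the CLI."""

    alpha: float = 0.05
    flank: int = DEFAULT_FLANK
    forced_termination: bool = True
    window: tuple[int, int] | None = None
    seed: int = 0
    max_features: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")


@dataclass
class TrainedModel:
    config: RunConfig
    key_offsets: tuple[int, ...]
    window: tuple[int, int]
    chi2_values: dict[int, float]
    chi2_ave: float
    compression_groups: dict[int, list[str]]
    difference_scores: pd.DataFrame  # residues x key offsets
    selected_features: tuple[str, ...]
    selection_scores: tuple[float, ...]
    classifier: ChiDTClassifier

    # -- training ----------------------------------------------------------

    @classmethod
    def fit(
        cls, fragments: Sequence[SiteFragment], config: RunConfig = RunConfig()
    ) -> "TrainedModel":
        """Run the full pipeline on labeled fragments.

        Stages: per-position table compression and key-position selection,
        difference-table construction, feature encoding, Chi-MIC-share
        selection, ChiDT fitting.
        """
        labels = np.array([f.label for f in fragments])
        if set(np.unique(labels)) != {0, 1}:
            raise ValueError("training fragments must contain both classes")

        key_model = select_key_positions(fragments, alpha=config.alpha)
        window = config.window or key_model.window
        key_offsets = tuple(
            off for off in key_model.key_offsets if window[0] <= off <= window[1]
        )
        if not key_offsets:
            raise ValueError("window override excludes every key position")

        table = build_difference_table(fragments, key_offsets)
        features = encode_features(fragments, table, window)
        selection = select_features(
            features,
            labels,
            alpha=config.alpha,
            forced=config.forced_termination,
            max_features=config.max_features,
        )
        retained = features[list(selection.names)]
        clf = ChiDTClassifier(alpha=config.alpha).fit(retained, labels)

        groups = {
            off: [str(lab) for lab in key_model.compressed[off].table.status_labels]
            for off in key_model.offsets
        }
        return cls(
            config=config,
            key_offsets=key_offsets,
            window=tuple(window),
            chi2_values=dict(key_model.chi2_values),
            chi2_ave=key_model.chi2_ave,
            compression_groups=groups,
            difference_scores=table.scores,
            selected_features=selection.names,
            selection_scores=selection.score_history,
            classifier=clf,
        )

    # -- prediction --------------------------------------------------------

    def _difference_table(self) -> DifferenceTable:
        return DifferenceTable(self.key_offsets, self.difference_scores, {})

    def encode(self, fragments: Sequence[SiteFragment]) -> pd.DataFrame:
        """Feature matrix for new fragments, using the frozen fit-time
        difference table and window."""
        return encode_features(fragments, self._difference_table(), self.window)

    def predict(self, fragments: Sequence[SiteFragment]) -> np.ndarray:
        features = self.encode(fragments)
        return self.classifier.predict(features[list(self.selected_features)])

    def fit_report(self) -> dict:
        """Summary of the fit: chi-square scan, selection order, rule count."""
        return {
            "version": __version__,
            "chi2_ave": self.chi2_ave,
            "key_offsets": list(self.key_offsets),
            "window": list(self.window),
            "selected_features": list(self.selected_features),
            "selection_scores": list(self.selection_scores),
            "n_rules": len(self.classifier.rule_table_.rules),
            "theta": self.classifier.rule_table_.theta,
            "chidt_feature_order": list(self.classifier.feature_order_),
        }

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        clf = self.classifier
        rules = [
            {
                "conditions": [[c.feature, c.low, c.high] for c in r.conditions],
                "pos": r.pos_count,
                "neg": r.neg_count,
                "weighted_neg": round(r.weighted_neg, 2),  # display; recomputed on load
            }
            for r in clf.rule_table_.rules
        ]
        return {
            "schema": MODEL_SCHEMA,
            "version": __version__,
            "config": {
                "alpha": self.config.alpha,
                "flank": self.config.flank,
                "forced_termination": self.config.forced_termination,
                "window": list(self.config.window) if self.config.window else None,
                "seed": self.config.seed,
                "max_features": self.config.max_features,
            },
            "key_offsets": list(self.key_offsets),
            "window": list(self.window),
            "chi2_values": {str(k): v for k, v in self.chi2_values.items()},
            "chi2_ave": self.chi2_ave,
            "compression_groups": {
                str(k): v for k, v in self.compression_groups.items()
            },
            "difference_table": {
                str(off): [float(self.difference_scores.at[a, off]) for a in AMINO_ACIDS]
                for off in self.key_offsets
            },
            "selected_features": list(self.selected_features),
            "selection_scores": list(self.selection_scores),
            "classifier": {
                "feature_order": list(clf.feature_order_),
                "discretizations": {
                    name: {
                        "values": list(d.values),
                        "bin_of_value": list(d.bin_of_value),
                        "edges": list(d.edges),
                    }
                    for name, d in clf.discretizations_.items()
                },
                "tree": clf.tree_spec_,
                "rules": rules,
                "total_pos": clf.rule_table_.total_pos,
                "total_neg": clf.rule_table_.total_neg,
                "rule_decisions": [int(d) for d in clf.rule_decisions_],
            },
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "TrainedModel":
        if doc.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
        cfg = doc["config"]
        config = RunConfig(
            alpha=cfg["alpha"],
            flank=cfg["flank"],
            forced_termination=cfg["forced_termination"],
            window=tuple(cfg["window"]) if cfg["window"] else None,
            seed=cfg["seed"],
            max_features=cfg.get("max_features"),
        )
        key_offsets = tuple(doc["key_offsets"])
        scores = pd.DataFrame(
            {off: doc["difference_table"][str(off)] for off in key_offsets},
            index=list(AMINO_ACIDS),
        )
        cdoc = doc["classifier"]
        clf = ChiDTClassifier(alpha=config.alpha)
        clf.feature_names_ = list(cdoc["feature_order"])
        clf.feature_order_ = list(cdoc["feature_order"])
        from .chidt import FeatureDiscretization

        clf.discretizations_ = {
            name: FeatureDiscretization(
                name,
                tuple(d["values"]),
                tuple(d["bin_of_value"]),
                tuple(d["edges"]),
            )
            for name, d in cdoc["discretizations"].items()
        }
        total_pos, total_neg = cdoc["total_pos"], cdoc["total_neg"]
        theta = total_pos / total_neg
        rules = tuple(
            Rule(
                conditions=tuple(Condition(f, lo, hi) for f, lo, hi in r["conditions"]),
                pos_count=r["pos"],
                neg_count=r["neg"],
                weighted_neg=r["neg"] * theta,  # full precision, not the display value
            )
            for r in cdoc["rules"]
        )
        clf.rule_table_ = RuleTable(rules, total_pos, total_neg)
        clf.rule_decisions_ = np.array(cdoc["rule_decisions"], dtype=int)
        clf.tree_spec_ = cdoc["tree"]
        return cls(
            config=config,
            key_offsets=key_offsets,
            window=tuple(doc["window"]),
            chi2_values={int(k): v for k, v in doc["chi2_values"].items()},
            chi2_ave=doc["chi2_ave"],
            compression_groups={
                int(k): v for k, v in doc["compression_groups"].items()
            },
            difference_scores=scores,
            selected_features=tuple(doc["selected_features"]),
            selection_scores=tuple(doc["selection_scores"]),
            classifier=clf,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
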
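"""Seeded random-forest classification protocol with Shapley selection.

The protocol mirrors a conservative biomarker-discovery workflow: for each
of 10 seeds the samples are split 80/20 (stratified), a random forest is
fitted on raw iBAQ values (zeros kept as zeros — this arm is deliberately
independent of the imputation used by the frequentist arm) and scored on
the held-out 20%.  A seed whose accuracy falls below 85% gets one
cross-validated grid-search rescue over a small hyper-parameter grid; seeds
that cannot be improved above 75% are discarded.  Retained models provide
per-sample class scores (out-of-bag for training samples) and per-protein
feature importances — the mean absolute Shapley attribution across samples,
averaged over retained models — with proteins above an importance of 0.15
treated as the arm's "significant" set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from ._treeshap import forest_shap_values
from .data import (
    AbundanceMatrix,
    ComparisonDesign,
    SampleAnnotation,
    TrophoError,
    ValidationError,
)

__all__ = [
    "ProtocolConfig",
    "SeedOutcome",
    "ForestProtocolResults",
    "ForestClassifierProtocol",
    "train_protocol",
    "shapley_importance",
    "cross_predict",
]


@dataclass
class ProtocolConfig:
    """Protocol constants: gates, split, grid and selection cutoff."""

    n_seeds: int = 10
    train_fraction: float = 0.8
    acc_gate: float = 0.85
    retain_gate: float = 0.75
    fi_cutoff: float = 0.15
    n_predict_models: int = 5
    cv_folds: int = 3
    base_params: dict = field(
        default_factory=lambda: {
            "n_estimators": 100,
            "max_depth": 5,
            "min_samples_split": 8,
        }
    )
    param_grid: dict = field(
        default_factory=lambda: {
            "max_depth": [3, 5],
            "min_samples_split": [8, 12],
            "n_estimators": [100, 500],
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        for name in ("acc_gate", "retain_gate", "fi_cutoff"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.n_seeds < 1 or self.n_predict_models < 1:
            raise ValidationError("n_seeds and n_predict_models must be positive")


@dataclass
class SeedOutcome:
    """One protocol seed: accuracies, tuning, retention and sample scores."""

    seed: int
    initial_accuracy: float
    tuned: bool
    final_accuracy: float
    retained: bool
    params: dict
    test_samples: list[str]
    scores: dict[str, float]  # per-sample probability of class B


def _fixed_params(config: ProtocolConfig) -> dict:
    # max_features = sqrt(n_features) per split; min leaf 3
    return {"max_features": "sqrt", "min_samples_leaf": 3}


class ForestClassifierProtocol:
    """Machine-learning arm as a fittable model over an abundance matrix."""

    def __init__(
        self,
        matrix: AbundanceMatrix,
        annotations: Sequence[SampleAnnotation],
        design: ComparisonDesign,
        config: ProtocolConfig | None = None,
    ):
        self.matrix = matrix
        self.annotations = list(annotations)
        self.design = design
        self.config = config or ProtocolConfig()
        ids_a, ids_b = design.group_samples(self.annotations)
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValidationError("need at least 2 samples per class")
        self.sample_ids = ids_a + ids_b
        self.X = matrix.data[self.sample_ids].to_numpy().T  # samples x proteins
        self.y = np.array([0] * len(ids_a) + [1] * len(ids_b))
        self.feature_names = matrix.proteins

    def _split(self, seed: int):
        """Stratified 80/20 split; re-drawn (bounded) if a class is lost."""
        for attempt in range(10):
            idx_train, idx_test = train_test_split(
                np.arange(len(self.y)),
                test_size=1.0 - self.config.train_fraction,
                stratify=self.y,
                random_state=(seed + 104729 * attempt) % 2**31,
            )
            if (
                len(np.unique(self.y[idx_train])) == 2
                and len(np.unique(self.y[idx_test])) == 2
            ):
                return idx_train, idx_test
        raise TrophoError("could not draw a split containing both classes")

    def _new_forest(self, seed: int, **params) -> RandomForestClassifier:
        merged = {**self.config.base_params, **_fixed_params(self.config), **params}
        return RandomForestClassifier(
            oob_score=True, random_state=seed, n_jobs=1, **merged
        )

    def fit(self, seed: int = 0) -> "ForestProtocolResults":
        cfg = self.config
        seed_ids = [
            int(s % 2**31)
            for s in np.random.SeedSequence(seed).generate_state(cfg.n_seeds)
        ]
        outcomes: list[SeedOutcome] = []
        models: list[RandomForestClassifier | None] = []
        for s in seed_ids:
            idx_train, idx_test = self._split(s)
            Xtr, ytr = self.X[idx_train], self.y[idx_train]
            Xte, yte = self.X[idx_test], self.y[idx_test]
            clf = self._new_forest(s)
            clf.fit(Xtr, ytr)
            initial_acc = accuracy_score(yte, clf.predict(Xte))
            tuned = False
            final_acc = initial_acc
            if initial_acc < cfg.acc_gate:
                tuned = True
                grid = GridSearchCV(
                    RandomForestClassifier(
                        **_fixed_params(cfg), random_state=s, n_jobs=1
                    ),
                    cfg.param_grid,
                    cv=StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=s),
                    n_jobs=1,
                )
                grid.fit(Xtr, ytr)
                clf = self._new_forest(s, **grid.best_params_)
                clf.fit(Xtr, ytr)
                final_acc = accuracy_score(yte, clf.predict(Xte))
            retained = final_acc > cfg.retain_gate

            # out-of-bag scores for training samples, ensemble scores for test
            scores = {}
            oob = clf.oob_decision_function_
            proba_te = clf.predict_proba(Xte)
            b_col = int(np.where(clf.classes_ == 1)[0][0])
            for row, i in enumerate(idx_train):
                sc = oob[row, b_col]
                if np.isnan(sc):  # sample in every bootstrap (rare): fall back
                    sc = clf.predict_proba(self.X[i : i + 1])[0, b_col]
                scores[self.sample_ids[i]] = float(sc)
            for row, i in enumerate(idx_test):
                scores[self.sample_ids[i]] = float(proba_te[row, b_col])

            outcomes.append(
                SeedOutcome(
                    seed=s,
                    initial_accuracy=float(initial_acc),
                    tuned=tuned,
                    final_accuracy=float(final_acc),
                    retained=bool(retained),
                    params=clf.get_params(),
                    test_samples=[self.sample_ids[i] for i in idx_test],
                    scores=scores,
                )
            )
            models.append(clf)
        return ForestProtocolResults(self, outcomes, models, master_seed=seed)


@dataclass
class ForestProtocolResults:
    """Fitted protocol: per-seed outcomes, retained models and importances."""

    model: ForestClassifierProtocol
    outcomes: list[SeedOutcome]
    models: list[RandomForestClassifier]
    master_seed: int

    @property
    def retained_models(self) -> list[RandomForestClassifier]:
        return [m for o, m in zip(self.outcomes, self.models) if o.retained]

    @property
    def n_retained(self) -> int:
        return sum(o.retained for o in self.outcomes)

    @property
    def mean_accuracy(self) -> float:
        """Average classification accuracy over retained seeds."""
        accs = [o.final_accuracy for o in self.outcomes if o.retained]
        if not accs:
            raise TrophoError("no retained models")
        return float(np.mean(accs))

    def feature_importance(self, fi_cutoff: float | None = None) -> pd.DataFrame:
        """Mean |Shapley| per protein across samples, averaged over retained
        models; ``selected`` flags importances strictly above the cutoff."""
        retained = self.retained_models
        if not retained:
            raise TrophoError("no retained models")
        cutoff = self.model.config.fi_cutoff if fi_cutoff is None else fi_cutoff
        fi = np.zeros(self.model.X.shape[1])
        for clf in retained:
            phi, _ = forest_shap_values(clf, self.model.X, class_index=1)
            fi += np.abs(phi).mean(axis=0)
        fi /= len(retained)
        return pd.DataFrame(
            {"feature_importance": fi, "selected": fi > cutoff},
            index=pd.Index(self.model.feature_names, name="protein_id"),
        )

    def shapley_attributions(self) -> list[tuple[np.ndarray, float, np.ndarray]]:
        """Per retained model: (phi samples x proteins, base value, scores)."""
        out = []
        for clf in self.retained_models:
            phi, base = forest_shap_values(clf, self.model.X, class_index=1)
            out.append((phi, base, clf.predict_proba(self.model.X)[:, 1]))
        return out

    def cross_predict(
        self, new_matrix: AbundanceMatrix, n_models: int | None = None
    ) -> pd.Series:
        """Mean class-B score of new samples over the first retained models.

        New samples must share the training feature space; proteins absent
        from the new matrix are filled with 0 (not detected).
        """
        n_models = self.model.config.n_predict_models if n_models is None else n_models
        retained = self.retained_models
        if len(retained) < n_models:
            raise TrophoError(
                f"need {n_models} retained models, have {len(retained)}"
            )
        features = self.model.feature_names
        if not set(new_matrix.proteins) & set(features):
            raise TrophoError("feature mismatch: new matrix shares no training proteins")
        Xn = new_matrix.data.reindex(features).fillna(0.0).to_numpy().T
        scores = np.zeros(Xn.shape[0])
        for clf in retained[:n_models]:
            b_col = int(np.where(clf.classes_ == 1)[0][0])
            scores += clf.predict_proba(Xn)[:, b_col]
        scores /= n_models
        return pd.Series(scores, index=new_matrix.samples, name="score")

    def report_dict(self) -> dict:
        """JSON-serialisable protocol report with config echo."""
        cfg = self.model.config
        return {
            "design": {
                "group_a": self.model.design.group_a,
                "group_b": self.model.design.group_b,
            },
            "config": {
                "n_seeds": cfg.n_seeds,
                "train_fraction": cfg.train_fraction,
                "acc_gate": cfg.acc_gate,
                "retain_gate": cfg.retain_gate,
                "fi_cutoff": cfg.fi_cutoff,
                "param_grid": cfg.param_grid,
                "master_seed": self.master_seed,
            },
            "n_retained": self.n_retained,
            "seeds": [
                {
                    "seed": o.seed,
                    "initial_accuracy": o.initial_accuracy,
                    "tuned": o.tuned,
                    "final_accuracy": o.final_accuracy,
                    "retained": o.retained,
                    "params": {
                        k: o.params[k]
                        for k in ("n_estimators", "max_depth", "min_samples_split")
                    },
                    "test_samples": o.test_samples,
                    "scores": o.scores,
                }
                for o in self.outcomes
            ],
        }

    def significant_set(self) -> pd.DataFrame:
        """Differential-style table for consensus: selected == significant.

        With no retained models every protein is reported unselected.
        """
        if self.n_retained == 0:
            return pd.DataFrame(
                {
                    "feature_importance": np.zeros(len(self.model.feature_names)),
                    "significant": False,
                    "method": "random_forest",
                },
                index=pd.Index(self.model.feature_names, name="protein_id"),
            )
        fi = self.feature_importance()
        return pd.DataFrame(
            {
                "feature_importance": fi["feature_importance"],
                "significant": fi["selected"],
                "method": "random_forest",
            },
            index=fi.index,
        )

    def summary(self) -> str:
        lines = [
            f"random-forest protocol: {self.model.design.group_b} vs "
            f"{self.model.design.group_a} (master seed {self.master_seed})",
            f"  seeds retained:  {self.n_retained}/{len(self.outcomes)}",
        ]
        if self.n_retained:
            lines.append(f"  mean accuracy:   {100 * self.mean_accuracy:.0f}%")
        for o in self.outcomes:
            lines.append(
                f"  seed {o.seed:>10}: acc {o.initial_accuracy:.2f}"
                + (f" -> tuned {o.final_accuracy:.2f}" if o.tuned else "")
                + ("  [retained]" if o.retained else "  [dropped]")
            )
        return "\n".join(lines)


def train_protocol(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    design: ComparisonDesign,
    config: ProtocolConfig | None = None,
    seed: int = 0,
) -> ForestProtocolResults:
    """Functional wrapper over :class:`ForestClassifierProtocol`."""
    return ForestClassifierProtocol(matrix, annotations, design, config).fit(seed=seed)


def shapley_importance(
    results: ForestProtocolResults, fi_cutoff: float | None = None
) -> pd.DataFrame:
    """Feature-importance table of a fitted protocol (mean |Shapley|)."""
    return results.feature_importance(fi_cutoff=fi_cutoff)


def cross_predict(
    results: ForestProtocolResults,
    new_matrix: AbundanceMatrix,
    n_models: int | None = None,
) -> pd.Series:
    """Score new samples with the first retained models of a protocol."""
    return results.cross_predict(new_matrix, n_models=n_models)
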
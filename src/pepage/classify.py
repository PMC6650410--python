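"""RBF-kernel SVM age score: training, panel reduction, and scoring.

The age model is a soft-margin support vector machine with an RBF kernel,
trained on the two extreme age groups (youngest vs oldest); intermediate and
treated samples are scored post hoc.  A sample's score is its signed
Euclidean distance to the maximal-margin hyperplane in the kernel-induced
feature space:

    score(x) = (sum_i alpha_i y_i K(x_i, x) + b) / ||w||,
    ||w||^2  = sum_ij alpha_i y_i alpha_j y_j K(x_i, x_j),

with positive scores toward the older pole.  Scoring is evaluated directly
from the stored dual coefficients and support vectors, so a serialized model
reproduces scores without retraining.

Features are log2(1 + amplitude) with missing amplitudes imputed as 0 before
the transform (an absent peptide scores as zero signal).  Panel reduction
follows the take-one-out procedure: greedy backward elimination where, at
each round, the drop yielding the highest cross-validated accuracy is kept
as long as accuracy does not decrease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import AnalysisError, ConfigurationError
from .io import CohortDesign, MatchedMatrix


@dataclass(frozen=True)
class SvmHyperparameters:
    """Soft-margin cost and RBF kernel width."""

    C: float = 3.2
    gamma: float = 0.008

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ConfigurationError(f"C must be > 0, got {self.C}")
        if not self.gamma > 0:
            raise ConfigurationError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class Preprocessing:
    """Amplitude -> feature mapping (missing -> 0, then log2(1 + a))."""

    log2_transform: bool = True
    missing_to_zero: bool = True


def rbf_kernel_matrix(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-gamma * ||a_i - b_j||^2), computed with explicit squared norms."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    sq = (
        (a**2).sum(axis=1)[:, None]
        - 2.0 * a @ b.T
        + (b**2).sum(axis=1)[None, :]
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


@dataclass
class AgeScoreModel:
    """A trained age-score SVM: panel, preprocessing and dual solution."""

    panel: list
    preprocessing: Preprocessing
    hyper: SvmHyperparameters
    support_vectors: np.ndarray          # n_sv x len(panel)
    dual_coef: np.ndarray                # signed alpha_i y_i, |.| <= C
    intercept: float
    neg_label: str                       # younger pole (score < 0)
    pos_label: str                       # older pole (score > 0)
    w_norm: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()
        if len(self.panel) == 0:
            raise ConfigurationError("panel must be non-empty")
        if self.w_norm == 0.0:
            k = rbf_kernel_matrix(
                self.support_vectors, self.support_vectors, self.hyper.gamma
            )
            self.w_norm = float(np.sqrt(self.dual_coef @ k @ self.dual_coef))

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Raw SVM decision values sum_i alpha_i y_i K(x_i, x) + b."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.support_vectors.shape[1]:
            raise AnalysisError(
                f"feature dimension {x.shape[1]} != panel size "
                f"{self.support_vectors.shape[1]}"
            )
        k = rbf_kernel_matrix(self.support_vectors, x, self.hyper.gamma)
        return self.dual_coef @ k + self.intercept

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Signed Euclidean distance to the hyperplane in kernel space."""
        return self.decision_values(x) / self.w_norm

    # -- text serialization -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "panel": [int(p) if isinstance(p, (int, np.integer)) else p for p in self.panel],
            "preprocessing": {
                "log2_transform": self.preprocessing.log2_transform,
                "missing_to_zero": self.preprocessing.missing_to_zero,
            },
            "hyperparameters": {"C": self.hyper.C, "gamma": self.hyper.gamma},
            "support_vectors": [[float(v) for v in row] for row in self.support_vectors],
            "dual_coef": [float(v) for v in self.dual_coef],
            "intercept": float(self.intercept),
            "neg_label": self.neg_label,
            "pos_label": self.pos_label,
            "w_norm": float(self.w_norm),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "AgeScoreModel":
        d = json.loads(text)
        return cls(
            panel=d["panel"],
            preprocessing=Preprocessing(**d["preprocessing"]),
            hyper=SvmHyperparameters(**d["hyperparameters"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            neg_label=d["neg_label"],
            pos_label=d["pos_label"],
            w_norm=float(d["w_norm"]),
        )

    @classmethod
    def load(cls, path) -> "AgeScoreModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def prepare_features(
    matrix: MatchedMatrix,
    panel: Sequence,
    preprocessing: Preprocessing = Preprocessing(),
) -> pd.DataFrame:
    """Samples x panel feature table from a matched matrix.

    Missing amplitudes become 0 before the log2(1 + a) transform, so an
    absent peptide contributes zero signal.  Column order follows ``panel``.
    """
    panel = list(panel)
    missing = [p for p in panel if p not in matrix.amplitudes.index]
    if missing:
        raise AnalysisError(f"panel peptide(s) absent from matrix: {missing}")
    sub = matrix.amplitudes.loc[panel].T  # samples x panel
    x = sub.to_numpy(dtype=float)
    if preprocessing.missing_to_zero:
        x = np.nan_to_num(x, nan=0.0)
    if preprocessing.log2_transform:
        x = np.log2(1.0 + x)
    return pd.DataFrame(x, index=sub.index, columns=panel)


def train_svm(
    features: pd.DataFrame,
    labels: Sequence[str],
    hyper: SvmHyperparameters = SvmHyperparameters(),
    positive_label: str | None = None,
    preprocessing: Preprocessing = Preprocessing(),
) -> AgeScoreModel:
    """Fit the soft-margin RBF SVM and package it as an :class:`AgeScoreModel`.

    ``positive_label`` names the class mapped to positive scores (the older
    pole); by default the lexicographically larger label.  Samples are sorted
    by id before fitting so the result is invariant to input row order.
    """
    labels = pd.Series(list(labels), index=features.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise AnalysisError(f"need exactly 2 classes, got {classes!r}")
    if positive_label is None:
        positive_label = classes[1]
    if positive_label not in classes:
        raise AnalysisError(f"positive_label {positive_label!r} not in {classes!r}")
    neg_label = [c for c in classes if c != positive_label][0]

    order = np.argsort(features.index.to_numpy())
    x = features.to_numpy(dtype=float)[order]
    y = np.where(labels.to_numpy()[order] == positive_label, 1, -1)
    if np.all(x == 0):
        raise AnalysisError("degenerate all-zero feature matrix")

    clf = SVC(C=hyper.C, gamma=hyper.gamma, kernel="rbf")
    clf.fit(x, y)
    return AgeScoreModel(
        panel=list(features.columns),
        preprocessing=preprocessing,
        hyper=hyper,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        neg_label=str(neg_label),
        pos_label=str(positive_label),
    )


def classification_score(model: AgeScoreModel, feature_vector) -> float:
    """Score one feature vector: signed kernel-space distance to the hyperplane."""
    v = np.asarray(feature_vector, dtype=float)
    if v.ndim != 1 or v.shape[0] != len(model.panel):
        raise AnalysisError(
            f"feature vector of length {v.shape} does not match panel size "
            f"{len(model.panel)}"
        )
    return float(model.scores(v[None, :])[0])


def _cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    hyper: SvmHyperparameters,
    cv: str | int = "auto",
    seed: int = 0,
) -> float:
    """Cross-validated accuracy of the SVM on (x, y in {-1, +1}).

    ``cv='auto'`` uses leave-one-out when the smaller class has <= 15
    members, else stratified 5-fold; an integer requests that many
    stratified folds.  Folds are deterministic given ``seed``.
    """
    n = len(y)
    min_class = min((y == 1).sum(), (y == -1).sum())
    if cv == "auto":
        cv = "loo" if min_class <= 15 else 5
    if cv == "loo":
        folds = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    else:
        k = int(cv)
        if k > min_class:
            raise ConfigurationError(
                f"cv_folds={k} exceeds the smaller class size {min_class}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr.tolist(), te.tolist()) for tr, te in skf.split(x, y)]
    correct = 0
    for tr, te in folds:
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            continue  # untestable fold; counts as wrong
        clf = SVC(C=hyper.C, gamma=hyper.gamma, kernel="rbf")
        clf.fit(x[tr], ytr)
        correct += int((clf.predict(x[te]) == y[te]).sum())
    return correct / n


def take_one_out_optimize(
    features: pd.DataFrame,
    labels: Sequence[str],
    initial_panel: Sequence | None = None,
    hyper: SvmHyperparameters = SvmHyperparameters(),
    cv: str | int = "auto",
    seed: int = 0,
    positive_label: str | None = None,
) -> AgeScoreModel:
    """Take-one-out panel reduction under cross-validation.

    Greedy backward elimination: each round tentatively drops every remaining
    peptide, evaluates cross-validated accuracy without it, and commits the
    best drop provided accuracy does not fall below the current panel's
    (ties drop the lowest master id).  Stops when every drop would hurt or a
    single peptide remains; the returned model is retrained on the final
    panel.  CV accuracy of the final panel is never below the initial one.
    """
    if initial_panel is None:
        initial_panel = list(features.columns)
    panel = list(initial_panel)
    if len(panel) < 2:
        raise ConfigurationError("initial_panel must contain >= 2 peptides")
    labels = pd.Series(list(labels), index=features.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise AnalysisError(f"need exactly 2 classes, got {classes!r}")
    pos = positive_label if positive_label is not None else classes[1]

    order = np.argsort(features.index.to_numpy())
    xfull = features.loc[:, panel].to_numpy(dtype=float)[order]
    y = np.where(labels.to_numpy()[order] == pos, 1, -1)
    col_of = {p: i for i, p in enumerate(panel)}

    def acc(cols: list) -> float:
        idx = [col_of[p] for p in cols]
        return _cv_accuracy(xfull[:, idx], y, hyper, cv=cv, seed=seed)

    current = acc(panel)
    while len(panel) > 1:
        trials = [(p, acc([q for q in panel if q != p])) for p in panel]
        best_acc = max(a for _, a in trials)
        if best_acc < current:
            break
        drop = min(p for p, a in trials if a == best_acc)
        panel.remove(drop)
        current = best_acc
    return train_svm(
        features.loc[:, panel], labels, hyper=hyper, positive_label=pos
    )


def fit_age_model(
    matrix: MatchedMatrix,
    design: CohortDesign,
    panel: Sequence,
    hyper: SvmHyperparameters = SvmHyperparameters(),
    preprocessing: Preprocessing = Preprocessing(),
    treatment: str | None = None,
    optimize: bool = False,
    cv: str | int = "auto",
    seed: int = 0,
) -> AgeScoreModel:
    """Train youngest-vs-oldest on one treatment arm; oldest pole positive."""
    young, old = design.age_order[0], design.age_order[-1]
    samples = [
        s
        for s in design.samples
        if design.age_group[s] in (young, old)
        and (treatment is None or design.treatment[s] == treatment)
    ]
    feats = prepare_features(matrix, panel, preprocessing).loc[samples]
    labels = [design.age_group[s] for s in samples]
    if optimize:
        return take_one_out_optimize(
            feats, labels, hyper=hyper, cv=cv, seed=seed, positive_label=old
        )
    return train_svm(
        feats, labels, hyper=hyper, positive_label=old, preprocessing=preprocessing
    )


def score_cohort(
    model: AgeScoreModel, matrix: MatchedMatrix, design: CohortDesign
) -> pd.DataFrame:
    """Score every sample of the cohort, grouped by (age, treatment).

    Returns a DataFrame with columns sample_id, age_group, treatment, score —
    including groups that played no part in training (middle ages, treated
    arms).
    """
    feats = prepare_features(matrix, model.panel, model.preprocessing)
    feats = feats.loc[list(design.samples)]
    scores = model.scores(feats.to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "sample_id": list(design.samples),
            "age_group": [design.age_group[s] for s in design.samples],
            "treatment": [design.treatment[s] for s in design.samples],
            "score": scores,
        }
    )
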
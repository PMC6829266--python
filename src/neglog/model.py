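"""L2-regularized logistic regression over pair instances, decision
combination, and margin-thresholded labeling.

One classifier is trained per instance kind (target, homolog) on the same
+1/-1 labels, each minimizing the primal objective

    min_w  1/2 w'w + C * sum_i log(1 + exp(-y_i w'x_i))

with an unpenalized intercept. The ridge term damps the annotation noise
that homolog knowledge transfer inevitably introduces, and the linear
model scales to genome-sized training sets.

Decision values use a signed-probability convention: with ``p`` the
posterior probability of the winning class, the decision value is ``+p``
for a positive call and ``-p`` for a negative call (boundary ``p = 0.5``
maps to the weakest positive). On this scale both labeling branches read
"the winning-class probability exceeds 0.5 + delta": predictions whose
confidence does not beat a random guess by at least ``delta`` are
returned as undetermined and excluded from downstream confusion
matrices. For a pair scored under both instance kinds, the decision with
the larger absolute value (the more confident instance) wins; on exact
ties the homolog decision is taken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .features import InstanceKind, Vocabulary

DEFAULT_C = 1.0
DEFAULT_DELTA = 0.0
#: Sentinel label for predictions inside the delta margin.
UNDETERMINED = 0

Label = Literal[-1, 0, 1]


@dataclass
class TrainingSet:
    """Feature matrix with +1/-1 labels for one instance kind."""

    instances: sp.spmatrix | np.ndarray
    labels: np.ndarray
    instance_kind: InstanceKind = "target"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.instances.shape[0] != self.labels.shape[0]:
            raise ValueError("instance count != label count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be drawn from {-1, +1}")


@dataclass
class FittedModel:
    """Weight vector, intercept and penalty of one fitted classifier."""

    weights: np.ndarray
    intercept: float
    penalty: float
    instance_kind: InstanceKind = "target"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite model parameters")
        if self.penalty <= 0:
            raise ValueError("penalty C must be > 0")

    def positive_probability(self, x: sp.spmatrix | np.ndarray) -> np.ndarray:
        x = sp.csr_matrix(x) if sp.issparse(x) else np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature length {x.shape[1]} != model length {self.weights.shape[0]}"
            )
        z = np.asarray(x @ self.weights).ravel() + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, directory: str | Path, vocab: Vocabulary) -> Path:
        """Serialize as a term-keyed weight TSV plus a JSON header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if len(vocab) != self.weights.shape[0]:
            raise ValueError("vocabulary length != weight length")
        with open(directory / f"weights_{self.instance_kind}.tsv", "wt") as fh:
            for term, w in zip(vocab.terms, self.weights):
                fh.write(f"{term}\t{float(w)!r}\n")
        header = {
            "C": self.penalty,
            "intercept": self.intercept,
            "instance_kind": self.instance_kind,
        }
        path = directory / f"model_{self.instance_kind}.json"
        path.write_text(json.dumps(header, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, directory: str | Path, instance_kind: InstanceKind, vocab: Vocabulary) -> "FittedModel":
        directory = Path(directory)
        header = json.loads((directory / f"model_{instance_kind}.json").read_text())
        weights = np.zeros(len(vocab))
        with open(directory / f"weights_{instance_kind}.tsv") as fh:
            for line in fh:
                term, w = line.rstrip("\n").split("\t")
                weights[vocab.index[term]] = float(w)
        return cls(
            weights=weights,
            intercept=float(header["intercept"]),
            penalty=float(header["C"]),
            instance_kind=header["instance_kind"],
        )


def primal_objective(
    weights: np.ndarray,
    intercept: float,
    x: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    C: float,
) -> float:
    """Value of 1/2 w'w + C sum log(1 + exp(-y(w'x + b)))."""
    weights = np.asarray(weights, dtype=float).ravel()
    margins = np.asarray(x @ weights).ravel() + intercept
    # log1p(exp(-t)) computed stably for large |t|
    t = np.asarray(y, dtype=float) * margins
    loss = np.logaddexp(0.0, -t).sum()
    return 0.5 * float(weights @ weights) + C * float(loss)


def train(ts: TrainingSet, C: float = DEFAULT_C) -> FittedModel:
    """Fit the ridge-penalized logistic model by convex minimization.

    Deterministic (quasi-Newton solve at tight tolerance); requires both
    classes present and finite features.
    """
    if C <= 0:
        raise ValueError("C must be > 0")
    if len(set(np.unique(ts.labels))) < 2:
        raise ValueError("training set must contain both classes")
    data = ts.instances.data if sp.issparse(ts.instances) else np.asarray(ts.instances)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite feature values")
    clf = LogisticRegression(
        C=C,
        solver="lbfgs",
        tol=1e-8,
        max_iter=10_000,
        fit_intercept=True,
    )
    clf.fit(ts.instances, ts.labels)
    # sklearn orders classes ascending: [-1, +1]; coef_ is for the larger.
    return FittedModel(
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        penalty=C,
        instance_kind=ts.instance_kind,
    )


def decision_value(model: FittedModel, x: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Signed-probability decision values for one or more instances.

    ``+p`` when the positive-class posterior ``p >= 0.5``, otherwise
    ``-(1 - p)`` (the negative-class posterior, negated). Values lie in
    [-1, -0.5) u [+0.5, +1].
    """
    p = model.positive_probability(x)
    return np.where(p >= 0.5, p, -(1.0 - p))


def combine_decisions(
    d_target: float | np.ndarray, d_homolog: float | np.ndarray
) -> float | np.ndarray:
    """Pick the more confident instance's decision; ties go to homolog."""
    dt = np.asarray(d_target, dtype=float)
    dh = np.asarray(d_homolog, dtype=float)
    out = np.where(np.abs(dt) > np.abs(dh), dt, dh)
    return float(out) if out.ndim == 0 else out


def assign_label(
    d_combined: float | np.ndarray, delta: float = DEFAULT_DELTA
) -> int | np.ndarray:
    """Margin-thresholded label: +1 / -1 / 0 (undetermined).

    A prediction is accepted only when its winning-class probability
    exceeds the random-guess level 0.5 by more than ``delta``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    d = np.asarray(d_combined, dtype=float)
    pos = (d > 0) & (d - 0.5 > delta)
    neg = (d < 0) & (-d - 0.5 > delta)
    out = np.where(pos, 1, np.where(neg, -1, UNDETERMINED))
    return int(out) if out.ndim == 0 else out


@dataclass
class Prediction:
    """Per-pair decision values under both instance kinds and the label."""

    d_target: float
    d_homolog: float
    d_combined: float
    label: int

    def __post_init__(self) -> None:
        if self.d_combined not in (self.d_target, self.d_homolog):
            raise ValueError("combined decision must be one of the two instances'")


Setting = Literal["combined", "target", "homolog"]
SETTINGS: tuple[Setting, ...] = ("combined", "target", "homolog")


def predict_decisions(
    vt: sp.spmatrix,
    vh: sp.spmatrix,
    target_model: FittedModel | None,
    homolog_model: FittedModel | None,
    setting: Setting = "combined",
) -> np.ndarray:
    """Decision values for encoded pairs under an experimental setting.

    ``target``/``homolog`` use one instance kind alone; ``combined``
    scores both and keeps the more confident decision per pair.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    if setting == "target":
        assert target_model is not None
        return decision_value(target_model, vt)
    if setting == "homolog":
        assert homolog_model is not None
        return decision_value(homolog_model, vh)
    assert target_model is not None and homolog_model is not None
    return np.asarray(
        combine_decisions(decision_value(target_model, vt), decision_value(homolog_model, vh))
    )
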
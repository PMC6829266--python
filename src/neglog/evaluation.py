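"""Model evaluation: the confusion-matrix metric suite, stratified
cross-validation under the three instance settings, independent tests on
labeled pair lists, and validation of candidate interaction lists with
per-evidence-channel positive rates.

Metrics are computed from an L x L confusion matrix ``M`` where
``M[i, j]`` counts class-i pairs classified as class j. Per class ``l``
the intermediates are

    p_l = M[l, l]                     (true positives for class l)
    q_l = sum_{i != l, j != l} M[i,j] (true negatives)
    r_l = sum_{i != l} M[i, l]        (false positives)
    s_l = sum_{j != l} M[l, j]        (false negatives)

giving per-class precision PR_l = p_l/(p_l+r_l), sensitivity
SE_l = p_l/(p_l+s_l) and a per-class Matthews coefficient; the overall
accuracy and MCC use the class sums of the same intermediates, and F1 is
the harmonic mean of the positive class's PR and SE. Reporting the
negative class alongside the positive one is the point: a model can look
excellent on positives while being badly biased, which only the negative
side exposes.

Undetermined predictions (inside the delta margin) are excluded from the
confusion matrix and counted separately; ROC-AUC is computed on raw
decision values before thresholding and therefore includes them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import (
    AnnotationStore,
    InstanceKind,
    Vocabulary,
    build_vocabulary,
    encode_pairs,
)
from .io_formats import PairList, ProteinPair, canonical_pair
from .model import (
    DEFAULT_C,
    DEFAULT_DELTA,
    FittedModel,
    Setting,
    TrainingSet,
    assign_label,
    predict_decisions,
    train,
)

logger = logging.getLogger("neglog")


# ---------------------------------------------------------------------------
# Confusion matrix and metric suite
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """L x L counts; row = true class, column = predicted class."""

    m: np.ndarray
    class_order: list[int] = field(default_factory=lambda: [1, -1])
    n_undetermined: int = 0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.m.ndim != 2 or self.m.shape[0] != self.m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.m.shape[0] != len(self.class_order):
            raise ValueError("class_order length != matrix size")
        if (self.m < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_predictions(
        cls,
        truth: Sequence[int],
        predicted: Sequence[int],
        class_order: Sequence[int] = (1, -1),
    ) -> "ConfusionMatrix":
        """Fill from labels, excluding undetermined (0) predictions."""
        truth = np.asarray(truth, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if truth.shape != predicted.shape:
            raise ValueError("truth/prediction length mismatch")
        keep = predicted != 0
        n_undet = int((~keep).sum())
        index = {c: k for k, c in enumerate(class_order)}
        m = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
        for t, p in zip(truth[keep], predicted[keep]):
            m[index[t], index[p]] += 1
        return cls(m=m, class_order=list(class_order), n_undetermined=n_undet)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("class orders differ")
        return ConfusionMatrix(
            m=self.m + other.m,
            class_order=list(self.class_order),
            n_undetermined=self.n_undetermined + other.n_undetermined,
        )


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


@dataclass
class ClassMetrics:
    precision: float
    sensitivity: float
    mcc: float


@dataclass
class MetricsReport:
    """Per-class PR/SE/MCC plus the pooled accuracy, MCC, F1 and AUC."""

    per_class: dict[int, ClassMetrics]
    acc: float
    overall_mcc: float
    f1_positive: float
    roc_auc: float | None = None
    n_undetermined: int = 0

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(lbl): {
                    "PR": cm.precision,
                    "SE": cm.sensitivity,
                    "MCC": cm.mcc,
                }
                for lbl, cm in self.per_class.items()
            },
            "Acc": self.acc,
            "MCC": self.overall_mcc,
            "F1": self.f1_positive,
            "ROC-AUC": self.roc_auc,
            "n_undetermined": self.n_undetermined,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_metrics(
    cm: ConfusionMatrix,
    roc_auc: float | None = None,
    positive_label: int = 1,
) -> MetricsReport:
    """Full metric suite from a confusion matrix (L >= 2 classes).

    Matthews coefficients with a zero denominator are 0 by convention,
    as are precisions/sensitivities of classes with no relevant counts.
    """
    m = cm.m
    L = m.shape[0]
    if L < 2:
        raise ValueError("need at least two classes")
    if m.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    per_class: dict[int, ClassMetrics] = {}
    p_sum = q_sum = r_sum = s_sum = 0.0
    for k, lbl in enumerate(cm.class_order):
        others = [i for i in range(L) if i != k]
        pl = float(m[k, k])
        ql = float(m[np.ix_(others, others)].sum())
        rl = float(m[others, k].sum())
        sl = float(m[k, others].sum())
        pr = _safe_div(pl, pl + rl)
        se = _safe_div(pl, pl + sl)
        mcc_den = np.sqrt((pl + rl) * (pl + sl) * (ql + rl) * (ql + sl))
        mcc = _safe_div(pl * ql - rl * sl, mcc_den)
        per_class[lbl] = ClassMetrics(precision=pr, sensitivity=se, mcc=mcc)
        p_sum += pl
        q_sum += ql
        r_sum += rl
        s_sum += sl
    acc = float(np.trace(m)) / float(m.sum())
    den = np.sqrt((p_sum + r_sum) * (p_sum + s_sum) * (q_sum + r_sum) * (q_sum + s_sum))
    overall_mcc = _safe_div(p_sum * q_sum - r_sum * s_sum, den)
    pos = per_class[positive_label]
    return MetricsReport(
        per_class=per_class,
        acc=acc,
        overall_mcc=overall_mcc,
        f1_positive=f1_score(pos.precision, pos.sensitivity),
        roc_auc=roc_auc,
        n_undetermined=cm.n_undetermined,
    )


def roc_auc(decisions: Sequence[float], truth: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative.

    Mann-Whitney formulation with ties counted 1/2; computed on raw
    decision values (no delta filtering). Both classes must be present.
    """
    truth = np.asarray(truth, dtype=int)
    decisions = np.asarray(decisions, dtype=float)
    if len(set(np.unique(truth))) < 2:
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score(truth == 1, decisions))


# ---------------------------------------------------------------------------
# Pair classifier orchestration
# ---------------------------------------------------------------------------

@dataclass
class PairClassifier:
    """Vocabulary plus the fitted target/homolog models for one setting.

    ``fit`` builds the GO vocabulary from the training pairs only (terms
    seen only at test time are discarded at encoding), encodes every
    training pair under the instance kinds the setting needs, and trains
    one classifier per kind on the same labels.
    """

    setting: Setting = "combined"
    C: float = DEFAULT_C
    vocab: Vocabulary | None = None
    target_model: FittedModel | None = None
    homolog_model: FittedModel | None = None
    training_pairs: set[ProteinPair] = field(default_factory=set)

    def _kinds(self) -> tuple[InstanceKind, ...]:
        if self.setting == "combined":
            return ("target", "homolog")
        return (self.setting,)

    def fit(
        self, positives: PairList, negatives: PairList, store: AnnotationStore
    ) -> "PairClassifier":
        if len(positives) == 0 or len(negatives) == 0:
            raise ValueError("both classes must be nonempty")
        pairs = list(positives) + list(negatives)
        labels = np.array([1] * len(positives) + [-1] * len(negatives))
        self.vocab = build_vocabulary(pairs, store)
        vt, vh = encode_pairs(pairs, store, self.vocab)
        if "target" in self._kinds():
            self.target_model = train(
                TrainingSet(instances=vt, labels=labels, instance_kind="target"), C=self.C
            )
        if "homolog" in self._kinds():
            self.homolog_model = train(
                TrainingSet(instances=vh, labels=labels, instance_kind="homolog"), C=self.C
            )
        self.training_pairs = set(pairs)
        return self

    def decisions(self, pairs: PairList | Sequence[ProteinPair], store: AnnotationStore) -> np.ndarray:
        if self.vocab is None:
            raise ValueError("classifier is not fitted")
        vt, vh = encode_pairs(list(pairs), store, self.vocab)
        return predict_decisions(vt, vh, self.target_model, self.homolog_model, self.setting)

    def predict(
        self,
        pairs: PairList | Sequence[ProteinPair],
        store: AnnotationStore,
        delta: float = DEFAULT_DELTA,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (decision values, delta-thresholded labels)."""
        d = self.decisions(pairs, store)
        return d, np.asarray(assign_label(d, delta))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _protein_fold_assignment(
    pairs: list[ProteinPair], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Protein-level folds: proteins are partitioned, a pair joins fold f
    only when both proteins fall in group f; straddling pairs are dropped
    (fold -1). Prevents shared proteins from leaking across folds."""
    proteins = sorted({p for pair in pairs for p in pair})
    group = {p: int(g) for p, g in zip(proteins, rng.integers(0, k, size=len(proteins)))}
    folds = np.full(len(pairs), -1, dtype=int)
    for i, (a, b) in enumerate(pairs):
        if group[a] == group[b]:
            folds[i] = group[a]
    return folds


def cross_validate(
    positives: PairList,
    negatives: PairList,
    store: AnnotationStore,
    k: int = 5,
    setting: Setting = "combined",
    C: float = DEFAULT_C,
    delta: float = DEFAULT_DELTA,
    rng_seed: int = 0,
    split: str = "pair",
) -> MetricsReport:
    """Stratified k-fold cross-validation pooled into one metric report.

    The vocabulary is rebuilt from each training fold only, so test-fold
    terms unseen in training are discarded exactly as they would be for
    genuinely new data. Per-fold predictions are pooled into a single
    confusion matrix before scoring; AUC is computed on the pooled raw
    decision values.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes must be nonempty")
    pairs = list(positives) + list(negatives)
    labels = np.array([1] * len(positives) + [-1] * len(negatives))

    if split == "pair":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        fold_iter = list(skf.split(np.zeros(len(pairs)), labels))
    elif split == "protein":
        rng = np.random.default_rng(rng_seed)
        assignment = _protein_fold_assignment(pairs, k, rng)
        n_dropped = int((assignment == -1).sum())
        if n_dropped:
            logger.info("protein-level split dropped %d straddling pair(s)", n_dropped)
        fold_iter = [
            (np.where((assignment != f) & (assignment != -1))[0], np.where(assignment == f)[0])
            for f in range(k)
        ]
    else:
        raise ValueError(f"unknown split {split!r}")

    pooled_cm: ConfusionMatrix | None = None
    all_decisions: list[np.ndarray] = []
    all_truth: list[np.ndarray] = []
    for train_idx, test_idx in fold_iter:
        train_labels = labels[train_idx]
        if len(set(train_labels)) < 2 or len(set(labels[test_idx])) < 2:
            raise ValueError("a fold contains a single class; use more data or fewer folds")
        clf = PairClassifier(setting=setting, C=C).fit(
            PairList(pairs=[pairs[i] for i in train_idx if labels[i] == 1], label=1),
            PairList(pairs=[pairs[i] for i in train_idx if labels[i] == -1], label=-1),
            store,
        )
        d, pred = clf.predict([pairs[i] for i in test_idx], store, delta=delta)
        cm = ConfusionMatrix.from_predictions(labels[test_idx], pred)
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
        all_decisions.append(d)
        all_truth.append(labels[test_idx])
    assert pooled_cm is not None
    auc = roc_auc(np.concatenate(all_decisions), np.concatenate(all_truth))
    return compute_metrics(pooled_cm, roc_auc=auc)


# ---------------------------------------------------------------------------
# Independent test and candidate validation
# ---------------------------------------------------------------------------

@dataclass
class IndependentTestResult:
    recall: float
    fraction_undetermined: float
    n_pairs: int


def independent_test(
    classifier: PairClassifier,
    test_pairs: PairList,
    store: AnnotationStore,
    delta: float = DEFAULT_DELTA,
) -> IndependentTestResult:
    """Recall of a single-label hold-out list, guarding against leakage.

    The list's ``label`` is the expected class for every pair; recall is
    the fraction of *determinate* predictions matching it. Any overlap
    with the classifier's training pairs is an error (listing offenders)
    rather than an optimistic number.
    """
    if test_pairs.label not in (-1, 1):
        raise ValueError("test list must carry a +1 or -1 label")
    overlap = test_pairs.pair_set & classifier.training_pairs
    if overlap:
        shown = sorted(overlap)[:10]
        raise ValueError(
            f"{len(overlap)} test pair(s) overlap the training set, e.g. {shown}"
        )
    if len(test_pairs) == 0:
        raise ValueError("empty test list")
    _, pred = classifier.predict(test_pairs, store, delta=delta)
    determinate = pred != 0
    n_det = int(determinate.sum())
    recall = float((pred[determinate] == test_pairs.label).sum() / n_det) if n_det else 0.0
    return IndependentTestResult(
        recall=recall,
        fraction_undetermined=1.0 - n_det / len(test_pairs),
        n_pairs=len(test_pairs),
    )


@dataclass
class ChannelReport:
    n_candidates: int
    n_positive: int
    n_negative: int
    n_undetermined: int

    @property
    def positive_rate(self) -> float:
        det = self.n_positive + self.n_negative
        return self.n_positive / det if det else 0.0


@dataclass
class CandidateValidation:
    channels: dict[str, ChannelReport]
    validated: PairList
    rejected: PairList

    def rates(self) -> dict[str, float]:
        return {ch: rep.positive_rate for ch, rep in self.channels.items()}


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV: protein1, protein2, channel, score."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["protein1", "protein2", "channel", "score"],
        dtype={"protein1": str, "protein2": str, "channel": str},
    )
    if len(df) == 0:
        raise ValueError(f"{path}: empty candidate file")
    return df


def validate_candidates(
    classifier: PairClassifier,
    candidates: pd.DataFrame | str | Path,
    thresholds: Mapping[str, float],
    store: AnnotationStore,
    delta: float = DEFAULT_DELTA,
) -> CandidateValidation:
    """Score an evidence-channelled candidate list.

    Candidates are first filtered by their channel's minimum score (every
    channel occurring in the list must have a threshold — an unknown
    channel name is an error), then classified; the per-channel positive
    rate is positives / (positives + negatives) with undetermined
    predictions excluded from the ratio but reported.
    """
    if not isinstance(candidates, pd.DataFrame):
        candidates = read_candidates(candidates)
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    unknown = sorted(set(candidates["channel"]) - set(thresholds))
    if unknown:
        raise ValueError(f"no threshold for channel(s): {unknown}")
    min_score = candidates["channel"].map(thresholds)
    kept = candidates[candidates["score"] >= min_score].reset_index(drop=True)
    channels: dict[str, ChannelReport] = {}
    validated: list[ProteinPair] = []
    rejected: list[ProteinPair] = []
    for channel, sub in kept.groupby("channel", sort=True):
        pairs = [canonical_pair(a, b) for a, b in zip(sub["protein1"], sub["protein2"])]
        _, pred = classifier.predict(pairs, store, delta=delta)
        channels[str(channel)] = ChannelReport(
            n_candidates=len(pairs),
            n_positive=int((pred == 1).sum()),
            n_negative=int((pred == -1).sum()),
            n_undetermined=int((pred == 0).sum()),
        )
        validated.extend(p for p, lab in zip(pairs, pred) if lab == 1)
        rejected.extend(p for p, lab in zip(pairs, pred) if lab == -1)
    return CandidateValidation(
        channels=channels,
        validated=PairList(pairs=validated, label=1, source="validated candidates"),
        rejected=PairList(pairs=rejected, label=-1, source="rejected candidates"),
    )


def co_annotation_counts(
    pairs: PairList | Sequence[ProteinPair],
    store: AnnotationStore,
    kind: InstanceKind = "target",
) -> dict[ProteinPair, int]:
    """Number of GO terms shared within each pair (report utility)."""
    return {
        canonical_pair(a, b): len(store.terms(a, kind) & store.terms(b, kind))
        for a, b in pairs
    }
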
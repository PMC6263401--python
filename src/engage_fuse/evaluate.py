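"""Evaluation protocol: splits, metric panel, and the end-to-end experiment.

Three validation schemes are exposed:

* ``holdout_70_30_contiguous`` — the first 70% (floor) of each
  participant's windows in time order train, the contiguous remaining 30%
  test; this respects the serial dependence of adjacent windows;
* ``kfold`` — stratified k-fold (default 10) over pooled windows;
* ``leave_one_participant_out`` — one split per participant.

Feature selection and class balancing are re-fit inside every training
split; test instances are never visible to either (the leakage guard the
test suite asserts). The metric panel per class: TP rate, FP rate,
precision, recall, F-measure, ROC area, PRC area and the Matthews
correlation coefficient, plus overall accuracy reported as mean +/- sd
over splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .features import extract_features, feature_columns
from .labeling import label_session
from .model import balance_weights, knn_fit, knn_predict
from .session import SessionRecording
from .simulate import SimulationConfig, generate_sessions

__all__ = [
    "SplitPlan",
    "ClassMetrics",
    "EvaluationReport",
    "make_splits",
    "compute_metrics",
    "corpus_summary",
    "ExperimentConfig",
    "ModalityResult",
    "run_experiment",
    "build_feature_table",
]

CLASSES = ("low", "high")


@dataclass(frozen=True)
class SplitPlan:
    mode: str = "kfold"  # holdout_70_30_contiguous | kfold | leave_one_participant_out
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        allowed = ("holdout_70_30_contiguous", "kfold", "leave_one_participant_out")
        if self.mode not in allowed:
            raise ValueError(f"mode must be one of {allowed}")
        if self.mode == "kfold" and self.folds < 2:
            raise ValueError("kfold needs >= 2 folds")


def make_splits(table: pd.DataFrame, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test positional index pairs under a split plan.

    Holdout: per participant, train = first floor(0.7 n) rows in table
    order, test = the contiguous remainder (participants need >= 10
    windows). K-fold is stratified by class and partitions every instance
    into exactly one test fold.
    """
    n = len(table)
    if plan.mode == "holdout_70_30_contiguous":
        train, test = [], []
        for _, grp in table.groupby("participant_id", sort=False):
            if len(grp) < 10:
                raise ValueError(
                    f"participant {grp['participant_id'].iloc[0]!r} has only "
                    f"{len(grp)} windows; holdout needs >= 10"
                )
            cut = int(np.floor(0.7 * len(grp)))
            idx = grp.index.to_numpy()
            pos = table.index.get_indexer(idx)
            train.append(pos[:cut])
            test.append(pos[cut:])
        return [(np.concatenate(train), np.concatenate(test))]
    if plan.mode == "kfold":
        y = table["label"].to_numpy()
        skf = StratifiedKFold(n_splits=plan.folds, shuffle=True, random_state=plan.seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
    # leave one participant out
    pids = table["participant_id"].to_numpy()
    splits = []
    for pid in pd.unique(pids):
        te = np.flatnonzero(pids == pid)
        tr = np.flatnonzero(pids != pid)
        splits.append((tr, te))
    return splits


# --------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ClassMetrics:
    tp_rate: float
    fp_rate: float
    precision: float
    recall: float
    f_measure: float
    roc_area: float
    prc_area: float
    mcc: float


@dataclass
class EvaluationReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    confusion: pd.DataFrame  # rows = truth, cols = predicted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: vars(m) for c, m in self.per_class.items()}
        ).T.rename_axis("class")


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def compute_metrics(truth, predicted, scores) -> EvaluationReport:
    """Full per-class metric panel from labels and positive-class scores.

    ``scores`` are P(high); the low class is scored with their complement.
    With single-class truth the ROC/PRC/MCC entries are NaN (with a
    warning) — they are undefined.
    """
    y = np.asarray(truth)
    p = np.asarray(predicted)
    s = np.asarray(scores, dtype=float)
    if not (len(y) == len(p) == len(s)):
        raise ValueError("truth, predictions and scores must have equal length")
    single_class = len(np.unique(y)) < 2
    if single_class:
        warnings.warn("single-class truth: ROC/PRC/MCC are undefined", stacklevel=2)

    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for t in CLASSES:
        for q in CLASSES:
            conf.loc[t, q] = int(np.sum((y == t) & (p == q)))
    tp_h = conf.loc["high", "high"]
    tn_h = conf.loc["low", "low"]
    fp_h = conf.loc["low", "high"]
    fn_h = conf.loc["high", "low"]
    denom = np.sqrt(
        float(tp_h + fp_h) * (tp_h + fn_h) * (tn_h + fp_h) * (tn_h + fn_h)
    )
    mcc = (tp_h * tn_h - fp_h * fn_h) / denom if denom > 0 else np.nan

    per_class = {}
    for c in CLASSES:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = conf.to_numpy().sum() - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        sc = s if c == "high" else 1.0 - s
        if single_class:
            roc = prc = np.nan
        else:
            roc = float(roc_auc_score((y == c).astype(int), sc))
            prc = float(average_precision_score((y == c).astype(int), sc))
        per_class[c] = ClassMetrics(
            tp_rate=rec,
            fp_rate=_safe_div(fp, fp + tn),
            precision=prec,
            recall=rec,
            f_measure=_safe_div(2 * prec * rec, prec + rec),
            roc_area=roc,
            prc_area=prc,
            mcc=float(mcc) if not np.isnan(mcc) else np.nan,
        )
    return EvaluationReport(per_class, float(np.mean(y == p)), conf)


def corpus_summary(labels) -> pd.DataFrame:
    """Class counts, weights and percentages of a labeled corpus."""
    y = np.asarray(labels)
    y = y[np.isin(y, CLASSES)]
    rows = []
    for c in CLASSES:
        n = int(np.sum(y == c))
        rows.append(dict(label=c, count=n, weight=float(n), percentage=100.0 * n / len(y)))
    return pd.DataFrame(rows).set_index("label")


# --------------------------------------------------------------------------
# end-to-end experiment


@dataclass(frozen=True)
class ExperimentConfig:
    sim: SimulationConfig
    modalities: tuple[str, ...] = ("hybrid", "eeg", "ecg", "nirs")
    split: SplitPlan = SplitPlan()
    k: int = 9


@dataclass
class ModalityResult:
    report: EvaluationReport
    fold_accuracies: np.ndarray
    selected_counts: dict[str, int] = field(default_factory=dict)

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def build_feature_table(
    sessions: list[SessionRecording], labels_by_session: list[pd.DataFrame] | None = None
) -> pd.DataFrame:
    """Label every session and pool the hybrid feature tables.

    Stand-alone modality runs reuse these rows by column subsetting, so all
    modalities are compared on exactly the same windows.
    """
    tables = []
    for i, sess in enumerate(sessions):
        labels = labels_by_session[i] if labels_by_session is not None else label_session(sess)
        tables.append(extract_features(sess, labels, "hybrid"))
    return pd.concat(tables, ignore_index=True)


def evaluate_modality(
    table: pd.DataFrame,
    modality: str,
    splits: list[tuple[np.ndarray, np.ndarray]],
    k: int = 9,
) -> ModalityResult:
    """Balance + CFS + KNN over the given splits for one modality.

    Balancing weights and the selected feature subset are recomputed from
    each training split alone.
    """
    cols = feature_columns(modality)
    fold_acc, selected_counts = [], {}
    pooled_truth, pooled_pred, pooled_scores = [], [], []
    for tr, te in splits:
        train, test = table.iloc[tr], table.iloc[te]
        bw = balance_weights(train["label"].to_numpy())
        selected = model_mod.cfs_select_table(train, cols)
        if not selected:  # no informative column survived: fall back to all
            selected = cols
        for s in selected:
            selected_counts[s] = selected_counts.get(s, 0) + 1
        m = knn_fit(
            train[selected].to_numpy(float),
            train["label"].to_numpy(),
            bw.weights,
            k=k,
            feature_names=selected,
        )
        pred, score = knn_predict(m, test[selected].to_numpy(float))
        truth = test["label"].to_numpy()
        fold_acc.append(float(np.mean(pred == truth)))
        pooled_truth.append(truth)
        pooled_pred.append(pred)
        pooled_scores.append(score)
    report = compute_metrics(
        np.concatenate(pooled_truth),
        np.concatenate(pooled_pred),
        np.concatenate(pooled_scores),
    )
    return ModalityResult(report, np.array(fold_acc), selected_counts)


def run_experiment(config: ExperimentConfig) -> dict[str, ModalityResult]:
    """Simulate, label, extract, then balance/select/classify per modality.

    Returns one :class:`ModalityResult` per requested modality. The split
    plan (and therefore the train-only selection) is shared across
    modalities so their accuracies are paired.
    """
    sessions = generate_sessions(config.sim)
    table = build_feature_table(sessions)
    splits = make_splits(table, config.split)
    return {
        mod: evaluate_modality(table, mod, splits, k=config.k)
        for mod in config.modalities
    }
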
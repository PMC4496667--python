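"""Evaluation: confusion metrics, ROC AUC, F1 threshold scan, LOOCV driver,
and the single-nearest-neighbour (1NN) baseline with Tc-binned comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "f1_threshold_scan",
    "loocv",
    "one_nn_baseline",
    "OneNnResult",
    "adjusted_hit_rate",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """ACC, SEN, SPE, PRE, F1 (AUC optional); undefined ratios are NaN."""

    ACC: float
    SEN: float
    SPE: float
    PRE: float
    F1: float
    AUC: float = float("nan")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(bool)
    yp = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        TP=int((yt & yp).sum()),
        TN=int((~yt & ~yp).sum()),
        FP=int((~yt & yp).sum()),
        FN=int((yt & ~yp).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision and F1 from a confusion table."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.TP + counts.TN) / counts.total
    sen = _ratio(counts.TP, counts.TP + counts.FN, "SEN")
    spe = _ratio(counts.TN, counts.TN + counts.FP, "SPE")
    pre = _ratio(counts.TP, counts.TP + counts.FP, "PRE")
    if np.isnan(sen) or np.isnan(pre) or (pre + sen) == 0:
        f1 = float("nan") if (np.isnan(sen) or np.isnan(pre)) else 0.0
    else:
        f1 = 2 * pre * sen / (pre + sen)
    return MetricReport(ACC=acc, SEN=sen, SPE=spe, PRE=pre, F1=f1, AUC=auc)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney statistic); ties averaged."""
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def f1_threshold_scan(scores, labels) -> tuple[float, float]:
    """Best F1 over thresholds scanned at the observed score values.

    A pair is positive when ``score > threshold``; among thresholds with the
    maximal F1 the smallest is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size == 0:
        raise ValueError("empty score vector")
    cand = np.unique(s)
    # evaluate candidates just below each observed value so every observed
    # score can be called positive; include the max (nothing called)
    n_pos = y.sum()
    best_t, best_f1 = cand[0], -1.0
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tp_cum = np.cumsum(ys)
    # for threshold t = cand[i], predicted positives are scores > t
    for t in cand:
        k = int(np.searchsorted(-ss, -t, side="left"))  # count of scores > t
        tp = int(tp_cum[k - 1]) if k > 0 else 0
        fp = k - tp
        fn = int(n_pos - tp)
        if tp == 0:
            f1 = 0.0
        else:
            pre = tp / (tp + fp)
            sen = tp / (tp + fn)
            f1 = 2 * pre * sen / (pre + sen)
        if f1 > best_f1:
            best_t, best_f1 = float(t), float(f1)
    return best_t, best_f1


def loocv(clf, X, y, refit_thresholds: bool = True) -> pd.DataFrame:
    """Leave-one-interaction-out cross-validation of a WES classifier.

    Each labeled pair is scored with all trainable per-protein state refit
    with that pair excluded (a held-out positive is dropped from its
    protein's ensemble; enrichment weights, feature selection and the
    protein's null-calibration point are recomputed exactly).  The global
    cutoffs and decision thresholds are selected on the pooled held-out
    scores, matching the training protocol.  Order-independent.
    """
    from sklearn.base import clone

    pairs = _as_pair_frame(X, y)
    if pairs.shape[0] < 2 or pairs["label"].nunique() < 2:
        raise ValueError("LOOCV needs at least two pairs and both classes")
    model = clone(clf)
    model.fit(X, y)
    return model.score_pairs_heldout(pairs, refit_thresholds=refit_thresholds)


def _as_pair_frame(X, y=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
        if "protein_id" not in df.columns:
            df.columns = ["protein_id", "ligand_id"][: df.shape[1]]
    else:
        df = pd.DataFrame(np.asarray(X, dtype=object), columns=["protein_id", "ligand_id"])
    if y is not None:
        df = df.assign(label=np.asarray(y).astype(int))
    return df.reset_index(drop=True)


@dataclass
class OneNnResult:
    """1NN baseline output with the Tc-binned WES comparison."""

    table: pd.DataFrame            # per-pair: max_tc, label, call_1nn, call_wes
    threshold_1nn: float
    bins: np.ndarray
    tp_rate_wes: np.ndarray        # per-bin TP / positives in bin
    tp_rate_1nn: np.ndarray
    tp_count_wes: np.ndarray
    tp_count_1nn: np.ndarray
    positives_per_bin: np.ndarray
    adjusted_hit_rate_wes: float
    adjusted_hit_rate_1nn: float


def adjusted_hit_rate(confirmed: int, predicted: int) -> float:
    """Add-one-smoothed hit rate (confirmed + 1) / (predicted + 1).

    The added count keeps zero-prediction cases distinguishable: no
    predictions gives 1 (uninformative) rather than 0/0.
    """
    if predicted == 0:
        warnings.warn("no predictions made; adjusted hit rate of 1 is uninformative")
    return (confirmed + 1) / (predicted + 1)


def one_nn_baseline(max_tc, labels, wes_calls, bin_width: float = 0.05,
                    threshold: float | None = None) -> OneNnResult:
    """Nearest-neighbour baseline: call a pair by its maximum unweighted Tc.

    ``max_tc`` holds, per pair, the highest Tanimoto coefficient between the
    query and the target's ligand set.  The 1NN threshold is chosen at its
    own F1 optimum unless supplied.  True-positive rates of WES and 1NN are
    tabulated in Tc bins of width ``bin_width`` over [0, 1].
    """
    tc = np.asarray(max_tc, dtype=float)
    y = np.asarray(labels).astype(int)
    wes = np.asarray(wes_calls).astype(bool)
    if threshold is None:
        threshold, _ = f1_threshold_scan(tc, y)
    call_1nn = tc > threshold
    edges = np.round(np.arange(0.0, 1.0 + bin_width, bin_width), 10)
    which = np.clip(np.digitize(tc, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    pos_bin = np.zeros(n_bins, dtype=int)
    tp_wes = np.zeros(n_bins, dtype=int)
    tp_1nn = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        in_bin = which == b
        pos = in_bin & (y == 1)
        pos_bin[b] = int(pos.sum())
        tp_wes[b] = int((pos & wes).sum())
        tp_1nn[b] = int((pos & call_1nn).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_wes = np.where(pos_bin > 0, tp_wes / np.maximum(pos_bin, 1), np.nan)
        rate_1nn = np.where(pos_bin > 0, tp_1nn / np.maximum(pos_bin, 1), np.nan)
    table = pd.DataFrame({"max_tc": tc, "label": y,
                          "call_1nn": call_1nn, "call_wes": wes})
    ahr_wes = adjusted_hit_rate(int((wes & (y == 1)).sum()), int(wes.sum()))
    ahr_1nn = adjusted_hit_rate(int((call_1nn & (y == 1)).sum()), int(call_1nn.sum()))
    return OneNnResult(table=table, threshold_1nn=float(threshold),
                       bins=edges, tp_rate_wes=rate_wes, tp_rate_1nn=rate_1nn,
                       tp_count_wes=tp_wes, tp_count_1nn=tp_1nn,
                       positives_per_bin=pos_bin,
                       adjusted_hit_rate_wes=ahr_wes,
                       adjusted_hit_rate_1nn=ahr_1nn)
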
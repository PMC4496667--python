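"""Per-ensemble feature weighting by statistical enrichment.

Each feature of a protein's ligand ensemble is tested for enrichment against
the background incidence in the full training ligand library: a one-sided
Fisher exact test for binary fingerprint bits, a two-sample Wilcoxon rank-sum
test for continuous descriptors.  P-values are adjusted to q-values
(Benjamini-Hochberg) and converted to non-negative weights that are zero at
or above the significance threshold (default q = 0.05) and strictly
decreasing in q below it:

    w(q) = -log10(q)   for q < q_threshold,   0 otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureWeights",
    "binary_feature_pvalues",
    "continuous_feature_pvalues",
    "adjust_pvalues",
    "compute_weights",
    "select_features",
    "optimize_feature_count",
]

_Q_FLOOR = 1e-300  # guards log10 of an exactly-zero q-value


@dataclass
class FeatureWeights:
    """Learned enrichment weights for one (protein, channel)."""

    protein_id: str
    channel: str
    p_values: np.ndarray
    q_values: np.ndarray
    weights: np.ndarray
    selected_idx: np.ndarray
    q_threshold: float = 0.05


def binary_feature_pvalues(ensemble_fp, background_fp, background_includes_set=True,
                           set_indices=None) -> np.ndarray:
    """One-sided Fisher exact p-values for over-representation of each bit.

    For bit i the 2x2 table is [bit on/off] x [in set / in background-minus-
    set]; the over-representation tail equals the hypergeometric survival
    function and is computed exactly, vectorised over bits.

    ``background_fp`` is the full training library; when it still contains the
    ensemble rows (``background_includes_set=True``) the set's counts are
    subtracted so the table margins stay disjoint.
    """
    E = np.asarray(ensemble_fp, dtype=int)
    Bg = np.asarray(background_fp, dtype=int)
    if E.ndim != 2 or Bg.ndim != 2 or E.shape[1] != Bg.shape[1]:
        raise ValueError("ensemble and background must be 2-D with equal column counts")
    if E.shape[0] == 0:
        raise ValueError("empty ensemble")
    n_set = E.shape[0]
    k = E.sum(axis=0)                      # bit on in set
    if background_includes_set:
        M = Bg.shape[0]
        K = Bg.sum(axis=0)                 # bit on in whole library
    else:
        M = Bg.shape[0] + n_set
        K = Bg.sum(axis=0) + k
    # P(X >= k) with X ~ Hypergeom(M, K, n_set)
    p = stats.hypergeom.sf(k - 1, M, K, n_set)
    absent = K == 0
    if absent.any():
        logger.debug("%d bits absent from the entire library; p = 1 by convention",
                     int(absent.sum()))
        p = np.where(absent, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def continuous_feature_pvalues(ensemble_desc, background_desc, exact_max_n: int = 8) -> np.ndarray:
    """Two-sample Wilcoxon rank-sum p-values per descriptor.

    ``background_desc`` is the background *minus* the ensemble rows.  The
    exact null distribution is used when both groups have at most
    ``exact_max_n`` samples and the column is tie-free; otherwise the
    tie-corrected normal approximation.  Zero-variance columns get p = 1.
    """
    X = np.asarray(ensemble_desc, dtype=float)
    Y = np.asarray(background_desc, dtype=float)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if X.shape[0] == 1:
        warnings.warn("ensemble of size 1: rank-sum test has very low power")
    n_feat = X.shape[1]
    p = np.ones(n_feat)
    pooled = np.vstack([X, Y])
    varying = np.ptp(pooled, axis=0) > 0
    if not varying.all():
        logger.debug("%d zero-variance descriptors; p = 1", int((~varying).sum()))
    cols = np.where(varying)[0]
    if cols.size == 0:
        return p
    use_exact = X.shape[0] <= exact_max_n and Y.shape[0] <= exact_max_n
    if use_exact:
        for j in cols:
            xj, yj = X[:, j], Y[:, j]
            has_ties = np.unique(np.concatenate([xj, yj])).size < xj.size + yj.size
            method = "asymptotic" if has_ties else "exact"
            p[j] = stats.mannwhitneyu(xj, yj, alternative="two-sided", method=method).pvalue
    else:
        res = stats.mannwhitneyu(X[:, cols], Y[:, cols], alternative="two-sided",
                                 method="asymptotic", axis=0)
        p[cols] = res.pvalue
    return np.clip(p, 0.0, 1.0)


def adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values; order-preserving, in [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compute_weights(q_values, q_threshold: float = 0.05) -> np.ndarray:
    """Map q-values to non-negative enrichment weights.

    Zero at or above the threshold, ``-log10(q)`` below it — strictly
    decreasing in q over the significant range.
    """
    q = np.asarray(q_values, dtype=float)
    w = np.where(q < q_threshold, -np.log10(np.clip(q, _Q_FLOOR, 1.0)), 0.0)
    if not (w > 0).any():
        warnings.warn("no feature significant at q < %g; all weights zero" % q_threshold)
    return w


def select_features(weights, m: int) -> np.ndarray:
    """Indices of the m largest weights, ties broken by ascending index.

    Only features with positive weight are eligible; if fewer than m exist
    the shortfall is logged and all positive-weight features are returned.
    """
    w = np.asarray(weights, dtype=float)
    if m < 1:
        raise ValueError("m must be positive")
    nonzero = int((w > 0).sum())
    if nonzero == 0:
        warnings.warn("all-zero weights: empty feature selection")
        return np.array([], dtype=int)
    if m > nonzero:
        logger.debug("requested m=%d but only %d features have weight > 0", m, nonzero)
        m = nonzero
    # stable sort on (-weight, index)
    order = np.lexsort((np.arange(w.size), -w))
    return np.sort(order[:m])


def optimize_feature_count(candidate_ms, objective) -> int:
    """Grid-search the retained-feature count m.

    ``objective(m)`` returns a score to maximise (default pipelines use the
    leave-one-out F1 of the per-protein retrieval task); ties and an entirely
    flat profile resolve to the smallest candidate m.
    """
    ms = sorted(set(int(m) for m in candidate_ms))
    if not ms:
        raise ValueError("empty candidate grid")
    best_m, best_val = None, -np.inf
    failures = []
    for m in ms:
        try:
            val = float(objective(m))
        except Exception as exc:  # noqa: BLE001 - objective is caller code
            failures.append((m, exc))
            continue
        if val > best_val:
            best_m, best_val = m, val
    if best_m is None:
        raise RuntimeError(f"objective failed on every candidate m: {failures}")
    return best_m


def make_retrieval_objective(ensemble_fp, background_fp, weights, rng=None,
                             n_background_sample: int = 100):
    """Default objective for :func:`optimize_feature_count` (binary channel).

    For a given m, selects the top-m weighted bits and scores each ensemble
    ligand by its mean weighted Tanimoto to the rest of the set (leave-one-out)
    and each of a fixed background sample by its mean weighted Tanimoto to the
    whole set; returns the best-F1 separation of the two groups.
    """
    from .evaluate import f1_threshold_scan
    from .similarity import weighted_tanimoto_matrix

    E = np.asarray(ensemble_fp)
    Bg = np.asarray(background_fp)
    rng = np.random.default_rng(rng)
    if Bg.shape[0] > n_background_sample:
        Bg = Bg[rng.choice(Bg.shape[0], n_background_sample, replace=False)]

    def objective(m: int) -> float:
        idx = select_features(weights, m)
        if idx.size == 0:
            return 0.0
        S_pos = weighted_tanimoto_matrix(E, E, weights, idx)
        np.fill_diagonal(S_pos, np.nan)
        pos = np.nanmean(S_pos, axis=1)
        neg = weighted_tanimoto_matrix(Bg, E, weights, idx).mean(axis=1)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
        _, f1 = f1_threshold_scan(scores, labels)
        return f1

    return objective
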
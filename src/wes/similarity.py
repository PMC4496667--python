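"""Weighted pairwise similarities and ensemble raw scores.

Two channels share one contract: a similarity in [0, 1] between a query
molecule and each member of a protein's ligand ensemble, restricted to the
ensemble's selected (enriched) features and weighted by their enrichment
weights.  The *raw score* of a query against an ensemble is the sum of its
pairwise similarities at or above the cutoff ``s_cut``; scores below the
cutoff are discarded and do not contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "weighted_tanimoto",
    "weighted_cosine",
    "tanimoto_matrix",
    "weighted_tanimoto_matrix",
    "weighted_cosine_matrix",
    "raw_score",
    "raw_score_profile",
    "RawScore",
    "S_CUT_GRID",
]

#: the similarity-cutoff scan grid, step 0.01 on the open interval (0, 1)
S_CUT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class RawScore:
    """Ensemble raw score of one (query, protein, channel) triple."""

    ligand_id: str
    protein_id: str
    channel: str
    value: float
    n_contributing: int


def _as_selected(v: np.ndarray, idx) -> np.ndarray:
    v = np.asarray(v)
    return v if idx is None else v[np.asarray(idx, dtype=int)]


def weighted_tanimoto(a, b, w=None, idx=None) -> float:
    """Weighted Tanimoto coefficient between two binary vectors.

    Computes ``sum_i w_i (a_i AND b_i) / sum_i w_i (a_i OR b_i)`` over the
    selected feature indices ``idx`` (all features when None).  With equal
    weights this reduces to the classic Tanimoto coefficient.  An empty
    OR-support (no weighted bit set in either vector) yields 0 by convention.
    """
    a = _as_selected(a, idx).astype(bool)
    b = _as_selected(b, idx).astype(bool)
    if w is None:
        w = np.ones(a.shape[0])
    else:
        w = _as_selected(w, idx).astype(float)
    union = float(w[a | b].sum())
    if union == 0.0:
        warnings.warn("empty weighted OR-support; similarity 0 by convention")
        return 0.0
    return float(w[a & b].sum()) / union


def weighted_cosine(x, y, w=None, idx=None, clip_negative: bool = True) -> float:
    """Weighted cosine similarity between two real vectors.

    The weights enter elementwise (``w*x`` vs ``w*y``); negative cosines are
    clipped to 0 so both channels share the (0, 1) cutoff domain.  A zero-norm
    weighted vector yields 0 with a warning.
    """
    x = _as_selected(x, idx).astype(float)
    y = _as_selected(y, idx).astype(float)
    if w is not None:
        w = _as_selected(w, idx).astype(float)
        x = w * x
        y = w * y
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("zero-norm weighted vector; similarity 0 by convention")
        return 0.0
    s = float(np.dot(x, y) / (nx * ny))
    if clip_negative:
        s = max(s, 0.0)
    return s


def tanimoto_matrix(A, B) -> np.ndarray:
    """Unweighted Tanimoto coefficients between the rows of two binary matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def weighted_tanimoto_matrix(A, B, w=None, idx=None) -> np.ndarray:
    """Row-pairwise weighted Tanimoto between two binary matrices.

    ``A`` is (p, B_total), ``B`` is (n, B_total); the result is (p, n).
    """
    Asel = np.asarray(A, dtype=float) if idx is None else np.asarray(A, dtype=float)[:, idx]
    Bsel = np.asarray(B, dtype=float) if idx is None else np.asarray(B, dtype=float)[:, idx]
    if w is None:
        w = np.ones(Asel.shape[1])
    else:
        w = np.asarray(w, dtype=float)
        if idx is not None and w.shape[0] != Asel.shape[1]:
            w = w[idx]
    inter = (Asel * w) @ Bsel.T
    sa = Asel @ w
    sb = Bsel @ w
    union = sa[:, None] + sb[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def weighted_cosine_matrix(X, Y, w=None, idx=None, clip_negative: bool = True) -> np.ndarray:
    """Row-pairwise weighted cosine between two real matrices, negatives clipped."""
    Xs = np.asarray(X, dtype=float) if idx is None else np.asarray(X, dtype=float)[:, idx]
    Ys = np.asarray(Y, dtype=float) if idx is None else np.asarray(Y, dtype=float)[:, idx]
    if w is not None:
        w = np.asarray(w, dtype=float)
        if idx is not None and w.shape[0] != Xs.shape[1]:
            w = w[idx]
        Xs = Xs * w
        Ys = Ys * w
    nx = np.linalg.norm(Xs, axis=1)
    ny = np.linalg.norm(Ys, axis=1)
    dot = Xs @ Ys.T
    denom = nx[:, None] * ny[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, dot / denom, 0.0)
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return out


def raw_score(similarities, s_cut: float) -> tuple[float, int]:
    """Sum the pairwise similarities at or above ``s_cut``.

    Returns ``(value, n_contributing)``.  An empty contribution gives (0, 0).
    """
    s = np.asarray(similarities, dtype=float)
    mask = s >= s_cut
    return float(s[mask].sum()), int(mask.sum())


def raw_score_profile(similarities, grid=S_CUT_GRID) -> np.ndarray:
    """Raw score at every cutoff of the grid, vectorised.

    Monotone non-increasing in ``s_cut`` by construction.
    """
    s = np.sort(np.asarray(similarities, dtype=float))[::-1]
    csum = np.concatenate([[0.0], np.cumsum(s)])
    # number of sims >= g for each grid value
    counts = np.searchsorted(-s, -np.asarray(grid), side="right")
    return csum[counts]
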
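"""Bayesian fusion of the two channel Z-scores.

The hybrid model treats the pair (z_binary, z_continuous) of a drug-target
pair as a point in the plane and estimates the class-conditional densities
P(z1, z2 | binder) and P(z1, z2 | non-binder) with a joint two-dimensional
Gaussian kernel density estimate.  The posterior probability of binding,

    L = pi_+ f_+(z) / (pi_+ f_+(z) + pi_- f_-(z)),

is the likelihood score; a pair is called a binder when L exceeds the
threshold theta, itself selected by the same highest-F1 scan used for the
single-channel Z thresholds.

The KDE uses a full d x d bandwidth matrix H = factor^2 * Cov(points), with
Scott's or Silverman's factor (both n^(-1/(d+4))-type rules, d = 2) or a
user-fixed H.  A singular sample covariance falls back to a diagonal H with
floored variances so the density stays finite everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["KdeClassDensity", "fit_kde", "likelihood", "choose_theta"]

_VAR_FLOOR = 1e-6


@dataclass
class KdeClassDensity:
    """Gaussian-kernel class-conditional density over (z1, z2) points."""

    class_label: str
    points: np.ndarray          # (n, d) training points
    H: np.ndarray               # (d, d) bandwidth matrix, symmetric PD
    n: int = field(init=False)
    _chol: np.ndarray = field(init=False, repr=False)
    _norm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.H = np.asarray(self.H, dtype=float)
        self.n = self.points.shape[0]
        d = self.points.shape[1]
        self._chol = np.linalg.cholesky(self.H)
        det = float(np.prod(np.diag(self._chol))) ** 2
        self._norm = 1.0 / ((2 * np.pi) ** (d / 2) * np.sqrt(det))

    def kernel_at_zero(self) -> float:
        """Kernel value K_H(0), the self-contribution of a training point."""
        return self._norm

    def evaluate(self, X) -> np.ndarray:
        """Density at each query point: mean of Gaussian kernels K_H(x - x_i)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # solve L u = (x - xi)^T for the Mahalanobis form, batched
        diff = X[:, None, :] - self.points[None, :, :]      # (q, n, d)
        u = np.linalg.solve(self._chol, diff[..., None]).squeeze(-1)
        expo = -0.5 * (u**2).sum(axis=-1)
        return self._norm * np.exp(expo).mean(axis=1)

    __call__ = evaluate


def _bandwidth_factor(rule: str, n: int, d: int) -> float:
    if rule == "scott":
        return n ** (-1.0 / (d + 4))
    if rule == "silverman":
        return (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    raise ValueError(f"unknown bandwidth rule {rule!r}")


def fit_kde(points, bandwidth_rule: str = "scott", H=None,
            class_label: str = "") -> KdeClassDensity:
    """Fit a Gaussian KDE with a full bandwidth matrix.

    ``bandwidth_rule`` is ``scott``, ``silverman`` or ``fixed`` (then ``H``
    must be supplied).  Requires n >= 2 finite points.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("KDE requires at least 2 training points")
    if not np.isfinite(P).all():
        raise ValueError("KDE training points must be finite")
    d = P.shape[1]
    if bandwidth_rule == "fixed":
        if H is None:
            raise ValueError("fixed bandwidth rule requires H")
        Hm = np.asarray(H, dtype=float)
    else:
        factor = _bandwidth_factor(bandwidth_rule, P.shape[0], d)
        cov = np.atleast_2d(np.cov(P, rowvar=False))
        Hm = factor**2 * cov
    # singular H (collinear or identical points) -> diagonal fallback
    try:
        np.linalg.cholesky(Hm)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        warnings.warn("singular bandwidth matrix; falling back to floored diagonal H")
        var = np.maximum(np.diag(np.atleast_2d(np.cov(P, rowvar=False))), _VAR_FLOOR)
        if bandwidth_rule == "fixed":
            factor = 1.0
        else:
            factor = _bandwidth_factor(bandwidth_rule, P.shape[0], d)
        Hm = np.diag(np.maximum(factor**2 * var, _VAR_FLOOR))
    return KdeClassDensity(class_label=class_label, points=P, H=Hm)


def likelihood(z, density_pos: KdeClassDensity, density_neg: KdeClassDensity,
               priors: tuple[float, float] | None = None) -> np.ndarray:
    """Posterior probability of the binder class at each (z1, z2) point.

    ``priors`` are (pi_binder, pi_nonbinder); when None, empirical class
    frequencies from the two densities' training-set sizes are used.  Where
    both densities vanish numerically the prior itself is returned.
    """
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    if priors is None:
        n_tot = density_pos.n + density_neg.n
        priors = (density_pos.n / n_tot, density_neg.n / n_tot)
    fp = priors[0] * density_pos.evaluate(Z)
    fn = priors[1] * density_neg.evaluate(Z)
    total = fp + fn
    both_zero = total <= 0
    if both_zero.any():
        warnings.warn("both class densities ~0 at %d points; returning the prior"
                      % int(both_zero.sum()))
    prior_pos = priors[0] / (priors[0] + priors[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(both_zero, prior_pos, fp / np.where(both_zero, 1.0, total))
    return L


def choose_theta(likelihoods, labels) -> tuple[float, float]:
    """Decision threshold on L maximising F1 — the same scan as for Z."""
    from .evaluate import f1_threshold_scan

    L = np.asarray(likelihoods, dtype=float)
    if np.ptp(L) == 0:
        warnings.warn("constant likelihood: degenerate threshold")
        return float(L[0]), 0.0
    return f1_threshold_scan(L, labels)
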
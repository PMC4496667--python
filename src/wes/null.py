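"""Size-calibrated random null for ensemble raw scores.

A raw score grows with the size of the ligand set it is summed over, so raw
scores of different proteins are not comparable.  The null model calibrates
this away: for each protein, the raw scores of a random ligand set (default
size 50, drawn without replacement from the full training library) give a
null mean and standard deviation; ordinary least squares across proteins
then maps ligand-set size to the null moments,

    mu(size)    = alpha1 * size + beta1
    sigma(size) = alpha2 * size + beta2

and the Z-score of a raw score s against a protein of size n is
``(s - mu(n)) / max(sigma(n), sigma_floor)``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .similarity import raw_score

__all__ = [
    "NullModel",
    "protein_seed",
    "sample_background_indices",
    "sample_random_raw_scores",
    "fit_null",
    "z_score",
    "choose_z_threshold",
]


def protein_seed(base_seed: int, protein_id: str) -> int:
    """Stable per-protein RNG seed, independent of iteration order."""
    return (int(base_seed) * 2654435761 + zlib.crc32(str(protein_id).encode())) % (2**31)


@dataclass
class NullModel:
    """Linear size calibration of the random raw-score null for one channel."""

    channel: str
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    n_random: int = 50
    sigma_floor: float = 1e-6
    r2_mu: float = float("nan")
    r2_sigma: float = float("nan")
    rng_seed: int | None = None

    def predict_mu(self, size) -> np.ndarray:
        return self.alpha1 * np.asarray(size, dtype=float) + self.beta1

    def predict_sigma(self, size) -> np.ndarray:
        s = self.alpha2 * np.asarray(size, dtype=float) + self.beta2
        return np.maximum(s, self.sigma_floor)

    def z(self, raw, size) -> np.ndarray:
        sig = self.predict_sigma(size)
        if np.any(self.alpha2 * np.asarray(size, dtype=float) + self.beta2 <= 0):
            warnings.warn("non-positive predicted sigma; floored at %g" % self.sigma_floor)
        return (np.asarray(raw, dtype=float) - self.predict_mu(size)) / sig


def sample_background_indices(n_background: int, n_random: int, seed: int) -> np.ndarray:
    """Without-replacement draw of ``n_random`` library indices, seed-reproducible."""
    if n_background < n_random:
        raise ValueError(
            f"background of {n_background} ligands cannot supply {n_random} random draws")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_background, size=n_random, replace=False))


def sample_random_raw_scores(sim_matrix, s_cut: float) -> np.ndarray:
    """Raw scores of each random ligand (row) against the ensemble (columns)."""
    S = np.asarray(sim_matrix, dtype=float)
    return np.array([raw_score(row, s_cut)[0] for row in S])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_null(sizes, null_means, null_sds, channel: str = "binary",
             n_random: int = 50, sigma_floor: float = 1e-6,
             rng_seed: int | None = None) -> NullModel:
    """Fit the two size regressions from per-protein null moments.

    Requires at least three proteins with at least two distinct ligand-set
    sizes (an all-equal design is singular).
    """
    x = np.asarray(sizes, dtype=float)
    mu = np.asarray(null_means, dtype=float)
    sd = np.asarray(null_sds, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 proteins to fit the null regressions")
    if np.unique(x).size < 2:
        raise ValueError("all ligand-set sizes equal: singular regression design")
    a1, b1, r2m = _ols_line(x, mu)
    a2, b2, r2s = _ols_line(x, sd)
    model = NullModel(channel=channel, alpha1=a1, beta1=b1, alpha2=a2, beta2=b2,
                      n_random=n_random, sigma_floor=sigma_floor,
                      r2_mu=r2m, r2_sigma=r2s, rng_seed=rng_seed)
    if np.any(model.predict_sigma(x) <= sigma_floor):
        warnings.warn("predicted sigma at or below the floor for some training sizes")
    return model


def z_score(raw_value: float, null: NullModel, set_size: int) -> float:
    """Standardise one raw score with the fitted null at the given set size."""
    return float(null.z(raw_value, set_size))


def choose_z_threshold(scores, labels) -> tuple[float, float]:
    """Threshold on a score maximising F1, scanned over the observed values.

    A pair is called positive when ``score > threshold``.  Ties resolve to the
    smallest threshold.  Returns ``(threshold, f1_at_threshold)``.
    """
    from .evaluate import f1_threshold_scan

    return f1_threshold_scan(scores, labels)
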
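"""Statistical summaries: signal-detection d-prime, visual-field quadrant
confusion, Pearson and circular correlation, paired t-tests, and FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

QUADRANTS = ("R-UVF", "L-UVF", "L-LVF", "R-LVF")  # 90 deg bins from 0 deg CCW


@dataclass
class BehavioralRecord:
    """Hit / false-alarm proportions of one subject's detection task."""

    hit_rate: float
    false_alarm_rate: float
    n_targets: int
    n_nontargets: int

    def __post_init__(self) -> None:
        if not (0 <= self.hit_rate <= 1 and 0 <= self.false_alarm_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_targets <= 0 or self.n_nontargets <= 0:
            raise ValueError("need positive trial counts")


def _correct_extreme(rate: float, n: int) -> float:
    """1/(2N) correction so the inverse-normal transform stays finite."""
    if rate <= 0:
        return 1.0 / (2 * n)
    if rate >= 1:
        return 1.0 - 1.0 / (2 * n)
    return rate


def d_prime(rec: BehavioralRecord) -> float:
    """Sensitivity d' = Z(hit) - Z(false alarm), Z the inverse standard normal
    CDF; 0 is chance, ~3 near-perfect performance.  Extreme rates are pulled
    in by the 1/(2N) rule before the transform."""
    hit = _correct_extreme(rec.hit_rate, rec.n_targets)
    fa = _correct_extreme(rec.false_alarm_rate, rec.n_nontargets)
    return float(sps.norm.ppf(hit) - sps.norm.ppf(fa))


def angle_to_quadrant(angle_deg: np.ndarray) -> np.ndarray:
    """Map polar angles in [0, 360) to visual-field quadrants.

    [0, 90) right upper, [90, 180) left upper, [180, 270) left lower,
    [270, 360) right lower (angle counterclockwise from the right horizontal
    meridian)."""
    a = np.asarray(angle_deg, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    return np.floor_divide(a, 90.0).astype(int)


def quadrant_confusion(
    true_labels: np.ndarray, fitted_angles_deg: np.ndarray
) -> tuple[np.ndarray, float]:
    """4x4 confusion matrix (rows: true quadrant, columns: fitted-angle
    quadrant) and overall accuracy = trace / total."""
    true_idx = np.asarray(true_labels, dtype=int)
    if len(true_idx) != len(fitted_angles_deg):
        raise ValueError("label/angle length mismatch")
    fit_idx = angle_to_quadrant(fitted_angles_deg)
    mat = np.zeros((4, 4), dtype=int)
    np.add.at(mat, (true_idx, fit_idx), 1)
    accuracy = float(np.trace(mat)) / len(true_idx)
    return mat, accuracy


def circular_correlation(alpha: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    """Circular-circular correlation of two angle vectors (radians).

    rho = sum sin(a - abar) sin(b - bbar) /
          sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar)),
    with circular means abar, bbar; p-value from the large-sample normal
    approximation."""
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    n = len(a)
    if n < 5 or len(b) != n:
        raise ValueError("need two equal-length vectors of >= 5 angles")
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    den = np.sqrt((sa**2).sum() * (sb**2).sum())
    if den == 0:
        raise ValueError("zero angular variance in one of the vectors")
    rho = float((sa * sb).sum() / den)
    lam20 = (sa**2).mean()
    lam02 = (sb**2).mean()
    lam22 = (sa**2 * sb**2).mean()
    tval = np.sqrt(n * lam20 * lam02 / lam22) * rho
    p = float(2 * (1 - sps.norm.cdf(abs(tval))))
    return rho, p


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need two equal-length vectors of >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired-sample t-test on the differences a - b (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) != len(a):
        raise ValueError("need two equal-length vectors of >= 2 values")
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p-values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject
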
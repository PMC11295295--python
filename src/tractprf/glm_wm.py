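"""Working-memory activation analysis.

Preprocessing (detrend + 0.01-0.1 Hz bandpass), motion-based volume censoring,
GLM estimation with a region-appropriate HRF (white-matter tracts get the
delayed-onset double-gamma, cortical/thalamic gray matter the canonical one),
and the 2-back minus 0-back contrast that indexes working-memory load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CENSOR_THRESHOLD_MM = 0.3  # Euclidean norm of frame-to-frame motion difference


@dataclass
class TaskDesign:
    """Block timing plus nuisance information for one run.

    onsets_s / durations_s / condition are per-block; motion_params is an
    (n_vol, 6) rigid-body table, csf_series an (n_vol,) nuisance regressor,
    censor_flags an (n_vol,) boolean mask of volumes to drop.
    """

    onsets_s: list
    durations_s: list
    condition: list
    tr: float
    n_vol: int
    motion_params: np.ndarray | None = None
    csf_series: np.ndarray | None = None
    censor_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.onsets_s) == len(self.durations_s) == len(self.condition)):
            raise ValueError("onsets, durations and conditions must align")
        run_end = self.n_vol * self.tr
        for o, d in zip(self.onsets_s, self.durations_s):
            if o < 0 or o + d > run_end + 1e-9:
                raise ValueError("block extends outside the run")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.n_vol, 6):
                raise ValueError("motion table must be n_vol x 6")

    @property
    def conditions(self) -> list:
        return sorted(set(self.condition))


@dataclass
class GLMResult:
    betas: dict
    contrast_2bk_0bk: float
    t_stat: float
    dof: int
    censored_count: int
    se_contrast: float = float("nan")


def convolve_regressor(
    onsets_s, durations_s, tr: float, n_vol: int, hrf, oversample: int = 16
) -> np.ndarray:
    """Boxcar at ``oversample`` x TR resolution convolved with the HRF, then
    sampled at volume acquisition times."""
    from .prf import _hrf_convolve  # shared double-gamma sampling

    dt = tr / oversample
    n_fine = n_vol * oversample
    box = np.zeros(n_fine)
    tgrid = np.arange(n_fine) * dt
    for o, d in zip(onsets_s, durations_s):
        box[(tgrid >= o) & (tgrid < o + d)] = 1.0
    conv = _hrf_convolve(box, hrf, dt)
    return conv[::oversample][:n_vol]


def preprocess(
    series: np.ndarray, tr: float, band: tuple = (0.01, 0.1)
) -> np.ndarray:
    """Linear detrend, then an ideal FFT-domain bandpass.

    Frequencies outside [band[0], band[1]] Hz are zeroed (the mean is removed
    with the trend).  Requires band[1] below the Nyquist frequency 1/(2 TR).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 20:
        raise ValueError("need at least 20 volumes")
    nyquist = 0.5 / tr
    if not (0 <= band[0] < band[1] <= nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:.3f}) Hz")
    t = np.arange(n)
    slope, intercept = np.polyfit(t, series, 1)
    detrended = series - (slope * t + intercept)
    freqs = np.fft.rfftfreq(n, d=tr)
    spectrum = np.fft.rfft(detrended)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    return np.fft.irfft(spectrum, n=n)


def censor_volumes(motion_params: np.ndarray,
                   threshold_mm: float = CENSOR_THRESHOLD_MM) -> np.ndarray:
    """Flag volume t when ||motion(t) - motion(t-1)||_2 strictly exceeds the
    threshold, and also flag t-1.  Volume 0 is never flagged by the difference
    rule alone."""
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be n_vol x 6")
    flags = np.zeros(len(motion), dtype=bool)
    enorm = np.linalg.norm(np.diff(motion, axis=0), axis=1)  # enorm[t-1] = t vs t-1
    bad = np.nonzero(enorm > threshold_mm)[0] + 1
    flags[bad] = True
    flags[bad - 1] = True
    return flags


def build_design(design: TaskDesign, hrf) -> tuple[np.ndarray, list]:
    """Design matrix: one HRF-convolved boxcar per condition, six motion
    regressors, CSF, intercept and linear drift.  Returns (matrix, names);
    censored volumes are dropped later, at estimation."""
    cols, names = [], []
    for cond in design.conditions:
        reg = convolve_regressor(
            [o for o, c in zip(design.onsets_s, design.condition) if c == cond],
            [d for d, c in zip(design.durations_s, design.condition) if c == cond],
            design.tr, design.n_vol, hrf,
        )
        cols.append(reg)
        names.append(cond)
    if design.motion_params is not None:
        for i in range(6):
            cols.append(design.motion_params[:, i])
            names.append(f"motion{i}")
    if design.csf_series is not None:
        cols.append(np.asarray(design.csf_series, dtype=float))
        names.append("csf")
    cols.append(np.ones(design.n_vol))
    names.append("intercept")
    cols.append(np.linspace(-1.0, 1.0, design.n_vol))
    names.append("drift")
    x = np.column_stack(cols)
    keep = ~design.censor_flags if design.censor_flags is not None else np.ones(
        design.n_vol, dtype=bool
    )
    if keep.sum() == 0:
        raise ValueError("all volumes censored")
    if np.linalg.matrix_rank(x[keep]) < x.shape[1]:
        raise ValueError("rank-deficient design matrix on uncensored volumes")
    return x, names


def fit_glm(
    series: np.ndarray,
    design_matrix: np.ndarray,
    names: list,
    censor_flags: np.ndarray | None = None,
    contrast: tuple = ("2bk", "0bk"),
) -> GLMResult:
    """Ordinary least squares on uncensored volumes; the contrast is the
    difference of the two named condition betas with a t statistic from the
    usual OLS covariance."""
    y = np.asarray(series, dtype=float)
    x = np.asarray(design_matrix, dtype=float)
    keep = np.ones(len(y), dtype=bool) if censor_flags is None else ~np.asarray(
        censor_flags, dtype=bool
    )
    xk, yk = x[keep], y[keep]
    n_used, n_par = xk.shape
    if n_used <= n_par:
        raise ValueError("fewer usable volumes than design columns")
    beta, _, rank, _ = np.linalg.lstsq(xk, yk, rcond=None)
    if rank < n_par:
        raise ValueError("rank-deficient design matrix")
    resid = yk - xk @ beta
    dof = n_used - n_par
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(xk.T @ xk)
    c = np.zeros(n_par)
    c[names.index(contrast[0])] = 1.0
    c[names.index(contrast[1])] = -1.0
    value = float(c @ beta)
    se = float(np.sqrt(sigma2 * c @ xtx_inv @ c))
    t_stat = value / se if se > 0 else float("inf") * np.sign(value)
    return GLMResult(
        betas=dict(zip(names, beta)),
        contrast_2bk_0bk=value,
        t_stat=float(t_stat),
        dof=dof,
        censored_count=int((~keep).sum()),
        se_contrast=se,
    )


def behavioral_inclusion(accuracy_2bk: float, min_accuracy: float = 0.70) -> bool:
    """Pre-filter: keep subjects whose 2-back accuracy is at least 70%."""
    return accuracy_2bk >= min_accuracy
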
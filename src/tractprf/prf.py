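"""Compressive spatial summation (CSS) population receptive field model.

The model predicts a BOLD time series as baseline plus a stimulus-related
component

    r(t) = g * (S_t . G)^n  convolved with  h(t),

where ``S_t`` is the binary stimulus aperture at time t, ``G`` an isotropic 2-D
Gaussian receptive field, ``n`` a static compressive exponent (fixed at 0.05 by
default), ``g`` a gain, and ``h`` a double-gamma hemodynamic response function
(HRF).  White-matter HRFs differ from cortical ones (delayed onset, smaller
amplitude), so the HRF is an explicit, swappable parameter of every fit.

Fitting is two-stage: an exhaustive grid search over eccentricity x polar angle
x size candidates (gain and baseline solved in closed form per candidate),
followed by damped least-squares refinement of (x0, y0, sigma) from the best
seed, with the gain and polynomial baseline projected out at every step.

Pixel coordinate convention: the visual field is centred on the frame centre,
x increases with column index (rightward), y decreases with row index (upward),
so that polar angle measured counterclockwise from the right horizontal
meridian has the upper visual field in (0deg, 180deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal
from scipy.stats import gamma as gamma_dist
from sklearn.mixture import GaussianMixture

from .io_formats import StimulusApertureMovie

DEFAULT_EXPONENT = 0.05


@dataclass
class HRFSpec:
    """Five-parameter double-gamma hemodynamic response.

    h(t) = t^(a1-1) b1^a1 e^(-b1 t) / Gamma(a1)
         - t^(a2-1) b2^a2 e^(-b2 t) / (c Gamma(a2))

    a1: time-to-response shape, a2: time-to-undershoot shape, b1/b2: response
    and undershoot dispersions (1/s), c: response/undershoot ratio.  ``dt`` and
    ``duration`` (seconds) define the sampling grid of :func:`hrf_curve`.
    """

    a1: float = 6.0
    b1: float = 1.0
    a2: float = 16.0
    b2: float = 1.0
    c: float = 6.0
    dt: float = 0.1
    duration: float = 32.0

    def __post_init__(self) -> None:
        if not (self.a1 > 1 and self.a2 > 1):
            raise ValueError("shape parameters a1, a2 must exceed 1")
        if not (self.b1 > 0 and self.b2 > 0 and self.c > 0):
            raise ValueError("dispersions and undershoot ratio must be positive")
        if not (self.dt > 0 and self.duration > 0):
            raise ValueError("dt and duration must be positive")


def canonical_hrf(dt: float = 0.1) -> HRFSpec:
    """SPM-style canonical double-gamma (peak near 5 s)."""
    return HRFSpec(a1=6.0, b1=1.0, a2=16.0, b2=1.0, c=6.0, dt=dt)


def wm_hrf(dt: float = 0.1) -> HRFSpec:
    """White-matter preset: delayed onset/peak relative to the canonical HRF."""
    return HRFSpec(a1=8.0, b1=1.0, a2=16.0, b2=1.0, c=6.0, dt=dt)


def hrf_curve(spec: HRFSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the double-gamma response on [0, duration] at spec.dt.

    Returns (t, h).  Each gamma term is a proper probability density in t, so
    the positive lobe integrates to 1 over [0, inf).
    """
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    h = gamma_dist.pdf(t, spec.a1, scale=1.0 / spec.b1) - gamma_dist.pdf(
        t, spec.a2, scale=1.0 / spec.b2
    ) / spec.c
    return t, h


@dataclass
class PRFParams:
    """One receptive field: position/spread in centred pixel units, exponent,
    gain, plus derived visual-field quantities (filled by
    :func:`derive_quantities`)."""

    x0_px: float
    y0_px: float
    sigma_px: float
    n_exp: float = DEFAULT_EXPONENT
    gain: float = 1.0
    ecc_deg: float | None = None
    angle_deg: float | None = None
    size_deg: float | None = None
    r2: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma must be positive")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")


@dataclass
class GridSpec:
    """Candidate seeds for the grid stage: eccentricities x angles x sizes.

    Values are in degrees of visual angle; they are converted to pixels with
    the movie's scale at fit time.  Defaults: 25 log-spaced eccentricities and
    13 log-spaced sigmas spanning 0.1-8 deg, 32 uniform polar angles —
    25 x 32 x 13 = 10,400 combinations.
    """

    ecc_values: np.ndarray
    angle_values: np.ndarray
    size_values: np.ndarray

    @classmethod
    def default(cls, n_ecc: int = 25, n_angle: int = 32, n_size: int = 13,
                ecc_range: tuple = (0.1, 8.0), size_range: tuple = (0.1, 8.0)) -> "GridSpec":
        return cls(
            ecc_values=np.geomspace(ecc_range[0], ecc_range[1], n_ecc),
            angle_values=np.linspace(0.0, 360.0, n_angle, endpoint=False),
            size_values=np.geomspace(size_range[0], size_range[1], n_size),
        )

    @property
    def n_candidates(self) -> int:
        return len(self.ecc_values) * len(self.angle_values) * len(self.size_values)

    def candidates_px(self, deg_per_pixel: float) -> np.ndarray:
        """(n_candidates, 3) array of (x0_px, y0_px, sigma_px)."""
        ecc, ang, sig = np.meshgrid(
            self.ecc_values, self.angle_values, self.size_values, indexing="ij"
        )
        ecc, ang, sig = ecc.ravel(), ang.ravel(), sig.ravel()
        x0 = ecc * np.cos(np.deg2rad(ang)) / deg_per_pixel
        y0 = ecc * np.sin(np.deg2rad(ang)) / deg_per_pixel
        return np.column_stack([x0, y0, sig / deg_per_pixel])


@dataclass
class BaselineModel:
    """Slow baseline drift as a weighted sum of low-order Legendre polynomials."""

    max_poly_degree: int = 2

    def __post_init__(self) -> None:
        if self.max_poly_degree < 0:
            raise ValueError("degree must be >= 0")

    @classmethod
    def for_duration(cls, duration_s: float) -> "BaselineModel":
        """Degree = round(duration / 2 min), at least 1."""
        return cls(max_poly_degree=max(1, round(duration_s / 120.0)))

    def basis(self, n_samples: int) -> np.ndarray:
        x = np.linspace(-1.0, 1.0, n_samples)
        return np.polynomial.legendre.legvander(x, self.max_poly_degree)


def pixel_lattice(shape_px: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Centred pixel coordinates (x right, y up) for an (H, W) frame."""
    h, w = shape_px
    x = np.arange(w) - (w - 1) / 2.0
    y = (h - 1) / 2.0 - np.arange(h)
    return np.meshgrid(x, y)  # (H, W) each


def gaussian_field(x0: float, y0: float, sigma: float, shape_px: tuple) -> np.ndarray:
    """Unnormalized isotropic Gaussian G = exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xx, yy = pixel_lattice(shape_px)
    return np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma ** 2))


def _hrf_convolve(drive: np.ndarray, hrf: HRFSpec, dt: float) -> np.ndarray:
    """Causal convolution of a frame-rate drive with the HRF sampled at dt."""
    t = np.arange(0.0, hrf.duration + dt / 2, dt)
    h = gamma_dist.pdf(t, hrf.a1, scale=1.0 / hrf.b1) - gamma_dist.pdf(
        t, hrf.a2, scale=1.0 / hrf.b2
    ) / hrf.c
    if drive.ndim == 1:
        return np.convolve(drive, h * dt)[: len(drive)]
    return signal.fftconvolve(drive, (h * dt)[:, None], axes=0)[: len(drive)]


def _downsample_to_tr(series: np.ndarray, n_frames_per_tr: int) -> np.ndarray:
    if n_frames_per_tr == 1:
        return series
    n_tr = series.shape[0] // n_frames_per_tr
    trimmed = series[: n_tr * n_frames_per_tr]
    return trimmed.reshape((n_tr, n_frames_per_tr) + series.shape[1:]).mean(axis=1)


def stimulus_drive(
    prf_px: np.ndarray, movie: StimulusApertureMovie, n_exp: float
) -> np.ndarray:
    """Per-frame (S_t . G)^n for one or many candidate pRFs.

    prf_px: (3,) or (C, 3) array of (x0, y0, sigma) in centred pixels.
    Returns (T,) or (T, C).
    """
    prf_px = np.atleast_2d(prf_px)
    frames = movie.frames.reshape(movie.n_frames, -1)
    xx, yy = pixel_lattice(movie.shape_px)
    xf, yf = xx.ravel(), yy.ravel()
    out = np.empty((movie.n_frames, len(prf_px)))
    # chunk the Gaussian bank to bound memory at large candidate counts
    chunk = max(1, int(2e8 // (8 * frames.shape[1])))
    for lo in range(0, len(prf_px), chunk):
        sub = prf_px[lo : lo + chunk]
        g = np.exp(
            -((xf[:, None] - sub[:, 0]) ** 2 + (yf[:, None] - sub[:, 1]) ** 2)
            / (2.0 * sub[:, 2] ** 2)
        )
        out[:, lo : lo + chunk] = frames @ g
    np.power(out, n_exp, out=out, where=out > 0)
    out[out <= 0] = 0.0
    return out if out.shape[1] > 1 else out[:, 0]


def forward_model(
    prf: PRFParams,
    movie: StimulusApertureMovie,
    hrf: HRFSpec,
    baseline_coefficients: np.ndarray | None = None,
    tr: float = 1.0,
    n_frames_per_tr: int = 1,
    baseline: BaselineModel | None = None,
) -> np.ndarray:
    """Predict the TR-sampled BOLD series for one pRF.

    Pipeline: aperture . Gaussian dot product per frame -> power-law exponent
    -> gain -> HRF convolution at the frame rate -> average within TRs -> add
    polynomial baseline (zero if no coefficients given).
    """
    drive = stimulus_drive(
        np.array([prf.x0_px, prf.y0_px, prf.sigma_px]), movie, prf.n_exp
    )
    assert np.all(drive >= 0), "aperture-Gaussian overlap must be non-negative"
    dt = tr / n_frames_per_tr
    stim = prf.gain * _hrf_convolve(drive, hrf, dt)
    series = _downsample_to_tr(stim, n_frames_per_tr)
    if baseline_coefficients is not None:
        bl = baseline if baseline is not None else BaselineModel(
            max_poly_degree=len(np.atleast_1d(baseline_coefficients)) - 1
        )
        series = series + bl.basis(len(series)) @ np.atleast_1d(baseline_coefficients)
    return series


class CandidateBank:
    """Precomputed grid-stage predictions for one (movie, hrf, grid, baseline).

    Building the bank is the expensive step (one large matrix product); fitting
    a series against it is a cheap projection, so a bank can be shared across
    all sub-bundles recorded under the same stimulus.
    """

    def __init__(
        self,
        movie: StimulusApertureMovie,
        hrf: HRFSpec,
        grid: GridSpec,
        tr: float = 1.0,
        n_frames_per_tr: int = 1,
        baseline: BaselineModel | None = None,
        n_exp: float = DEFAULT_EXPONENT,
    ) -> None:
        self.movie = movie
        self.hrf = hrf
        self.grid = grid
        self.tr = tr
        self.n_frames_per_tr = n_frames_per_tr
        self.n_exp = n_exp
        self.params_px = grid.candidates_px(movie.deg_per_pixel)
        drive = stimulus_drive(self.params_px, movie, n_exp)  # (T_frames, C)
        dt = tr / n_frames_per_tr
        conv = _hrf_convolve(drive, hrf, dt)
        preds = _downsample_to_tr(conv, n_frames_per_tr)  # (n_tr, C)
        n_tr = preds.shape[0]
        self.baseline = baseline if baseline is not None else BaselineModel.for_duration(
            n_tr * tr
        )
        b = self.baseline.basis(n_tr)
        self._q, _ = np.linalg.qr(b)  # orthonormal baseline basis
        self._basis = b
        qp = preds - self._q @ (self._q.T @ preds)
        self._qp = qp
        self._qp_norm2 = np.einsum("tc,tc->c", qp, qp)

    @property
    def n_tr(self) -> int:
        return self._qp.shape[0]

    def project_out_baseline(self, series: np.ndarray) -> np.ndarray:
        return series - self._q @ (self._q.T @ series)

    def best_candidate(self, series: np.ndarray) -> tuple[int, float, float]:
        """Return (index, gain, rss) of the least-squares-best candidate."""
        series = np.asarray(series, dtype=float)
        qy = self.project_out_baseline(series)
        scale = max(1.0, float(series @ series))
        if float(qy @ qy) < 1e-20 * scale:
            raise ValueError("degenerate fit: series is flat after baseline removal")
        dots = self._qp.T @ qy  # (C,)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(self._qp_norm2 > 0, dots**2 / self._qp_norm2, 0.0)
        idx = int(np.argmax(score))
        gain = dots[idx] / self._qp_norm2[idx]
        rss = float(qy @ qy - score[idx])
        return idx, float(gain), rss


def grid_fit(
    series: np.ndarray,
    movie: StimulusApertureMovie,
    hrf: HRFSpec,
    grid: GridSpec | None = None,
    tr: float = 1.0,
    n_frames_per_tr: int = 1,
    baseline: BaselineModel | None = None,
    n_exp: float = DEFAULT_EXPONENT,
    bank: CandidateBank | None = None,
) -> PRFParams:
    """Exhaustive grid search; gain and baseline solved closed-form per candidate."""
    if bank is None:
        bank = CandidateBank(
            movie, hrf, grid or GridSpec.default(), tr, n_frames_per_tr, baseline, n_exp
        )
    series = np.asarray(series, dtype=float)
    if len(series) != bank.n_tr:
        raise ValueError("series length does not match movie frames / n_frames_per_tr")
    idx, gain, rss = bank.best_candidate(series)
    x0, y0, sig = bank.params_px[idx]
    qy = bank.project_out_baseline(series)
    tss = float(qy @ qy)
    r2 = 100.0 * (1.0 - rss / tss) if tss > 0 else 0.0
    return PRFParams(
        x0_px=x0, y0_px=y0, sigma_px=sig, n_exp=bank.n_exp, gain=gain, r2=r2
    )


def refine_fit(
    seed: PRFParams,
    series: np.ndarray,
    movie: StimulusApertureMovie,
    hrf: HRFSpec,
    tr: float = 1.0,
    n_frames_per_tr: int = 1,
    baseline: BaselineModel | None = None,
    max_iter: int = 500,
    xtol: float = 1e-6,
) -> PRFParams:
    """Damped least-squares refinement of (x0, y0, sigma, gain) from the seed.

    The exponent n stays fixed; gain and polynomial baseline are re-solved in
    closed form at every parameter evaluation (variable projection), so the
    optimizer only sees (x0, y0, log sigma).  Never returns a fit with larger
    residual than the seed.
    """
    series = np.asarray(series, dtype=float)
    n_tr = len(series)
    bl = baseline if baseline is not None else BaselineModel.for_duration(n_tr * tr)
    b = bl.basis(n_tr)
    q, _ = np.linalg.qr(b)
    qy = series - q @ (q.T @ series)
    dt = tr / n_frames_per_tr

    def qpred(theta: np.ndarray) -> np.ndarray:
        x0, y0, logsig = theta
        drive = stimulus_drive(
            np.array([x0, y0, math.exp(logsig)]), movie, seed.n_exp
        )
        p = _downsample_to_tr(_hrf_convolve(drive, hrf, dt), n_frames_per_tr)
        return p - q @ (q.T @ p)

    def residuals(theta: np.ndarray) -> np.ndarray:
        qp = qpred(theta)
        nrm2 = qp @ qp
        g = (qp @ qy) / nrm2 if nrm2 > 0 else 0.0
        return qy - g * qp

    theta0 = np.array([seed.x0_px, seed.y0_px, math.log(seed.sigma_px)])
    result = optimize.least_squares(
        residuals, theta0, method="lm", max_nfev=max_iter, xtol=xtol, ftol=xtol
    )
    seed_rss = float(residuals(theta0) @ residuals(theta0))
    rss = float(result.fun @ result.fun)
    if rss <= seed_rss:
        theta, converged = result.x, bool(result.success)
    else:  # optimizer wandered off: keep the seed, flag it
        theta, rss, converged = theta0, seed_rss, False
    qp = qpred(theta)
    nrm2 = qp @ qp
    gain = float((qp @ qy) / nrm2) if nrm2 > 0 else 0.0
    tss = float(qy @ qy)
    r2 = 100.0 * (1.0 - rss / tss) if tss > 0 else 0.0
    return PRFParams(
        x0_px=float(theta[0]),
        y0_px=float(theta[1]),
        sigma_px=float(math.exp(theta[2])),
        n_exp=seed.n_exp,
        gain=gain,
        r2=r2,
        converged=converged,
    )


def derive_quantities(
    prf: PRFParams, scale: float, size_definition: str = "sigma_over_n"
) -> PRFParams:
    """Fill derived visual-field quantities from the pixel-space fit.

    ecc = scale * sqrt(x0^2 + y0^2);  angle = atan2(y0, x0) in [0, 360) with
    the right upper visual field in [0, 90);  size = scale * sigma / n (or
    scale * sigma / sqrt(n) with ``size_definition='sigma_over_sqrt_n'``, the
    convention of the wider CSS literature).
    """
    ecc = scale * math.hypot(prf.x0_px, prf.y0_px)
    angle = math.degrees(math.atan2(prf.y0_px, prf.x0_px)) % 360.0
    if size_definition == "sigma_over_n":
        size = scale * prf.sigma_px / prf.n_exp
    elif size_definition == "sigma_over_sqrt_n":
        size = scale * prf.sigma_px / math.sqrt(prf.n_exp)
    else:
        raise ValueError(f"unknown size definition {size_definition!r}")
    return replace(prf, ecc_deg=ecc, angle_deg=angle, size_deg=size)


@dataclass
class GMMThresholdResult:
    threshold: float
    keep: np.ndarray
    degenerate: bool


def gmm_threshold(
    r2_values: np.ndarray,
    random_state: int = 0,
    fallback_quantile: float = 0.25,
) -> GMMThresholdResult:
    """Explained-variance cutoff from a two-component 1-D Gaussian mixture.

    Fits two Gaussians to the distribution of R^2 values (noise-level fits
    versus signal-level fits) and places the threshold where the posterior
    responsibility of the higher-mean component crosses 0.5 between the two
    component means; values below threshold are flagged as noise.  If the
    components collapse (indistinguishable means, or no posterior crossing)
    the threshold falls back to a fixed quantile and the result is flagged.
    """
    vals = np.asarray(r2_values, dtype=float).ravel()
    if len(vals) < 2:
        raise ValueError("need at least two values")
    spread = vals.std()
    degenerate = spread < 1e-12
    threshold = None
    if not degenerate:
        gm = GaussianMixture(n_components=2, random_state=random_state, n_init=5)
        gm.fit(vals[:, None])
        means = gm.means_.ravel()
        lo, hi = np.sort(means)
        hi_comp = int(np.argmax(means))
        if hi - lo < 1e-6 * max(1.0, spread):
            degenerate = True
        else:
            xs = np.linspace(lo, hi, 2001)
            post = gm.predict_proba(xs[:, None])[:, hi_comp]
            crossing = np.nonzero(post >= 0.5)[0]
            if len(crossing) == 0 or crossing[0] == 0:
                degenerate = True
            else:
                i = crossing[0]
                # linear interpolation of the 0.5 crossing
                x0, x1, p0, p1 = xs[i - 1], xs[i], post[i - 1], post[i]
                threshold = float(x0 + (0.5 - p0) * (x1 - x0) / (p1 - p0))
    if degenerate or threshold is None:
        threshold = float(np.quantile(vals, fallback_quantile))
        degenerate = True
    return GMMThresholdResult(
        threshold=threshold, keep=vals >= threshold, degenerate=degenerate
    )
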
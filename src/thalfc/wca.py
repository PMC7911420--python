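"""Wavelet transform coherence (WTC) with Monte Carlo red-noise significance.

The dynamic-connectivity engine: a continuous wavelet transform with the
analytic Morlet mother wavelet, the squared wavelet coherence

    R^2(s, tau) = |S(s^-1 Wxy)|^2 / ( S(s^-1 |Wx|^2) S(s^-1 |Wy|^2) )

with ``Wxy = conj(Wx) * Wy`` and ``S`` a smoothing operator in time and
scale, the cone of influence (COI) marking edge-contaminated cells, and a
Monte Carlo significance test against surrogate AR(1) ("red noise") pairs
matched to the two input series.

Conventions (following the standard continuous-wavelet practice):

* Morlet ``psi(eta) = pi^(-1/4) exp(i omega0 eta) exp(-eta^2/2)`` with
  ``omega0 = 6`` by default; Fourier period ``= 4 pi s / (omega0 +
  sqrt(2 + omega0^2))``.
* Scales ``s_j = s0 * 2^(j dj)`` with ``s0 = 2 dt`` and ``dj = 1/12`` by
  default, up to the largest period ``<= n dt / 2``.
* The transform is computed in the frequency domain after zero padding to
  the next power of two; the COI masks the padding-contaminated region.
* Phase sign: ``phase = arg(S(s^-1 conj(Wx) Wy))``; a *positive* phase
  means x lags y (y's oscillation is ahead), so an angle of -pi/2 reads
  "x leads y by a quarter cycle".  Classification bins are centred on the
  four cardinal directions: in-phase (|theta| < pi/4), antiphase
  (|theta| > 3 pi/4), x_leads (theta in (-3pi/4, -pi/4)), x_lags
  (theta in (pi/4, 3pi/4)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .prep import TimeCourse

__all__ = [
    "WcaParams",
    "CwtResult",
    "WtcResult",
    "Ar1Fit",
    "PhaseSummary",
    "fourier_factor",
    "morlet_cwt",
    "cone_of_influence",
    "smooth_time_scale",
    "wtc",
    "fit_ar1",
    "mc_significance",
    "phase_classify",
    "circular_mean",
    "segment_phase_summary",
]

PHASE_CLASSES = ("in_phase", "antiphase", "x_leads", "x_lags", "none")


@dataclass(frozen=True)
class WcaParams:
    """Wavelet-coherence parameters.

    omega0
        Morlet central frequency (dimensionless); >= 5 keeps the analytic
        approximation admissible.
    dj
        Scale resolution as a fraction of an octave.
    s0_dt
        Smallest scale in units of dt (scale s0 = s0_dt * dt).
    mc_n
        Number of surrogate AR(1) pairs for the significance test.
    alpha
        Significance level of the coherence threshold.
    guard_band
        Samples excluded around concatenation seams in phase summaries.
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s0_dt: float = 2.0
    mc_n: int = 1000
    alpha: float = 0.05
    seed: int = 0
    guard_band: int = 5

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for the analytic Morlet")
        if self.dj <= 0:
            raise ValueError("dj must be positive")
        if self.mc_n < 100:
            raise ValueError("mc_n must be >= 100")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def fourier_factor(omega0: float = 6.0) -> float:
    """Fourier period per unit scale: 4 pi / (omega0 + sqrt(2 + omega0^2))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


@dataclass
class CwtResult:
    """Complex Morlet coefficients over (scale, time)."""

    coeffs: np.ndarray          # (n_scales, n_times) complex
    scales: np.ndarray          # seconds
    fourier_periods: np.ndarray  # seconds
    dt_s: float


@dataclass
class Ar1Fit:
    """Red-noise (AR(1)) fit of a series: lag-1 autocorrelation + innovation SD."""

    phi: float
    sigma: float
    n: int


@dataclass
class WtcResult:
    """Squared wavelet coherence with phase, COI and significance."""

    coherence: np.ndarray       # R^2 in [0, 1], (n_scales, n_times)
    phase: np.ndarray           # radians in (-pi, pi]
    scales: np.ndarray          # seconds
    fourier_periods: np.ndarray  # seconds
    times_s: np.ndarray
    coi: np.ndarray             # per-time max uncontaminated period (s)
    sig_mask: np.ndarray | None  # True where R^2 exceeds the MC threshold, in-COI
    thresholds: np.ndarray | None  # per-scale (1 - alpha) coherence quantile
    params: WcaParams
    segment_bounds: list[tuple[int, int]] | None = None
    segment_names: list[str] | None = None

    @property
    def in_coi(self) -> np.ndarray:
        """Boolean (scale, time) mask of cells inside the cone of influence."""
        return self.fourier_periods[:, None] <= self.coi[None, :]


@dataclass
class PhaseSummary:
    """Per-segment circular phase statistics of the significant cells."""

    segments: list[dict]        # name, circular_mean_phase, sig_fraction, dominant_class

    def to_records(self) -> list[dict]:
        return list(self.segments)


# ---------------------------------------------------------------------------
# Engine: cached filters for a fixed (n, dt, params) geometry
# ---------------------------------------------------------------------------

class _WtcEngine:
    """Precomputed wavelet filter bank and smoothing kernels.

    The Monte Carlo significance loop evaluates hundreds of transforms on
    series of identical length; caching the frequency-domain Morlet filters
    and smoothing-kernel FFTs makes that loop cheap.
    """

    def __init__(self, n: int, dt: float, params: WcaParams):
        self.n, self.dt, self.params = n, dt, params
        self.nfft = int(2 ** np.ceil(np.log2(n)))
        s0 = params.s0_dt * dt
        ff = fourier_factor(params.omega0)
        max_period = n * dt / 2.0
        jmax = int(np.floor(np.log2(max_period / (ff * s0)) / params.dj))
        self.scales = s0 * 2.0 ** (params.dj * np.arange(max(jmax, 0) + 1))
        self.periods = ff * self.scales
        # frequency-domain Morlet filter bank, one row per scale
        omega = 2.0 * np.pi * np.fft.fftfreq(self.nfft, d=dt)
        pos = omega > 0
        arg = self.scales[:, None] * omega[None, :]
        self.filters = np.zeros((len(self.scales), self.nfft))
        norm = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * self.scales / dt)
        self.filters[:, pos] = (norm[:, None]
                                * np.exp(-0.5 * (arg[:, pos] - params.omega0) ** 2))
        # time-smoothing kernels: Gaussian with SD = s (in time units) per scale,
        # normalised; stored as rFFTs for linear convolution of length n
        self.conv_len = int(2 ** np.ceil(np.log2(2 * n)))
        t = np.arange(-(n - 1), n) * dt
        kerns = np.exp(-0.5 * (t[None, :] / self.scales[:, None]) ** 2)
        kerns /= kerns.sum(axis=1, keepdims=True)
        self.kern_fft = np.fft.rfft(kerns, n=self.conv_len, axis=1)
        # normaliser so boundary cells keep constants: smoothed ones
        self.time_norm = self._time_conv(np.ones((len(self.scales), n)))
        # scale-smoothing boxcar: 0.6 octave decorrelation width
        self.scale_width = max(1, int(round(0.6 / params.dj)))
        self.coi = cone_of_influence(n, dt, params.omega0)

    def cwt(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xhat = np.fft.fft(x - x.mean(), n=self.nfft)
        W = np.fft.ifft(xhat[None, :] * self.filters, axis=1)
        return W[:, : self.n]

    def _time_conv(self, F: np.ndarray) -> np.ndarray:
        Fh = np.fft.rfft(F, n=self.conv_len, axis=1)
        full = np.fft.irfft(Fh * self.kern_fft, n=self.conv_len, axis=1)
        return full[:, self.n - 1: 2 * self.n - 1]

    def smooth(self, F: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(F):
            out = self._time_conv(F.real) + 1j * self._time_conv(F.imag)
        else:
            out = self._time_conv(F)
        out = out / self.time_norm
        # boxcar over scale with edge renormalisation
        w = self.scale_width
        if w > 1:
            kernel = np.ones(w) / w
            num = np.apply_along_axis(
                lambda c: np.convolve(c, kernel, mode="same"), 0, out)
            den = np.convolve(np.ones(out.shape[0]), kernel, mode="same")
            out = num / den[:, None]
        return out

    def coherence_fields(self, x: np.ndarray, y: np.ndarray):
        Wx, Wy = self.cwt(x), self.cwt(y)
        inv_s = 1.0 / self.scales[:, None]
        Sx = self.smooth(inv_s * np.abs(Wx) ** 2)
        Sy = self.smooth(inv_s * np.abs(Wy) ** 2)
        Sxy = self.smooth(inv_s * np.conj(Wx) * Wy)
        # Symmetric floor resolves 0/0 at cells where both spectra sink into
        # the FFT round-off floor (possible only for exactly band-limited
        # inputs such as pure tones); such cells take the self-coherence
        # limit 1.  The floor sits ~1e-12 below the round-off noise squared
        # (noise ~ 1e-16 of the field maximum), so any cell with genuine
        # power is unaffected beyond O(1e-8).
        d2 = 1e-20 * float(Sx.max()) * float(Sy.max())
        r2 = (np.abs(Sxy) ** 2 + d2) / (Sx * Sy + d2)
        if r2.max() > 1.0 + 1e-6:
            warnings.warn(f"coherence overshoot {r2.max() - 1:.2e} clipped")
        r2 = np.clip(r2, 0.0, 1.0)
        return r2, np.angle(Sxy)


_engine_cache: dict[tuple, _WtcEngine] = {}


def _get_engine(n: int, dt: float, params: WcaParams) -> _WtcEngine:
    key = (n, round(dt, 12), params.omega0, params.dj, params.s0_dt)
    eng = _engine_cache.get(key)
    if eng is None:
        eng = _WtcEngine(n, dt, params)
        _engine_cache[key] = eng
    return eng


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def morlet_cwt(tc: TimeCourse, params: WcaParams = WcaParams()) -> CwtResult:
    """Continuous Morlet wavelet transform of a time course.

    Computed by frequency-domain multiplication after zero padding to the
    next power of two (padding removed on return); the series mean is
    removed first.
    """
    x = np.asarray(tc.samples, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    eng = _get_engine(len(x), tc.dt_s, params)
    return CwtResult(coeffs=eng.cwt(x), scales=eng.scales.copy(),
                     fourier_periods=eng.periods.copy(), dt_s=tc.dt_s)


def cone_of_influence(n: int, dt: float, omega0: float = 6.0) -> np.ndarray:
    """Per-time maximum uncontaminated Fourier period (seconds).

    Uses the Morlet e-folding time sqrt(2) * s: the COI at distance d from
    the nearer edge is ``fourier_factor * sqrt(2) * d * dt``, hence zero at
    the first and last samples and maximal (about
    ``sqrt(2) * ff * (n/2) * dt``) at the midpoint.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    idx = np.arange(n)
    dist = np.minimum(idx, n - 1 - idx).astype(float)
    return fourier_factor(omega0) * np.sqrt(2.0) * dist * dt


def smooth_time_scale(field: np.ndarray, scales: np.ndarray, dt: float,
                      dj: float = 1.0 / 12.0, omega0: float = 6.0) -> np.ndarray:
    """Smooth a (scale, time) field in time (scale-proportional Gaussian)
    and scale (fixed-octave boxcar).

    Linear, and preserves constant fields exactly (kernels renormalised at
    the boundaries).
    """
    field = np.asarray(field)
    scales = np.asarray(scales, dtype=float)
    if field.shape[0] != len(scales):
        raise ValueError("field rows must match scales")
    params = WcaParams(omega0=omega0, dj=dj)
    eng = _WtcEngine.__new__(_WtcEngine)
    # build a minimal engine for arbitrary scales
    eng.n, eng.dt, eng.params = field.shape[1], dt, params
    n = eng.n
    eng.scales = scales
    eng.conv_len = int(2 ** np.ceil(np.log2(2 * n)))
    t = np.arange(-(n - 1), n) * dt
    kerns = np.exp(-0.5 * (t[None, :] / scales[:, None]) ** 2)
    kerns /= kerns.sum(axis=1, keepdims=True)
    eng.kern_fft = np.fft.rfft(kerns, n=eng.conv_len, axis=1)
    eng.time_norm = eng._time_conv(np.ones((len(scales), n)))
    eng.scale_width = max(1, int(round(0.6 / dj)))
    return eng.smooth(field)


def wtc(x: TimeCourse, y: TimeCourse, params: WcaParams = WcaParams(),
        significance: bool = False) -> WtcResult:
    """Squared wavelet coherence and phase between two equal-length series.

    With ``significance=True``, AR(1) models are fitted to both inputs and
    ``mc_significance`` computes per-scale coherence thresholds from
    ``params.mc_n`` surrogate pairs; ``sig_mask`` then marks in-COI cells
    whose coherence exceeds the threshold at their scale.
    """
    if len(x) != len(y) or abs(x.dt_s - y.dt_s) > 1e-12:
        raise ValueError("series must share length and sampling interval")
    xs, ys = np.asarray(x.samples), np.asarray(y.samples)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("constant input series: coherence undefined")
    eng = _get_engine(len(x), x.dt_s, params)
    r2, phase = eng.coherence_fields(xs, ys)
    result = WtcResult(coherence=r2, phase=phase, scales=eng.scales.copy(),
                       fourier_periods=eng.periods.copy(),
                       times_s=np.arange(len(x)) * x.dt_s,
                       coi=eng.coi.copy(), sig_mask=None, thresholds=None,
                       params=params,
                       segment_bounds=x.segment_bounds,
                       segment_names=x.segment_names)
    if significance:
        thr = mc_significance(fit_ar1(x), fit_ar1(y), params,
                              n=len(x), dt=x.dt_s)
        result.thresholds = thr
        result.sig_mask = (r2 > thr[:, None]) & result.in_coi
    return result


def fit_ar1(tc: TimeCourse) -> Ar1Fit:
    """Fit a red-noise AR(1) model: lag-1 autocorrelation and innovation SD.

    A phi estimate above 0.98 (e.g. from a deterministic trend) triggers a
    warning: the surrogate null is then nearly nonstationary.
    """
    x = np.asarray(tc.samples, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples to fit AR(1)")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant series: AR(1) undefined")
    phi = float(x[:-1] @ x[1:]) / denom
    phi = float(np.clip(phi, -0.999, 0.999))
    if phi > 0.98:
        warnings.warn("AR(1) phi estimate near 1 (trend-like series); "
                      "red-noise surrogates may be a poor null")
    var = denom / len(x)
    sigma = float(np.sqrt(max(var * (1.0 - phi ** 2), np.finfo(float).tiny)))
    return Ar1Fit(phi=phi, sigma=sigma, n=len(x))


def _ar1_paths(n: int, phi: float, sigma: float, rng: np.random.Generator,
               size: int) -> np.ndarray:
    eps = rng.standard_normal((size, n)) * sigma
    x = np.empty((size, n))
    x[:, 0] = eps[:, 0] / np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    return x


def mc_significance(fit_x: Ar1Fit, fit_y: Ar1Fit,
                    params: WcaParams = WcaParams(),
                    n: int | None = None, dt: float = 1.0) -> np.ndarray:
    """Per-scale coherence significance thresholds from AR(1) surrogates.

    Generates ``params.mc_n`` independent surrogate pairs with the fitted
    red-noise parameters, computes their wavelet coherence, pools the
    in-COI coherence values over time at each scale and returns the
    (1 - alpha) quantile per scale.  Deterministic given ``params.seed``.
    """
    if n is None:
        n = fit_x.n
    eng = _get_engine(n, dt, params)
    rng = np.random.default_rng(params.seed)
    in_coi = eng.periods[:, None] <= eng.coi[None, :]
    n_scales = len(eng.scales)
    samples: list[list[np.ndarray]] = [[] for _ in range(n_scales)]
    phx = abs(fit_x.phi)  # stationarity-safe: surrogates use |phi|
    phy = abs(fit_y.phi)
    for _ in range(params.mc_n):
        xs = _ar1_paths(n, phx, fit_x.sigma, rng, 1)[0]
        ys = _ar1_paths(n, phy, fit_y.sigma, rng, 1)[0]
        r2, _ = eng.coherence_fields(xs, ys)
        for j in range(n_scales):
            vals = r2[j, in_coi[j]]
            if vals.size:
                samples[j].append(vals)
    thr = np.ones(n_scales)
    for j in range(n_scales):
        if samples[j]:
            pooled = np.concatenate(samples[j])
            thr[j] = np.quantile(pooled, 1.0 - params.alpha)
    return thr


# ---------------------------------------------------------------------------
# Phase summaries
# ---------------------------------------------------------------------------

def normalize_angle(theta: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    t = np.remainder(theta + np.pi, 2 * np.pi) - np.pi
    if t == -np.pi:
        t = np.pi
    return float(t)


def phase_classify(angle: float) -> str:
    """Bin a phase angle into the four cardinal coupling classes.

    in_phase for |theta| < pi/4; antiphase for |theta| > 3pi/4; x_leads for
    theta in (-3pi/4, -pi/4); x_lags for theta in (pi/4, 3pi/4).  Boundary
    angles fall to the neighbouring lead/lag class (ties toward lead/lag).
    """
    t = normalize_angle(angle)
    if abs(t) < np.pi / 4:
        return "in_phase"
    if abs(t) > 3 * np.pi / 4:
        return "antiphase"
    return "x_leads" if t < 0 else "x_lags"


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction: argument of the mean unit phasor."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular mean of empty set")
    return float(np.angle(np.mean(np.exp(1j * angles))))


def segment_phase_summary(res: WtcResult,
                          segments: list[tuple[int, int]] | None = None,
                          segment_names: list[str] | None = None,
                          guard_band: int | None = None,
                          none_floor: float | None = None) -> PhaseSummary:
    """Circular-mean phase, significant fraction, and dominant class per segment.

    Cells enter a segment's statistics when they are (a) inside the global
    COI, (b) at least ``guard_band`` samples away from any interior segment
    seam, and (c) inside the *segment-local* cone: the wavelet at scale s
    averages over roughly its e-folding time sqrt(2) s, so a cell whose
    Fourier period exceeds ``fourier_factor * sqrt(2) * (distance to the
    nearest seam)`` mixes neighbouring segments and cannot be attributed to
    this one.  Concatenated multi-phase series would otherwise leak each
    phase's coupling into its neighbours at large scales.

    The dominant class is the majority vote of the classified significant
    cells, except that a segment whose significant fraction does not exceed
    ``none_floor`` (default 2 * alpha, i.e. chance level with margin) is
    reported as ``"none"``: its scattered significant cells are consistent
    with false positives.  The circular-mean phase is NaN when there is no
    significant cell.
    """
    if res.sig_mask is None:
        raise ValueError("run wtc(..., significance=True) first")
    if segments is None:
        segments = res.segment_bounds
    if segments is None:
        segments = [(0, res.coherence.shape[1])]
    if segment_names is None:
        segment_names = res.segment_names or [f"segment_{i}"
                                              for i in range(len(segments))]
    gb = res.params.guard_band if guard_band is None else guard_band
    if none_floor is None:
        none_floor = 2.0 * res.params.alpha
    n_t = res.coherence.shape[1]
    dt = float(res.times_s[1] - res.times_s[0]) if n_t > 1 else 1.0
    seams = sorted({s for s, _ in segments} | {e for _, e in segments})
    interior = [s for s in seams if 0 < s < n_t]
    keep_t = np.ones(n_t, dtype=bool)
    for s in interior:
        keep_t[max(0, s - gb): min(n_t, s + gb)] = False
    # Segment-local cone: distance to the nearest seam (segment edges
    # count).  A coherence cell at scale s draws on the wavelet envelope
    # (SD s) convolved with the time-smoothing kernel (SD s): combined
    # Gaussian SD sqrt(2) s, amplitude e-folding distance 2 s.  A cell is
    # attributable to a segment only when it sits at least 2 s from every
    # seam, i.e. period <= fourier_factor * dist * dt / 2.
    edges = np.asarray(sorted({0, n_t} | set(interior)))
    dist = np.min(np.abs(np.arange(n_t)[None, :] - edges[:, None]), axis=0)
    seg_coi = fourier_factor(res.params.omega0) * dist * dt / 2.0
    local = res.fourier_periods[:, None] <= seg_coi[None, :]

    in_coi = res.in_coi & local
    out = []
    for (start, end), name in zip(segments, segment_names):
        cols = np.zeros(n_t, dtype=bool)
        cols[start:end] = True
        cols &= keep_t
        valid = in_coi[:, cols]
        sig = res.sig_mask[:, cols] & valid
        n_valid = int(valid.sum())
        n_sig = int(sig.sum())
        frac = n_sig / n_valid if n_valid else 0.0
        if n_sig == 0 or frac <= none_floor:
            mean_phase = (circular_mean(res.phase[:, cols][sig])
                          if n_sig else float("nan"))
            out.append({"name": name, "circular_mean_phase": mean_phase,
                        "sig_fraction": frac, "dominant_class": "none",
                        "n_cells": n_valid})
            continue
        phases = res.phase[:, cols][sig]
        classes = [phase_classify(a) for a in phases]
        counts = {c: classes.count(c) for c in set(classes)}
        dom = max(counts, key=counts.get)
        out.append({"name": name, "circular_mean_phase": circular_mean(phases),
                    "sig_fraction": frac, "dominant_class": dom,
                    "n_cells": n_valid})
    return PhaseSummary(segments=out)
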
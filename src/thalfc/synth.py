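"""Synthetic multi-subject, four-phase BOLD sessions with planted coupling.

Every downstream stage of the pipeline (preprocessing, seed-based
correlation, group ICA, wavelet coherence) is testable without any imaging
download: this module builds four-scan sessions in which two "thalamus" seed
blobs and a salience-network-like spatial component carry a low-frequency
oscillation whose mutual phase relationship follows a scripted per-phase
protocol, embedded in voxelwise AR(1) ("red") noise with white-matter and
CSF nuisance compartments.

The default protocol encodes the qualitative attack sequence the analysis
is designed to detect: seed and network in antiphase at baseline, seed
leading by 90 degrees in the prodrome, no coherent relationship at the
full-blown peak, and in-phase coupling during recovery.

All generators are pure functions of their configuration and seed: the same
(config, subject_index) always yields bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .prep import BoldScan, LabelAtlas, TimeCourse, PHASES

__all__ = [
    "PhaseSpec",
    "SynthConfig",
    "GroundTruth",
    "INCOHERENT",
    "default_phase_protocol",
    "gen_ar1_series",
    "gen_oscillatory_pair",
    "gen_session",
    "gen_study",
]

#: Sentinel for a phase with no coherent seed/network relationship.
INCOHERENT = "incoherent"

ATLAS_NAMES = {1: "left_thalamus", 2: "right_thalamus", 3: "wm", 4: "csf"}


@dataclass(frozen=True)
class PhaseSpec:
    """Planted coupling for one attack phase.

    ``phase_offset_rad`` is the angle by which the network signal is shifted
    relative to the seed signal (network = sin(wt + offset)); under the
    coherence phase convention used in :mod:`thalfc.wca` the measured
    seed-vs-network phase recovers this value with its sign.  The sentinel
    :data:`INCOHERENT` replaces the network oscillation with independent
    AR(1) noise.  ``coupling_snr`` is the oscillation amplitude divided by
    the stationary noise standard deviation.
    """

    phase_name: str
    phase_offset_rad: float | str
    coupling_snr: float = 1.0

    def __post_init__(self) -> None:
        if self.phase_name not in PHASES:
            raise ValueError(f"unknown phase {self.phase_name!r}")
        if self.phase_offset_rad != INCOHERENT:
            off = float(self.phase_offset_rad)
            if not (-np.pi < off <= np.pi):
                raise ValueError("phase_offset_rad must lie in (-pi, pi]")
        if self.coupling_snr < 0:
            raise ValueError("coupling_snr must be >= 0")

    @property
    def coherent(self) -> bool:
        return self.phase_offset_rad != INCOHERENT


def default_phase_protocol(snr: float = 1.0) -> tuple[PhaseSpec, ...]:
    """Antiphase baseline, seed-leads prodrome, incoherent peak, in-phase recovery."""
    return (
        PhaseSpec("baseline", np.pi, snr),
        PhaseSpec("prodrome", -np.pi / 2, snr),
        PhaseSpec("full_blown", INCOHERENT, snr),
        PhaseSpec("recovery", 0.0, snr),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study-level generator configuration.

    Defaults mirror the acquisition the pipeline targets: 200 volumes per
    scan at TR = 3.01 s on a 2.5 mm isotropic grid, a planted oscillation at
    0.05 Hz (inside the 0.007 Hz high-pass pass-band and far below the
    0.166 Hz Nyquist), and five subjects.
    """

    n_subjects: int = 5
    n_volumes_per_scan: int = 200
    tr_s: float = 3.01
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_mm: float = 2.5
    osc_freq_hz: float = 0.05
    ar1_phi: float = 0.3
    ar1_sigma: float = 1.0
    baseline_intensity: float = 100.0
    nuisance_amp: float = 2.0          # compartment signal, units of noise SD
    noise_spatial_fwhm_mm: float = 0.0  # optional spatial noise smoothing
    seed: int = 0
    phase_protocol: tuple[PhaseSpec, ...] = field(default_factory=default_phase_protocol)

    def __post_init__(self) -> None:
        if self.n_volumes_per_scan < 8:
            raise ValueError("need at least 8 volumes per scan")
        if not (0 <= self.ar1_phi < 1):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.osc_freq_hz >= 0.5 / self.tr_s:
            raise ValueError("osc_freq_hz at or above Nyquist")
        if len(self.phase_protocol) != 4:
            raise ValueError("phase_protocol must have exactly 4 entries")
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid dims must be positive")

    @property
    def noise_sd(self) -> float:
        """Stationary AR(1) standard deviation sigma/sqrt(1 - phi^2)."""
        return self.ar1_sigma / np.sqrt(1.0 - self.ar1_phi ** 2)

    def affine(self) -> np.ndarray:
        """Isotropic affine centring the grid on the world origin."""
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = -0.5 * (np.asarray(self.grid_dims) - 1) * self.voxel_mm
        return aff


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery testing."""

    seed_masks: dict[str, np.ndarray]
    network_map: np.ndarray
    phase_schedule: tuple[PhaseSpec, ...]
    noise_params: tuple[float, float]
    component_timecourses: list[dict[str, np.ndarray]]


# ---------------------------------------------------------------------------
# 1D generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator,
         size: int | None = None) -> np.ndarray:
    """Stationary AR(1) sample paths; shape (n,) or (size, n)."""
    shape = (n,) if size is None else (size, n)
    eps = rng.standard_normal(shape) * sigma
    x = np.empty(shape)
    # stationary initialisation: x0 ~ N(0, sigma^2 / (1 - phi^2))
    x[..., 0] = eps[..., 0] / np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        x[..., t] = phi * x[..., t - 1] + eps[..., t]
    return x


def gen_ar1_series(n: int, phi: float, sigma: float, seed) -> TimeCourse:
    """Stationary AR(1) (red-noise) series x_t = phi*x_{t-1} + eps_t.

    The first sample is drawn from the stationary distribution
    N(0, sigma^2/(1-phi^2)), so the whole path is stationary.  ``seed`` may
    be an integer or a ``numpy.random.Generator``.
    """
    if not (0 <= phi < 1):
        raise ValueError("phi must lie in [0, 1) for a stationary surrogate")
    if n < 2:
        raise ValueError("need n >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return TimeCourse(samples=_ar1(n, phi, sigma, _as_rng(seed)), dt_s=1.0,
                      provenance=f"ar1(phi={phi}, sigma={sigma})")


def gen_oscillatory_pair(n: int, dt: float, freq: float, phase_offset: float,
                         snr: float, phi: float = 0.3, seed=0,
                         ) -> tuple[TimeCourse, TimeCourse]:
    """Pair of sinusoids with a fixed mutual phase offset in AR(1) noise.

    ``x_t = sin(2 pi f t dt) + noise`` and
    ``y_t = sin(2 pi f t dt + phase_offset) + noise`` with independent AR(1)
    noise scaled so that (unit) oscillation amplitude over noise SD equals
    ``snr``.  ``snr = inf`` disables the noise and returns pure sinusoids.
    """
    if not (0 < freq < 0.5 / dt):
        raise ValueError("freq must lie strictly below Nyquist")
    t = np.arange(n) * dt
    x = np.sin(2 * np.pi * freq * t)
    y = np.sin(2 * np.pi * freq * t + phase_offset)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive (or inf for noise-free)")
        rng = _as_rng(seed)
        target_sd = 1.0 / snr
        sigma = target_sd * np.sqrt(1.0 - phi ** 2)
        x = x + _ar1(n, phi, sigma, rng)
        y = y + _ar1(n, phi, sigma, rng)
    dt_ = float(dt)
    return (TimeCourse(x, dt_, provenance="oscillatory pair x"),
            TimeCourse(y, dt_, provenance="oscillatory pair y"))


# ---------------------------------------------------------------------------
# Spatial layout
# ---------------------------------------------------------------------------

def _sphere_mask(dims, center_vox, radius_vox) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return d2 <= radius_vox ** 2


def _gauss_blob(dims, center_vox, sd_vox) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return np.exp(-0.5 * d2 / sd_vox ** 2)


def build_layout(config: SynthConfig):
    """Seed masks, salience-like network map, WM/CSF compartments, atlas.

    Two spherical thalamic blobs sit mid-grid; the network map is three
    Gaussian clusters (bilateral insula-like plus a dorsal midline one);
    WM and CSF are the bottom and top slice pairs.  Raises when the grid is
    too small to keep the components apart.
    """
    dims = config.grid_dims
    if min(dims[0], dims[1]) < 12 or dims[2] < 8:
        raise ValueError(
            f"grid {dims} too small to place seeds, network clusters and "
            "WM/CSF compartments without overlap; need >= 12x12x8")
    cx, cy, cz = dims
    seeds = {
        "left_thalamus": _sphere_mask(dims, (0.32 * cx, 0.5 * cy, 0.5 * cz), 2.0),
        "right_thalamus": _sphere_mask(dims, (0.68 * cx, 0.5 * cy, 0.5 * cz), 2.0),
    }
    net = (_gauss_blob(dims, (0.18 * cx, 0.22 * cy, 0.62 * cz), 1.6)
           + _gauss_blob(dims, (0.82 * cx, 0.22 * cy, 0.62 * cz), 1.6)
           + _gauss_blob(dims, (0.5 * cx, 0.85 * cy, 0.62 * cz), 1.6))
    net /= net.max()
    net[net < 1e-3] = 0.0
    labels = np.zeros(dims, dtype=np.int32)
    labels[:, :, :2] = 3      # WM slab
    labels[:, :, -2:] = 4     # CSF slab
    labels[seeds["left_thalamus"]] = 1
    labels[seeds["right_thalamus"]] = 2
    # keep compartments clear of planted components
    net[:, :, :2] = 0.0
    net[:, :, -2:] = 0.0
    for m in seeds.values():
        if (net[m] > 0.5).any():
            raise ValueError("layout failure: network map overlaps a seed blob")
    atlas = LabelAtlas(labels=labels, affine=config.affine(), names=dict(ATLAS_NAMES))
    return seeds, net, atlas


# ---------------------------------------------------------------------------
# Session generator
# ---------------------------------------------------------------------------

def gen_session(config: SynthConfig, subject_index: int,
                ) -> tuple[list[BoldScan], LabelAtlas, GroundTruth]:
    """One subject's four-phase session.

    Each scan carries: voxelwise AR(1) noise everywhere; the seed signal in
    both thalamic blobs; the network signal, weighted by the network map,
    whose phase offset relative to the seed follows that phase's
    :class:`PhaseSpec`; and a shared nuisance signal in the WM and CSF
    compartments.  The scan-level absolute oscillation phase is drawn from
    the study seed (common to all subjects), so group averaging preserves
    the planted coupling.
    """
    seeds, net_map, atlas = build_layout(config)
    dims = config.grid_dims
    n = config.n_volumes_per_scan
    n_vox = int(np.prod(dims))
    t = np.arange(n) * config.tr_s
    omega = 2 * np.pi * config.osc_freq_hz

    # study-level stream: per-scan absolute phases, shared across subjects
    study_rng = np.random.default_rng([config.seed, 7919])
    scan_phases = study_rng.uniform(-np.pi, np.pi, size=4)

    scans: list[BoldScan] = []
    comp_tcs: list[dict[str, np.ndarray]] = []
    osc_amp0 = config.noise_sd  # amplitude at snr = 1

    for scan_idx, spec in enumerate(config.phase_protocol):
        rng = np.random.default_rng([config.seed, subject_index, scan_idx])
        amp = spec.coupling_snr * osc_amp0
        phi0 = scan_phases[scan_idx]
        seed_sig = amp * np.sin(omega * t + phi0)
        if spec.coherent:
            net_sig = amp * np.sin(omega * t + phi0 + float(spec.phase_offset_rad))
        else:
            net_sig = _ar1(n, config.ar1_phi, config.ar1_sigma, rng) * spec.coupling_snr

        noise = _ar1(n, config.ar1_phi, config.ar1_sigma, rng, size=n_vox
                     ).reshape(*dims, n)
        if config.noise_spatial_fwhm_mm > 0:
            sig_vox = config.noise_spatial_fwhm_mm / (
                2 * np.sqrt(2 * np.log(2))) / config.voxel_mm
            noise = ndimage.gaussian_filter(noise, sigma=(sig_vox,) * 3 + (0.0,),
                                            mode="nearest")
        data = config.baseline_intensity + noise
        for m in seeds.values():
            data[m] += seed_sig
        data += net_map[..., None] * net_sig

        # compartment signals at nuisance_amp x the voxel-noise SD
        wm_sig = config.nuisance_amp * _ar1(n, config.ar1_phi, config.ar1_sigma, rng)
        csf_sig = config.nuisance_amp * _ar1(n, config.ar1_phi, config.ar1_sigma, rng)
        data[atlas.labels == 3] += wm_sig
        data[atlas.labels == 4] += csf_sig

        scans.append(BoldScan(data=data, affine=config.affine(),
                              tr_s=config.tr_s, phase_name=spec.phase_name))
        comp_tcs.append({"seed": seed_sig.copy(), "network": net_sig.copy(),
                         "wm": wm_sig, "csf": csf_sig})

    truth = GroundTruth(seed_masks=seeds, network_map=net_map,
                        phase_schedule=tuple(config.phase_protocol),
                        noise_params=(config.ar1_phi, config.ar1_sigma),
                        component_timecourses=comp_tcs)
    return scans, atlas, truth


def gen_study(config: SynthConfig):
    """All subjects' sessions: list of (scans, atlas, truth) per subject."""
    return [gen_session(config, i) for i in range(config.n_subjects)]
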
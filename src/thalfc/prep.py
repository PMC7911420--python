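"""ROI construction, temporal preprocessing, and time-course extraction.

This module houses the in-memory containers for 4D BOLD data
(:class:`BoldScan`), integer label atlases (:class:`LabelAtlas`), spherical
ROI specifications in MNI millimetres (:class:`SphereRoi`) and 1D signals
(:class:`TimeCourse`), together with the preprocessing chain applied before
any connectivity analysis: high-pass temporal filtering, Gaussian spatial
smoothing, white-matter/CSF nuisance regression, and mean-time-course
extraction.

Conventions
-----------
* World space is MNI millimetres, reached from 0-based voxel indices through
  the NIfTI affine.
* A voxel belongs to a spherical ROI when its *centre* lies within the
  sphere's radius, boundary inclusive.
* The high-pass filter applies a raised-cosine roll-off in the discrete
  cosine (DCT-II) basis (see :func:`highpass_response`), so its response is
  analytic and inspectable rather than an opaque running-line detrend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import nibabel as nib
from scipy import ndimage


__all__ = [
    "BoldScan",
    "LabelAtlas",
    "SphereRoi",
    "TimeCourse",
    "small_volume_rois",
    "make_sphere_roi",
    "highpass",
    "highpass_response",
    "spatial_smooth",
    "regress_nuisance",
    "extract_mean_timecourse",
    "concatenate_timecourses",
    "load_bold",
    "save_volume",
]

PHASES = ("baseline", "prodrome", "full_blown", "recovery")


def small_volume_rois() -> tuple["SphereRoi", ...]:
    """The eight brainstem/diencephalic spheres used for small-volume
    correction: MNI-mm centres of previously reported pain-circuit
    activations with anatomically chosen radii."""
    return (
        SphereRoi((-8, -24, -32), 5, "left_dorsal_pons"),
        SphereRoi((8, -24, -32), 5, "right_dorsal_pons"),
        SphereRoi((-2, -28, -6), 3, "left_pag"),
        SphereRoi((4, -28, -6), 3, "right_pag"),
        SphereRoi((0, 2, -6), 3, "hypothalamus"),
        SphereRoi((4, -40, -55), 3, "left_spinal_trigeminal_pars_caudalis"),
        SphereRoi((-4, -40, -55), 3, "right_spinal_trigeminal_pars_caudalis"),
        SphereRoi((0, -28, -12), 3, "dorsal_raphe"),
    )

#: Residual bound for a unit-amplitude sinusoid at or below half the
#: high-pass cutoff on windows of >= 4 cutoff periods.  The filter's gain in
#: the stop band is exactly zero; the residual is the drift's own
#: finite-window content above the cutoff (a 0.6-cycle drift carries ~8% of
#: its amplitude there), which any filter with the documented pass band must
#: let through.
HIGHPASS_STOPBAND_BOUND = 0.1


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BoldScan:
    """One phase's 4D volume series.

    Parameters
    ----------
    data
        Intensities indexed ``(i, j, k, t)``.
    affine
        4x4 voxel-to-world (MNI mm) map.
    tr_s
        Repetition time in seconds.
    phase_name
        Attack-phase label (one of ``baseline``, ``prodrome``,
        ``full_blown``, ``recovery``) or any free-text label.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    phase_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldScan data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BoldScan needs at least 2 volumes")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldScan intensities must be finite")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldScan":
        return BoldScan(data=data, affine=self.affine, tr_s=self.tr_s,
                        phase_name=self.phase_name)


@dataclass
class LabelAtlas:
    """Integer label volume plus a label -> region-name table."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels missing from name table: {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        """Binary mask of the region called ``name``."""
        for label, nm in self.names.items():
            if nm == name:
                return self.labels == label
        raise KeyError(f"no atlas region named {name!r}")


@dataclass(frozen=True)
class SphereRoi:
    """Spherical ROI given by an MNI-mm centre and a radius."""

    center_mni: tuple[float, float, float]
    radius_mm: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class TimeCourse:
    """A 1D signal with its sampling interval and provenance.

    ``segment_bounds`` marks the spans of concatenated attack phases as
    half-open ``(start, end)`` index pairs tiling ``[0, n)``.
    """

    samples: np.ndarray
    dt_s: float
    segment_bounds: list[tuple[int, int]] | None = None
    segment_names: list[str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.segment_bounds is not None:
            b = sorted(self.segment_bounds)
            if b[0][0] != 0 or b[-1][1] != len(self.samples):
                raise ValueError("segment bounds must tile [0, n)")
            for (_, e0), (s1, _) in zip(b[:-1], b[1:]):
                if e0 != s1:
                    raise ValueError("segment bounds overlap or leave gaps")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_s

    def with_samples(self, samples: np.ndarray, provenance: str | None = None) -> "TimeCourse":
        return TimeCourse(samples=samples, dt_s=self.dt_s,
                          segment_bounds=self.segment_bounds,
                          segment_names=self.segment_names,
                          provenance=self.provenance if provenance is None else provenance)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_bold(path, tr_s: float | None = None, phase_name: str = "") -> BoldScan:
    """Load a 4D NIfTI file into a :class:`BoldScan`.

    ``tr_s`` overrides the header pixdim[4] when given (headers are often
    wrong in practice).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    return BoldScan(data=data, affine=np.asarray(img.affine), tr_s=tr_s,
                    phase_name=phase_name)


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D/4D array as NIfTI, preserving the given affine."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# Spherical ROIs
# ---------------------------------------------------------------------------

def _grid_world_coords(shape3d, affine) -> np.ndarray:
    """World (mm) coordinates of every voxel centre; shape (nx, ny, nz, 3)."""
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape3d), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return vox @ np.asarray(affine, dtype=float).T[:, :3]


def make_sphere_roi(sphere: SphereRoi, reference: BoldScan | LabelAtlas) -> np.ndarray:
    """Binary mask of voxels whose centre lies within the sphere (inclusive).

    Raises
    ------
    ValueError
        If no voxel centre falls inside the sphere (sphere off-grid).
    """
    shape3d = reference.data.shape[:3] if isinstance(reference, BoldScan) else reference.labels.shape
    world = _grid_world_coords(shape3d, reference.affine)
    d2 = np.sum((world - np.asarray(sphere.center_mni, dtype=float)) ** 2, axis=-1)
    mask = d2 <= sphere.radius_mm ** 2 + 1e-9
    if not mask.any():
        raise ValueError(
            f"sphere ROI {sphere.name or sphere.center_mni} (r={sphere.radius_mm} mm) "
            "contains no voxel centre on this grid")
    return mask


# ---------------------------------------------------------------------------
# High-pass filter
# ---------------------------------------------------------------------------

def highpass_response(freqs_hz: np.ndarray, cutoff_hz: float) -> np.ndarray:
    """Amplitude response of the raised-cosine high-pass filter.

    The response is 0 at or below ``cutoff/2``, 1 at or above ``3*cutoff/2``,
    with a half-cosine transition centred on the cutoff.  DC is always
    removed.  This function *is* the documented filter: :func:`highpass`
    applies exactly these gains to the DCT-II coefficients (basis frequency
    ``k / (2 n dt)``), whose implicit even extension keeps slow drifts free
    of wrap-around leakage.
    """
    f = np.abs(np.asarray(freqs_hz, dtype=float))
    lo, hi = 0.5 * cutoff_hz, 1.5 * cutoff_hz
    resp = np.clip((f - lo) / (hi - lo), 0.0, 1.0)
    resp = 0.5 * (1.0 - np.cos(np.pi * resp))
    resp[f == 0.0] = 0.0
    return resp


def _highpass_array(x: np.ndarray, dt_s: float, cutoff_hz: float) -> np.ndarray:
    # Diagonal filter in the DCT-II basis: the implicit even extension keeps
    # slow drifts compact in a few low-order coefficients (no wrap-around
    # leakage), so the raised-cosine gain removes them cleanly.  Basis
    # frequency of coefficient k is k / (2 n dt).
    from scipy.fft import dct, idct
    n = x.shape[-1]
    freqs = np.arange(n) / (2.0 * n * dt_s)
    gain = highpass_response(freqs, cutoff_hz)
    return idct(dct(x, type=2, norm="ortho", axis=-1) * gain,
                type=2, norm="ortho", axis=-1)


def highpass(tc, cutoff_hz: float):
    """High-pass filter a :class:`TimeCourse` or :class:`BoldScan`.

    Removes the mean and all fluctuations slower than the cutoff; frequencies
    well above the cutoff pass essentially unattenuated (see
    :func:`highpass_response`).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if isinstance(tc, TimeCourse):
        if cutoff_hz >= 0.5 / tc.dt_s:
            raise ValueError("cutoff at or above Nyquist")
        return tc.with_samples(_highpass_array(tc.samples, tc.dt_s, cutoff_hz))
    if isinstance(tc, BoldScan):
        if cutoff_hz >= 0.5 / tc.tr_s:
            raise ValueError("cutoff at or above Nyquist")
        return tc.with_data(_highpass_array(tc.data, tc.tr_s, cutoff_hz))
    raise TypeError(f"cannot high-pass a {type(tc).__name__}")


# ---------------------------------------------------------------------------
# Spatial smoothing
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def spatial_smooth(scan: BoldScan, fwhm_mm: float) -> BoldScan:
    """Per-volume Gaussian smoothing with the given FWHM in millimetres.

    The kernel sigma is converted from mm to voxels through the affine's
    column scales; only orthogonal (possibly flipped/permuted) affines are
    supported, since an oblique affine has no per-axis voxel size.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return scan
    rzs = scan.affine[:3, :3]
    gram = rzs.T @ rzs
    off = gram - np.diag(np.diag(gram))
    if np.max(np.abs(off)) > 1e-6 * np.max(np.diag(gram)):
        raise ValueError("spatial_smooth supports only orthogonal affines")
    voxel_mm = np.sqrt(np.diag(gram))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    out = ndimage.gaussian_filter(scan.data, sigma=(*sigma_vox, 0.0), mode="nearest")
    return scan.with_data(out)


# ---------------------------------------------------------------------------
# Nuisance regression
# ---------------------------------------------------------------------------

def regress_nuisance(scan: BoldScan, nuisance_masks: list[np.ndarray],
                     extra_regressors: np.ndarray | None = None) -> BoldScan:
    """Regress compartment mean signals (plus an intercept) out of every voxel.

    Each mask contributes its spatial-mean time series as one regressor.
    Returns the residual scan; residuals are orthogonal to every regressor.
    Linearly dependent regressors are tolerated via the pseudo-inverse.
    """
    if not nuisance_masks:
        raise ValueError("need at least one nuisance mask")
    n_t = scan.n_volumes
    cols = [np.ones(n_t)]
    for m in nuisance_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != scan.shape3d:
            raise ValueError("nuisance mask geometry mismatch")
        if not m.any():
            raise ValueError("empty nuisance mask")
        cols.append(scan.data[m].mean(axis=0))
    if extra_regressors is not None:
        extra = np.atleast_2d(np.asarray(extra_regressors, dtype=float))
        if extra.shape[0] == n_t:
            extra = extra.T
        cols.extend(list(extra))
    X = np.column_stack(cols)
    Y = scan.data.reshape(-1, n_t).T            # (t, voxels)
    beta = np.linalg.pinv(X) @ Y
    resid = (Y - X @ beta).T.reshape(scan.data.shape)
    return scan.with_data(resid)


# ---------------------------------------------------------------------------
# Time-course extraction and concatenation
# ---------------------------------------------------------------------------

def extract_mean_timecourse(scan: BoldScan, mask: np.ndarray,
                            name: str = "roi") -> TimeCourse:
    """Spatial-mean time series over a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scan.shape3d:
        raise ValueError("mask geometry mismatch")
    if not mask.any():
        raise ValueError(f"ROI {name!r}: mask is empty")
    return TimeCourse(samples=scan.data[mask].mean(axis=0), dt_s=scan.tr_s,
                      provenance=f"mean over {name} ({int(mask.sum())} voxels), "
                                 f"phase={scan.phase_name}")


def concatenate_timecourses(parts: list[TimeCourse]) -> TimeCourse:
    """Join time courses in order, recording each part's span.

    All parts must share the sampling interval.  The result's
    ``segment_bounds`` are half-open index pairs, e.g. four 200-sample parts
    give ``[(0, 200), (200, 400), (400, 600), (600, 800)]``.
    """
    if not parts:
        raise ValueError("need at least one time course")
    dt = parts[0].dt_s
    for p in parts:
        if abs(p.dt_s - dt) > 1e-12:
            raise ValueError("mismatched sampling intervals")
    bounds, names, pos = [], [], 0
    for p in parts:
        bounds.append((pos, pos + len(p)))
        names.append(p.provenance)
        pos += len(p)
    return TimeCourse(samples=np.concatenate([p.samples for p in parts]),
                      dt_s=dt, segment_bounds=bounds, segment_names=names,
                      provenance="concatenation of %d segments" % len(parts))
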
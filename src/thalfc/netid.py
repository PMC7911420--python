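"""Group spatial ICA, salience-network selection by template matching, and
per-scan network time-course extraction (stage-1 dual regression).

The group decomposition follows the usual temporal-concatenation scheme:
per-subject scans are stacked along time, the stacked matrix is
PCA-reduced/whitened and decomposed with fixed-point ICA maximising spatial
non-Gaussianity.  Model order is a fixed component count or a PCA
variance-explained threshold; full Bayesian model-order estimation is out
of scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd

from .prep import BoldScan, TimeCourse

__all__ = [
    "IcaDecomposition",
    "NetworkTemplate",
    "temporal_concat_group",
    "group_spatial_ica",
    "select_network",
    "network_timecourse",
    "average_across_subjects",
]


@dataclass
class IcaDecomposition:
    """Spatial ICA result.

    ``maps`` is (k, voxels) with unit-norm rows, sign-aligned so each map's
    largest-magnitude weight is positive, ordered by variance explained.
    ``mixing`` is (time, k); ``grid_shape`` allows reshaping maps to 3D.
    """

    maps: np.ndarray
    mixing: np.ndarray
    variance_explained: np.ndarray
    grid_shape: tuple[int, ...] | None = None
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, idx: int) -> np.ndarray:
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        return self.maps[idx].reshape(self.grid_shape)


@dataclass
class NetworkTemplate:
    """Spatial weight map (or binary mask) naming a target network."""

    weights: np.ndarray
    name: str = "salience"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights):
            raise ValueError("empty network template")


def temporal_concat_group(scans_per_subject: list[list[BoldScan]]) -> np.ndarray:
    """Stack scans into a (time x voxels) matrix, subject-by-subject.

    Each scan's voxel series is demeaned before stacking, so no subject- or
    scan-level offset leaks into the decomposition.
    """
    if not scans_per_subject or not scans_per_subject[0]:
        raise ValueError("need at least one subject with one scan")
    shape = scans_per_subject[0][0].shape3d
    rows = []
    for scans in scans_per_subject:
        for scan in scans:
            if scan.shape3d != shape:
                raise ValueError("geometry mismatch across scans")
            X = scan.data.reshape(-1, scan.n_volumes).T  # (t, voxels)
            rows.append(X - X.mean(axis=0, keepdims=True))
    return np.vstack(rows)


def group_spatial_ica(data: np.ndarray, k: int, seed: int = 0,
                      fun: str = "logcosh", max_iter: int = 500,
                      tol: float = 1e-6,
                      grid_shape: tuple[int, ...] | None = None,
                      ) -> IcaDecomposition:
    """Spatial ICA of a demeaned (time x voxels) matrix.

    The data are whitened to ``k`` dimensions and unmixed by fixed-point
    (FastICA) iteration treating voxels as samples, so the recovered sources
    are spatial maps and the mixing matrix holds their time courses.
    Deterministic given ``seed``; raises if the iteration does not converge
    within ``max_iter``.
    """
    data = np.asarray(data, dtype=float)
    if k > min(data.shape):
        raise ValueError(f"k={k} exceeds data rank bound {min(data.shape)}")
    if max(data.shape) <= 2048:  # exact rank check affordable on small data
        rank = np.linalg.matrix_rank(data)
        if k > rank:
            raise ValueError(f"k={k} exceeds numerical data rank {rank}")

    # PCA-whiten to k dimensions via randomized SVD; rows of Vt are the
    # orthonormal spatial principal components
    U, s, Vt = randomized_svd(data, n_components=k, random_state=seed)
    if np.any(s <= s[0] * 1e-12):
        raise ValueError(f"k={k} exceeds numerical data rank")
    n_vox = data.shape[1]
    white = Vt.T * np.sqrt(n_vox)                     # (voxels, k), identity cov
    n_iter = 0
    if k == 1:
        # the 1D rotation is +-1: the component is the singular vector itself
        maps = Vt.copy()
        mixing = (U * s)                              # (time, 1)
    else:
        ica = FastICA(n_components=k, random_state=np.random.RandomState(seed),
                      fun=fun, max_iter=max_iter, tol=tol, whiten=False)
        import warnings as _warnings
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            ica.fit(white)
            if any("did not converge" in str(w.message) for w in caught):
                raise RuntimeError(
                    f"ICA did not converge within {max_iter} iterations "
                    f"(ran {ica.n_iter_})")
        n_iter = int(ica.n_iter_)
        R = ica.components_                           # (k, k) unmixing rotation
        maps = R @ Vt                                 # (k, voxels)
        mixing = (U * s) @ np.linalg.pinv(R)          # (time, k)

    # sign-align: largest-magnitude weight positive
    for i in range(k):
        j = np.argmax(np.abs(maps[i]))
        if maps[i, j] < 0:
            maps[i] = -maps[i]
            mixing[:, i] = -mixing[:, i]
    # unit-norm maps, compensating in the mixing time courses
    norms = np.linalg.norm(maps, axis=1)
    maps = maps / norms[:, None]
    mixing = mixing * norms[None, :]
    # order by variance explained (power of each rank-1 term)
    power = (mixing ** 2).sum(axis=0)  # maps are unit-norm
    order = np.argsort(power)[::-1]
    total = float((data ** 2).sum())
    var_exp = power[order] / total if total > 0 else power[order]
    return IcaDecomposition(maps=maps[order], mixing=mixing[:, order],
                            variance_explained=var_exp, grid_shape=grid_shape,
                            n_iter=n_iter)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two flattened spatial maps."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return 0.0
    return float(a @ b / den)


def select_network(decomp: IcaDecomposition, template: NetworkTemplate,
                   floor: float = 0.3) -> dict:
    """Pick the component most resembling the template map.

    Returns the winning index, its map, the |spatial correlation| score and
    the runner-up margin.  A best score below ``floor`` raises a warning but
    still returns the best match.
    """
    tmpl = template.weights.ravel()
    if tmpl.size != decomp.maps.shape[1]:
        raise ValueError("template grid does not match decomposition")
    scores = np.array([abs(spatial_correlation(m, tmpl)) for m in decomp.maps])
    order = np.argsort(scores)[::-1]
    best = int(order[0])
    margin = float(scores[order[0]] - scores[order[1]]) if decomp.k > 1 else float("inf")
    if scores[best] < floor:
        import warnings
        warnings.warn(
            f"best template match |r|={scores[best]:.3f} below floor {floor}; "
            f"no component resembles {template.name!r}")
    sel_map = decomp.maps[best]
    if spatial_correlation(sel_map, tmpl) < 0:
        sel_map = -sel_map  # orient toward the template
    return {"index": best, "map": sel_map, "correlation": float(scores[best]),
            "runner_up_margin": margin}


def network_timecourse(spatial_map: np.ndarray, scan: BoldScan) -> TimeCourse:
    """Per-volume regression weight of the network map (dual-regression stage 1).

    For each volume t the voxel intensities are regressed on
    ``[intercept, map]``; the returned series is the map coefficient.
    """
    w = np.asarray(spatial_map, dtype=float).ravel()
    if w.size != int(np.prod(scan.shape3d)):
        raise ValueError("spatial map does not match scan grid")
    wc = w - w.mean()
    denom = float(wc @ wc)
    if denom == 0:
        raise ValueError("constant spatial map: regression undefined")
    Y = scan.data.reshape(-1, scan.n_volumes)        # (voxels, t)
    beta = (wc @ Y) / denom
    return TimeCourse(samples=beta, dt_s=scan.tr_s,
                      provenance=f"network regression, phase={scan.phase_name}")


def average_across_subjects(tcs: list[TimeCourse],
                            standardize: bool = True) -> TimeCourse:
    """Pointwise mean of per-subject (z-scored) signals, bounds preserved.

    Subject signals are z-scored before averaging so no subject dominates
    the group signal; disable with ``standardize=False``.
    """
    if not tcs:
        raise ValueError("need at least one time course")
    n = len(tcs[0])
    dt = tcs[0].dt_s
    for tc in tcs:
        if len(tc) != n or abs(tc.dt_s - dt) > 1e-12:
            raise ValueError("length/dt mismatch across subjects")
    stack = np.stack([tc.samples for tc in tcs])
    if standardize:
        mu = stack.mean(axis=1, keepdims=True)
        sd = stack.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        stack = (stack - mu) / sd
    return TimeCourse(samples=stack.mean(axis=0), dt_s=dt,
                      segment_bounds=tcs[0].segment_bounds,
                      segment_names=tcs[0].segment_names,
                      provenance=f"average of {len(tcs)} subjects")
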
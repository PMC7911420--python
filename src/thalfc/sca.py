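"""Static functional connectivity: seed-based correlation maps, group
inference by sign-flip permutations with threshold-free cluster enhancement
(TFCE) and family-wise error (FWE) correction, and the baseline-normalised
relative-change-in-FC (rcFC) index with its across-phase comparison.

The rcFC index for a phase x is

    rcFC_x = (meanFC_x - meanFC_baseline) / meanFC_baseline

where meanFC is the mean correlation over the non-zero voxels of the
group-significant mask.  rcFC is zero at baseline by construction and
invariant to a common positive rescaling of all meanFC values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .prep import BoldScan, TimeCourse

__all__ = [
    "ScaMap",
    "GroupStat",
    "RcfcTable",
    "seed_correlation_map",
    "fisher_z",
    "tfce_enhance",
    "group_mean_effect",
    "mean_fc_over_mask",
    "rcfc",
    "compare_rcfc",
]

#: t value substituted where the across-subject standard deviation is zero
#: but the mean is not (e.g. identical input maps).
_T_DEGENERATE = 1e10


@dataclass
class ScaMap:
    """Voxelwise seed-correlation volume (Pearson r, or Fisher z)."""

    values: np.ndarray
    affine: np.ndarray
    seed_name: str = ""
    phase_name: str = ""
    subject_id: str = ""
    fisher: bool = False
    zero_variance_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.fisher and np.nanmax(np.abs(self.values), initial=0) > 1 + 1e-9:
            raise ValueError("correlation map exceeds |r| = 1")


@dataclass
class GroupStat:
    """Permutation-TFCE group mean-effect statistic."""

    tstat: np.ndarray
    tfce: np.ndarray
    fwe_p: np.ndarray
    n_permutations: int
    exhaustive: bool
    covariate_names: list[str] = field(default_factory=list)

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        return self.fwe_p < alpha


@dataclass
class RcfcTable:
    """Per-phase meanFC and rcFC for one seed, with subject-level values."""

    seed_name: str
    phases: list[str]
    mean_fc: dict[str, float]
    rcfc_values: dict[str, float]
    subject_mean_fc: pd.DataFrame  # rows subjects, columns phases

    def to_frame(self) -> pd.DataFrame:
        rows = [{"seed": self.seed_name, "phase": p,
                 "meanFC": self.mean_fc[p], "rcFC": self.rcfc_values[p]}
                for p in self.phases]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

def seed_correlation_map(scan: BoldScan, seed_tc: TimeCourse,
                         seed_name: str = "", subject_id: str = "") -> ScaMap:
    """Pearson correlation of every voxel's series with the seed series.

    Voxels with zero temporal variance get r = 0 and are flagged in
    ``zero_variance_mask``.
    """
    ref = np.asarray(seed_tc.samples, dtype=float)
    if len(ref) != scan.n_volumes:
        raise ValueError(
            f"seed length {len(ref)} != scan volumes {scan.n_volumes}")
    Y = scan.data.reshape(-1, scan.n_volumes)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    ref_ss = float(np.sqrt(np.sum(rc ** 2)))
    if ref_ss == 0:
        raise ValueError("seed time course is constant")
    vox_ss = np.sqrt(np.sum(Yc ** 2, axis=1))
    zero_var = vox_ss == 0
    denom = np.where(zero_var, 1.0, vox_ss) * ref_ss
    r = (Yc @ rc) / denom
    r[zero_var] = 0.0
    r = np.clip(r, -1.0, 1.0)  # guard float overshoot only
    return ScaMap(values=r.reshape(scan.shape3d), affine=scan.affine,
                  seed_name=seed_name, phase_name=scan.phase_name,
                  subject_id=subject_id,
                  zero_variance_mask=zero_var.reshape(scan.shape3d))


def fisher_z(m: ScaMap) -> ScaMap:
    """Voxelwise Fisher z = atanh(r); |r| = 1 is clipped with a warning."""
    if m.fisher:
        return m
    r = m.values
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlations at |r| = 1 clipped to 1 - 1e-7 before atanh")
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return ScaMap(values=np.arctanh(r), affine=m.affine, seed_name=m.seed_name,
                  phase_name=m.phase_name, subject_id=m.subject_id, fisher=True,
                  zero_variance_mask=m.zero_variance_mask)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be one of {6, 18, 26}")
    return ndimage.generate_binary_structure(3, rank)


def _tfce_positive(stat: np.ndarray, E: float, H: float, dh: float,
                   structure: np.ndarray) -> np.ndarray:
    out = np.zeros_like(stat)
    top = float(stat.max(initial=0.0))
    if top <= 0:
        return out
    h = dh
    while h <= top + 1e-12:
        mask = stat >= h
        lbl, n_lbl = ndimage.label(mask, structure=structure)
        if n_lbl:
            sizes = np.bincount(lbl.ravel())
            out[mask] += (sizes[lbl[mask]] ** E) * (h ** H) * dh
        h += dh
    return out


def tfce_enhance(stat_volume: np.ndarray, E: float = 0.5, H: float = 2.0,
                 dh: float | None = None, connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic volume.

    For each voxel v, sums e(h)^E * h^H * dh over thresholds
    h = dh, 2dh, ... <= stat(v), where e(h) is the size of v's connected
    suprathreshold component at height h.  Negative values are enhanced on
    the negated volume and returned negated, so the output is signed.

    ``dh`` defaults to max(|stat|)/100.
    """
    stat = np.asarray(stat_volume, dtype=float)
    if stat.ndim != 3:
        raise ValueError("TFCE expects a 3D volume")
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite values in statistic volume")
    if dh is None:
        top = float(np.abs(stat).max(initial=0.0))
        if top == 0:
            return np.zeros_like(stat)
        dh = top / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = _connectivity_structure(connectivity)
    pos = _tfce_positive(np.where(stat > 0, stat, 0.0), E, H, dh, structure)
    neg = _tfce_positive(np.where(stat < 0, -stat, 0.0), E, H, dh, structure)
    return pos - neg


# ---------------------------------------------------------------------------
# Group mean effect with sign-flip permutations
# ---------------------------------------------------------------------------

def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """t across axis 0, with a large finite value where the SD is zero."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    # relative tolerance: identical subject values can leave an sd of a few
    # ulps of the mean, which would otherwise explode into t >> sentinel
    zero = sd <= 1e-12 * np.abs(mean)
    t = np.where(zero, np.sign(mean) * _T_DEGENERATE,
                 mean / np.where(zero, 1.0, sd / np.sqrt(n)))
    return t


def group_mean_effect(maps: list[ScaMap] | np.ndarray,
                      covariates: np.ndarray | pd.DataFrame | None = None,
                      n_perm: int = 5000, seed: int = 0,
                      tfce_E: float = 0.5, tfce_H: float = 2.0,
                      tfce_dh: float | None = None,
                      connectivity: int = 26) -> GroupStat:
    """Group mean-effect inference by sign-flipping subject maps.

    Covariates (age, gender, disease duration, ...) are mean-centred and
    residualised out of each voxel without removing the group mean, in the
    Freedman-Lane spirit: the tested mean effect is the intercept of the
    reduced model.  The null is built by flipping the sign of whole subject
    residual maps; when 2^n <= ``n_perm`` all sign patterns are enumerated,
    otherwise ``n_perm`` random patterns (the identity always included).
    The FWE-corrected p at a voxel is the fraction of permutations whose
    maximum TFCE statistic reaches that voxel's observed TFCE value.
    """
    if isinstance(maps, np.ndarray):
        data = np.asarray(maps, dtype=float)
        cov_names: list[str] = []
    else:
        data = np.stack([m.values for m in maps]).astype(float)
        cov_names = []
    n_sub = data.shape[0]
    vol_shape = data.shape[1:]
    if n_sub < 2:
        raise ValueError("group inference needs at least 2 subjects")
    flat = data.reshape(n_sub, -1)
    if np.all(flat.std(axis=1) == 0):
        raise ValueError("constant maps: no spatial structure to test")

    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
            covariates = covariates.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n_sub:
            raise ValueError("covariate rows must match subjects")
        Xc = X - X.mean(axis=0, keepdims=True)
        if np.any(Xc.std(axis=0) > 0):
            beta = np.linalg.pinv(Xc) @ flat
            flat = flat - Xc @ beta

    t_obs = _one_sample_t(flat)
    if tfce_dh is None:
        top = float(np.abs(t_obs).max(initial=0.0))
        tfce_dh = top / 100.0 if top > 0 else 1.0
    tfce_obs = tfce_enhance(t_obs.reshape(vol_shape), tfce_E, tfce_H,
                            tfce_dh, connectivity)

    exhaustive = 2 ** n_sub <= n_perm
    if exhaustive:
        signs_iter = [np.array(s, dtype=float)
                      for s in itertools.product((1.0, -1.0), repeat=n_sub)]
    else:
        rng = np.random.default_rng(seed)
        signs_iter = [np.ones(n_sub)]
        signs_iter += [rng.choice([1.0, -1.0], size=n_sub)
                       for _ in range(n_perm - 1)]
    n_used = len(signs_iter)

    count_ge = np.zeros(tfce_obs.size)
    tfce_obs_flat = tfce_obs.ravel()
    for signs in signs_iter:
        t_p = _one_sample_t(flat * signs[:, None])
        tfce_p = tfce_enhance(t_p.reshape(vol_shape), tfce_E, tfce_H,
                              tfce_dh, connectivity)
        count_ge += tfce_p.max() >= tfce_obs_flat
    fwe_p = (count_ge / n_used).reshape(vol_shape)

    return GroupStat(tstat=t_obs.reshape(vol_shape), tfce=tfce_obs,
                     fwe_p=fwe_p, n_permutations=n_used,
                     exhaustive=exhaustive, covariate_names=cov_names)


# ---------------------------------------------------------------------------
# rcFC
# ---------------------------------------------------------------------------

def mean_fc_over_mask(m: ScaMap | np.ndarray, sig_mask: np.ndarray) -> float:
    """Mean map value over the non-zero voxels inside the significant mask."""
    values = m.values if isinstance(m, ScaMap) else np.asarray(m, dtype=float)
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if not sig_mask.any():
        raise ValueError("significant mask is empty")
    masked = values[sig_mask]
    nonzero = masked[masked != 0]
    if nonzero.size == 0:
        raise ValueError("all masked values are zero: meanFC undefined")
    return float(nonzero.mean())


def rcfc(mean_fc_x: float, mean_fc_baseline: float) -> float:
    """Relative change in FC: (meanFC_x - meanFC_baseline) / meanFC_baseline."""
    if mean_fc_baseline == 0:
        raise ValueError("rcFC undefined for zero baseline meanFC")
    return (mean_fc_x - mean_fc_baseline) / mean_fc_baseline


def compare_rcfc(subject_mean_fc: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA across phases plus Bonferroni post-hocs.

    ``subject_mean_fc``: rows = subjects, columns = phases, cells =
    per-subject meanFC.  Returns the ANOVA F and p together with all
    pairwise paired-t comparisons, Bonferroni-multiplied (capped at 1).
    Requires a balanced design (no missing cells).
    """
    df = subject_mean_fc
    if df.isna().any().any():
        raise ValueError("balanced design required: missing cells present")
    phases = list(df.columns)
    if len(phases) < 2 or len(df) < 2:
        raise ValueError("need >= 2 phases and >= 2 subjects")

    values = df.to_numpy(dtype=float)
    n_s, n_p = values.shape
    df_phase, df_err = n_p - 1, (n_s - 1) * (n_p - 1)
    ss_phase = n_s * np.sum((values.mean(axis=0) - values.mean()) ** 2)
    if ss_phase <= 1e-30:
        # no phase effect at all (e.g. all phases identical per subject)
        F, p = 0.0, 1.0
    else:
        from statsmodels.stats.anova import AnovaRM
        long = df.reset_index(names="subject").melt(
            id_vars="subject", var_name="phase", value_name="fc")
        res = AnovaRM(long, depvar="fc", subject="subject",
                      within=["phase"]).fit()
        F = float(res.anova_table.loc["phase", "F Value"])
        p = float(res.anova_table.loc["phase", "Pr > F"])
        if not np.isfinite(F):  # zero residual variance with a real effect
            F, p = np.inf, 0.0

    pairs = list(itertools.combinations(phases, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        d = values[:, phases.index(a)] - values[:, phases.index(b)]
        if np.allclose(d.std(ddof=1), 0):
            t_val, p_raw = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.inf, 0.0)
        else:
            t_val, p_raw = stats.ttest_rel(values[:, phases.index(a)],
                                           values[:, phases.index(b)])
        rows.append({"phase_a": a, "phase_b": b, "t": float(t_val),
                     "p_raw": float(p_raw),
                     "p_bonferroni": min(1.0, float(p_raw) * n_comp)})
    return {"anova_F": float(F), "anova_p": float(p),
            "df": (df_phase, df_err),
            "pairwise": pd.DataFrame(rows), "bonferroni_factor": n_comp}
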
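"""End-to-end study orchestration.

Runs the full four-phase connectivity study: simulate (or ingest) the
sessions, preprocess, compute seed-based correlation maps and their group
permutation-TFCE statistics plus the rcFC table, identify the
salience-network-like component by group ICA, build the 800-point
concatenated group signals, run wavelet coherence between each thalamic
seed and the network, summarise the clinical workflow table, and write
everything to disk with a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import netid, sca, wca
from .prep import (PHASES, BoldScan, LabelAtlas, TimeCourse,
                   concatenate_timecourses, extract_mean_timecourse, highpass,
                   regress_nuisance, save_volume, spatial_smooth)
from .synth import SynthConfig, gen_session

__all__ = [
    "StudyConfig",
    "StudyResult",
    "DEFAULT_CLINICAL_WORKFLOW",
    "NRS_BANDS",
    "nrs_band",
    "summarize_clinical",
    "run_study",
    "write_outputs",
]


# ---------------------------------------------------------------------------
# Clinical workflow table
# ---------------------------------------------------------------------------

#: Five-subject NTG-challenge workflow bundled as the package's example
#: clinical dataset: scan delays in minutes after nitroglycerin
#: administration (prodromal and full-blown scans) or after the rescue
#: NSAID (recovery scan), and 0-10 pain scores (NRS) at the full-blown and
#: recovery scans.
DEFAULT_CLINICAL_WORKFLOW = pd.DataFrame({
    "subject": ["EM1", "EM2", "EM3", "EM4", "EM5"],
    "prodrome_delay_min": [80, 31, 110, 38, 65],
    "full_blown_delay_min": [200, 140, 155, 70, 105],
    "nrs_full_blown": [7, 5, 6, 8, 6],
    "recovery_delay_min": [85, 50, 70, 95, 106],
    "nrs_recovery": [1, 0, 1, 0, 1],
})

#: Pain-intensity severity bands on the 0-10 numeric rating scale.
NRS_BANDS = {"mild": (1, 3), "moderate": (4, 6), "severe": (7, 10)}


def nrs_band(score: float) -> str:
    """Severity band of an NRS pain score (none/mild/moderate/severe)."""
    if score < 1:
        return "none"
    for name, (lo, hi) in NRS_BANDS.items():
        if lo <= score <= hi:
            return name
    return "severe"


def summarize_clinical(table: pd.DataFrame) -> dict:
    """Median of each numeric column; NRS medians get their severity band.

    Even-count medians are the mean of the two middle values.  Non-numeric
    cells in a numeric column are reported with their row and column.
    """
    if len(table) < 1:
        raise ValueError("clinical table is empty")
    out: dict = {"n_subjects": int(len(table)), "medians": {}, "nrs_bands": {}}
    for col in table.columns:
        if col == "subject":
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().all():
            continue  # wholly non-numeric column (labels), not summarised
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
        med = float(vals.median())
        out["medians"][col] = med
        if col.startswith("nrs"):
            if not vals.between(0, 10).all():
                raise ValueError(f"NRS column {col!r} outside [0, 10]")
            out["nrs_bands"][col] = nrs_band(med)
    return out


# ---------------------------------------------------------------------------
# Study configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything a study run needs; hashable to a provenance id."""

    mode: str = "synthetic"                     # "synthetic" or "nifti"
    synth: SynthConfig = field(default_factory=SynthConfig)
    scan_paths: dict | None = None              # nifti mode: subject -> 4 paths
    atlas_path: str | None = None
    seed_names: tuple[str, ...] = ("left_thalamus", "right_thalamus")
    network_name: str = "salience"
    # preprocessing
    highpass_hz: float = 0.007
    fwhm_mm: float = 5.0
    nuisance: bool = True
    wm_label: str = "wm"
    csf_label: str = "csf"
    # SCA / group stats
    n_perm: int = 5000
    alpha: float = 0.05
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    use_fisher_z: bool = True
    # netid
    ica_k: int = 8
    template_path: str | None = None            # nifti mode network template
    # wca
    wca_params: wca.WcaParams = field(default_factory=wca.WcaParams)
    # misc
    clinical: pd.DataFrame = field(default_factory=lambda: DEFAULT_CLINICAL_WORKFLOW.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "nifti"):
            raise ValueError("mode must be 'synthetic' or 'nifti'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SeedResult:
    """Per-seed SCA + WCA outputs."""

    seed_name: str
    group_stats: dict                 # phase -> GroupStat
    rcfc_table: sca.RcfcTable
    rcfc_comparison: dict
    wtc_result: wca.WtcResult
    phase_summary: wca.PhaseSummary


@dataclass
class StudyResult:
    config_hash: str
    seed_results: dict                # seed name -> SeedResult
    network: dict                     # index, map, correlation, margin
    clinical_summary: dict
    affine: np.ndarray
    provenance: dict


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_inputs(config: StudyConfig):
    """Per-subject scan lists + atlas (+ ground truth in synthetic mode)."""
    if config.mode == "synthetic":
        sessions = [gen_session(config.synth, i)
                    for i in range(config.synth.n_subjects)]
        atlas = sessions[0][1]
        scans = [s[0] for s in sessions]
        truth = sessions[0][2]
        return scans, atlas, truth
    from .prep import load_bold
    import nibabel as nib
    if not config.scan_paths or config.atlas_path is None:
        raise ValueError("nifti mode needs scan_paths and atlas_path")
    scans = []
    for subject, paths in config.scan_paths.items():
        if len(paths) != 4:
            raise ValueError(f"subject {subject}: need exactly 4 phase scans")
        scans.append([load_bold(p, phase_name=ph)
                      for p, ph in zip(paths, PHASES)])
    img = nib.load(config.atlas_path)
    labels = np.asanyarray(img.dataobj).astype(np.int64)
    names = {int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0}
    names.update({1: "left_thalamus", 2: "right_thalamus", 3: "wm", 4: "csf"})
    atlas = LabelAtlas(labels=labels, affine=np.asarray(img.affine), names=names)
    return scans, atlas, None


def preprocess_scan(scan: BoldScan, atlas: LabelAtlas,
                    config: StudyConfig) -> BoldScan:
    """High-pass, optional spatial smoothing, WM/CSF nuisance regression."""
    out = highpass(scan, config.highpass_hz)
    if config.fwhm_mm > 0:
        out = spatial_smooth(out, config.fwhm_mm)
    if config.nuisance:
        masks = [atlas.mask(config.wm_label), atlas.mask(config.csf_label)]
        out = regress_nuisance(out, masks)
    return out


def _synth_covariates(n_subjects: int, seed: int) -> pd.DataFrame:
    """Plausible age/gender/disease-duration covariates for synthetic runs."""
    rng = np.random.default_rng([seed, 4242])
    return pd.DataFrame({
        "age": np.round(rng.normal(33.4, 7.1, n_subjects), 1),
        "gender": rng.integers(0, 2, n_subjects).astype(float),
        "disease_duration": np.round(rng.normal(20.2, 7.2, n_subjects), 1),
    })


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full pipeline; fully reproducible given the config."""
    raw, atlas, truth = _load_inputs(config)
    n_subjects = len(raw)
    phase_names = [s.phase_name for s in raw[0]]
    if len(phase_names) != 4:
        raise ValueError("each subject must contribute exactly 4 phase scans")

    pre = [[preprocess_scan(s, atlas, config) for s in subject]
           for subject in raw]

    covariates = _synth_covariates(n_subjects, config.seed)

    # ----- static branch: SCA maps, group stats, rcFC --------------------
    seed_results_sca: dict = {}
    for seed_name in config.seed_names:
        mask = atlas.mask(seed_name)
        maps_by_phase: dict[str, list[sca.ScaMap]] = {p: [] for p in phase_names}
        for si, subject in enumerate(pre):
            for scan in subject:
                tc = extract_mean_timecourse(scan, mask, name=seed_name)
                m = sca.seed_correlation_map(scan, tc, seed_name=seed_name,
                                             subject_id=f"sub{si}")
                maps_by_phase[scan.phase_name].append(m)
        group_stats = {}
        subject_meanfc = pd.DataFrame(index=range(n_subjects),
                                      columns=phase_names, dtype=float)
        for phase, maps in maps_by_phase.items():
            stat_maps = ([sca.fisher_z(m) for m in maps]
                         if config.use_fisher_z else maps)
            gs = sca.group_mean_effect(stat_maps, covariates=covariates,
                                       n_perm=config.n_perm, seed=config.seed,
                                       tfce_E=config.tfce_E, tfce_H=config.tfce_H)
            group_stats[phase] = gs
            sig = gs.significant_mask(config.alpha)
            if not sig.any():
                # fall back to the positive-t support so meanFC stays defined
                sig = gs.tstat > 0
            for si, m in enumerate(maps):
                subject_meanfc.loc[si, phase] = sca.mean_fc_over_mask(m, sig)
        group_meanfc = {p: float(subject_meanfc[p].mean()) for p in phase_names}
        base = group_meanfc[phase_names[0]]
        rc = {p: sca.rcfc(group_meanfc[p], base) for p in phase_names}
        table = sca.RcfcTable(seed_name=seed_name, phases=phase_names,
                              mean_fc=group_meanfc, rcfc_values=rc,
                              subject_mean_fc=subject_meanfc)
        seed_results_sca[seed_name] = (group_stats, table,
                                       sca.compare_rcfc(subject_meanfc))

    # ----- dynamic branch: ICA, network time courses, WCA ----------------
    data = netid.temporal_concat_group(pre)
    decomp = netid.group_spatial_ica(data, k=config.ica_k, seed=config.seed,
                                     grid_shape=atlas.labels.shape)
    if config.mode == "synthetic":
        template = netid.NetworkTemplate(truth.network_map, config.network_name)
    else:
        import nibabel as nib
        if config.template_path is None:
            raise ValueError("nifti mode needs a network template")
        template = netid.NetworkTemplate(
            np.asanyarray(nib.load(config.template_path).dataobj),
            config.network_name)
    selection = netid.select_network(decomp, template)

    net_tc_per_subject = []
    for subject in pre:
        parts = [netid.network_timecourse(selection["map"], scan)
                 for scan in subject]
        net_tc_per_subject.append(concatenate_timecourses(parts))
    net_group = netid.average_across_subjects(net_tc_per_subject)
    bounds = net_group.segment_bounds

    seed_results: dict = {}
    for seed_name in config.seed_names:
        mask = atlas.mask(seed_name)
        seed_tcs = []
        for subject in pre:
            parts = [extract_mean_timecourse(scan, mask, name=seed_name)
                     for scan in subject]
            seed_tcs.append(concatenate_timecourses(parts))
        seed_group = netid.average_across_subjects(seed_tcs)
        wtc_res = wca.wtc(seed_group, net_group, config.wca_params,
                          significance=True)
        wtc_res.segment_bounds = bounds
        wtc_res.segment_names = phase_names
        summary = wca.segment_phase_summary(wtc_res, bounds, phase_names)
        gs, table, comparison = seed_results_sca[seed_name]
        seed_results[seed_name] = SeedResult(
            seed_name=seed_name, group_stats=gs, rcfc_table=table,
            rcfc_comparison=comparison, wtc_result=wtc_res,
            phase_summary=summary)

    import thalfc
    return StudyResult(
        config_hash=config.config_hash(),
        seed_results=seed_results,
        network={k: v for k, v in selection.items() if k != "map"}
        | {"map": selection["map"], "ica_k": decomp.k,
           "variance_explained": decomp.variance_explained},
        clinical_summary=summarize_clinical(config.clinical),
        affine=(atlas.affine if hasattr(atlas, "affine") else np.eye(4)),
        provenance={"config_hash": config.config_hash(),
                    "seed": config.seed,
                    "version": getattr(thalfc, "__version__", "0"),
                    "n_subjects": n_subjects})


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: StudyResult, outdir, force: bool = False) -> dict:
    """Serialise a study result: NIfTI volumes, TSV tables, NPZ arrays.

    Returns (and writes) a JSON manifest listing every file with its SHA-256
    checksum and the config hash.  Refuses to overwrite an existing
    manifest unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True")
    files: list[str] = []
    aff = result.affine

    shape = None
    for seed_name, sr in result.seed_results.items():
        for phase, gs in sr.group_stats.items():
            base = f"{seed_name}_{phase}"
            for nm, vol in (("tstat", gs.tstat), ("tfce", gs.tfce),
                            ("fwe_p", gs.fwe_p)):
                p = outdir / f"{base}_{nm}.nii.gz"
                save_volume(vol, aff, p)
                files.append(p.name)
            shape = gs.tstat.shape
        sr.rcfc_table.to_frame().to_csv(outdir / f"{seed_name}_rcfc.tsv",
                                        sep="\t", index=False)
        files.append(f"{seed_name}_rcfc.tsv")
        sr.rcfc_comparison["pairwise"].to_csv(
            outdir / f"{seed_name}_rcfc_pairwise.tsv", sep="\t", index=False)
        files.append(f"{seed_name}_rcfc_pairwise.tsv")
        w = sr.wtc_result
        np.savez(outdir / f"{seed_name}_wtc.npz",
                 coherence=w.coherence, phase=w.phase, scales=w.scales,
                 fourier_periods=w.fourier_periods, times_s=w.times_s,
                 coi=w.coi, sig_mask=w.sig_mask, thresholds=w.thresholds)
        files.append(f"{seed_name}_wtc.npz")
        pd.DataFrame(sr.phase_summary.to_records()).to_csv(
            outdir / f"{seed_name}_phase_summary.tsv", sep="\t", index=False)
        files.append(f"{seed_name}_phase_summary.tsv")

    if shape is not None:
        save_volume(np.asarray(result.network["map"], dtype=float
                               ).reshape(shape), aff,
                    outdir / "network_map.nii.gz")
        files.append("network_map.nii.gz")

    med = result.clinical_summary
    pd.DataFrame([med["medians"]]).to_csv(outdir / "clinical_medians.tsv",
                                          sep="\t", index=False)
    files.append("clinical_medians.tsv")

    manifest = {
        "config_hash": result.config_hash,
        "provenance": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in result.provenance.items()},
        "files": [{"name": f, "sha256": _sha256(outdir / f)} for f in files],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
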
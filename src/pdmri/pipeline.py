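"""End-to-end orchestration: manifest -> feature table -> classification.

`run_extract` turns a cohort manifest into the per-subject feature table
(6 metric channels x one value per atlas region), applying the subject
inclusion rules on the way; `run_classify` runs the leave-one-out SVM
evaluation on that table for the all-modal combination and the standard
sub-combinations. Both are re-entrant from files so long runs can resume.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminate import (
    EvaluationSummary,
    FeatureBundle,
    FoldResult,
    SvmGrid,
    bundles_to_frame,
    frame_to_bundles,
    loocv,
    selection_frequency,
)
from .fmri_metrics import (
    BandSpec,
    alff_map,
    bandpass_volume,
    connectivity_matrix,
    metric_to_roi_features,
    nuisance_regress,
    reho_map,
    rfcs,
    roi_time_series,
)
from .structural_metrics import TissueMap, gaussian_smooth, tissue_roi_features
from .volumes_io import (
    AtlasParcellation,
    CohortManifest,
    discard_initial_volumes,
    load_motion_trace,
    load_volume3d,
    load_volume4d,
    make_brain_mask,
    motion_exclusion,
)

__all__ = ["PipelineConfig", "extract_subject", "run_extract", "run_classify",
           "STANDARD_COMBINATIONS", "provenance"]

#: metric combinations evaluated by run_classify, in reporting order
STANDARD_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("ReHo", "ALFF", "RFCS", "GM", "WM", "CSF"),
    ("ReHo", "ALFF", "RFCS"),
    ("ALFF", "RFCS"),
    ("GM", "WM", "CSF"),
)


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with the reference protocol defaults."""

    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    discard_k: int = 10
    max_trans_mm: float = 2.0
    max_rot_deg: float = 1.0
    neighborhood: int = 26
    fwhm_mm: float = 10.0
    alpha: float = 0.05
    c_exponents: tuple[int, ...] = tuple(range(-10, 11))
    g_exponents: tuple[int, ...] = tuple(range(-10, 11))
    coef0: float = 0.0
    normalize_maps: bool = True
    rfcs_variant: str = "signed"
    selector: str = "t"
    grid_mode: str = "nested"
    filter_method: str = "fft"
    mask_fraction: float = 0.2
    tr_override: float | None = None
    rotation_unit: str = "deg"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError("invalid band")
        if self.discard_k < 0:
            raise ValueError("discard_k must be >= 0")
        if self.neighborhood not in (6, 18, 26):
            raise ValueError("neighborhood must be 6, 18 or 26")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.grid_mode not in ("nested", "global"):
            raise ValueError("grid_mode must be 'nested' or 'global'")

    @property
    def band(self) -> BandSpec:
        return BandSpec(low=self.band_low_hz, high=self.band_high_hz)

    @property
    def svm_grid(self) -> SvmGrid:
        return SvmGrid(c_exponents=tuple(self.c_exponents),
                       g_exponents=tuple(self.g_exponents), coef0=self.coef0)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_subject(record: pd.Series | dict, atlas: AtlasParcellation,
                    config: PipelineConfig) -> FeatureBundle | None:
    """Extract the six feature vectors for one subject.

    Returns None when the subject fails the motion-exclusion rule.
    """
    vol = load_volume4d(record["path_bold"], tr=config.tr_override)
    n_original = vol.n_timepoints
    vol = discard_initial_volumes(vol, config.discard_k)

    motion = load_motion_trace(record["path_motion"],
                               rotation_unit=config.rotation_unit)
    if motion.n_frames == n_original:
        motion_retained = motion.params[config.discard_k:]
    elif motion.n_frames == vol.n_timepoints:
        motion_retained = motion.params
    else:
        raise ValueError(
            f"{record['subject_id']}: motion rows ({motion.n_frames}) match "
            f"neither the written ({n_original}) nor the retained "
            f"({vol.n_timepoints}) frame count")
    decision = motion_exclusion(motion, config.max_trans_mm,
                                config.max_rot_deg)
    if not decision.keep:
        return None

    mask = make_brain_mask(vol, fraction=config.mask_fraction)
    filtered = bandpass_volume(vol, config.band, method=config.filter_method)

    features: dict[str, np.ndarray] = {}
    alff = alff_map(filtered, mask, config.band,
                    normalize=config.normalize_maps)
    features["ALFF"] = metric_to_roi_features(alff, atlas, mask=mask).values
    reho = reho_map(filtered, mask, neighborhood=config.neighborhood,
                    normalize=config.normalize_maps)
    features["ReHo"] = metric_to_roi_features(reho, atlas, mask=mask).values

    series, _ = roi_time_series(filtered, atlas, mask=mask)
    global_signal = filtered.data[mask.mask].mean(axis=0)
    confounds = np.column_stack([motion_retained, global_signal])
    residuals = nuisance_regress(series, confounds)
    corr = connectivity_matrix(residuals, region_ids=atlas.region_ids)
    features["RFCS"] = rfcs(corr, variant=config.rfcs_variant).values

    for tissue, key in (("GM", "path_gm"), ("WM", "path_wm"),
                        ("CSF", "path_csf")):
        data, voxel_size = load_volume3d(record[key])
        tmap = TissueMap(tissue_tag=tissue, values=data,
                         voxel_size=voxel_size)
        smoothed = gaussian_smooth(tmap, fwhm_mm=config.fwhm_mm)
        features[tissue] = tissue_roi_features(smoothed, atlas).values

    return FeatureBundle(subject_id=str(record["subject_id"]),
                         group=str(record["group"]), features=features)


def run_extract(manifest: CohortManifest, atlas: AtlasParcellation,
                config: PipelineConfig,
                out_path: str | Path | None = None
                ) -> tuple[pd.DataFrame, list[str], list[tuple[str, str]]]:
    """Extract features for every manifest subject.

    Returns (feature table, motion-excluded subject ids, per-subject
    failures as (id, message)). Missing or broken files are recorded and the
    run continues; if every subject fails, an error is raised.
    """
    bundles: list[FeatureBundle] = []
    excluded: list[str] = []
    failures: list[tuple[str, str]] = []
    for _, record in manifest.records.iterrows():
        sid = str(record["subject_id"])
        try:
            bundle = extract_subject(record, atlas, config)
        except Exception as exc:  # record and continue with other subjects
            failures.append((sid, str(exc)))
            continue
        if bundle is None:
            excluded.append(sid)
        else:
            bundles.append(bundle)
    if not bundles:
        raise RuntimeError("feature extraction failed for every subject")
    frame = bundles_to_frame(bundles, region_labels=atlas.abbreviations)
    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame, excluded, failures


def run_classify(frame: pd.DataFrame, config: PipelineConfig,
                 combinations: tuple[tuple[str, ...], ...] = STANDARD_COMBINATIONS,
                 out_dir: str | Path | None = None,
                 ) -> dict[str, tuple[EvaluationSummary, list[FoldResult]]]:
    """Leave-one-out evaluation for each metric combination.

    The first (all-modal) combination additionally produces the per-fold
    selection-count table, the selection-frequency report and the ROC points
    when ``out_dir`` is given.
    """
    bundles = frame_to_bundles(frame)
    if len({b.group for b in bundles}) < 2:
        raise ValueError("feature table must contain both groups")
    results: dict[str, tuple[EvaluationSummary, list[FoldResult]]] = {}
    for combo in combinations:
        name = "+".join(combo)
        summary, folds = loocv(bundles, alpha=config.alpha,
                               grid=config.svm_grid, metrics=combo,
                               selector=config.selector,
                               mode=config.grid_mode)
        results[name] = (summary, folds)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        main_name = "+".join(combinations[0])
        summary, folds = results[main_name]
        region_labels = _region_labels_from_frame(frame)
        summary.fold_counts.to_csv(out / "folds.csv", index=False)
        freq = selection_frequency(folds, bundles,
                                   region_names=region_labels,
                                   selector=config.selector)
        freq.to_csv(out / "selection_frequency.csv", index=False)
        scores = np.array([f.index_score for f in folds])
        is_case = np.array([f.truth == "case" for f in folds])
        from .discriminate import roc_auc  # local import avoids cycle noise
        fpr, tpr, thr, _ = roc_auc(scores, is_case)
        pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}).to_csv(
            out / "roc.csv", index=False)
        payload = {
            "provenance": provenance(config),
            "combinations": {
                name: {
                    "accuracy_percent": round(s.accuracy, 2),
                    "sensitivity_percent": round(s.sensitivity, 2),
                    "specificity_percent": round(s.specificity, 2),
                    "auc": round(s.auc, 4),
                    "n_folds": s.n_folds,
                    "mode": s.mode,
                }
                for name, (s, _) in results.items()
            },
            "index_scores": {name: dict(sorted(s.scores.items()))
                             for name, (s, _) in results.items()},
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))
    return results


def _region_labels_from_frame(frame: pd.DataFrame) -> dict[str, list[str]]:
    labels: dict[str, list[str]] = {}
    for col in frame.columns:
        if ":" in col:
            metric, region = col.split(":", 1)
            labels.setdefault(metric, []).append(region)
    return labels


def provenance(config: PipelineConfig) -> dict:
    """Machine-readable provenance block for reproducibility."""
    import scipy
    import sklearn

    return {
        "pdmri_version": __version__,
        "config_digest": config.digest(),
        "config": asdict(config),
        "seed": config.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }
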
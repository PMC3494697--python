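"""Desk-scale synthetic cohorts for end-to-end pipeline testing.

Generates complete cohorts — 4-D BOLD-like volumes, modulated-tissue-style
maps, motion-parameter files, a block atlas and a manifest — with
controllable group effects per metric channel, so every pipeline stage and
the full classifier are testable without clinical data.

Signal model. Every voxel in region r of subject s carries

    x_v(t) = a_sr * ( w1 * reg_r(t) + w2 * net_{r mod K}(t) + w3 * priv_v(t) )
             + a_sr/a0 * sigma_n * eps_v(t) + baseline

where reg_r, the K = N_NETWORKS network signals net_k and priv_v are
independent unit-RMS band-limited noise signals (flat spectrum with random
phases strictly inside 0.01-0.1 Hz) and w1^2 + w2^2 + w3^2 = 1.
Regions join the K networks round-robin, so each network contributes only
~1/K of the global mean and global-signal regression cannot remove the
inter-regional coupling wholesale. The three functional dials are then
orthogonal by construction:

- a_sr (amplitude) drives ALFF only: the mixture is unit-RMS, and the white
  noise is scaled with a, so synchrony and coupling are amplitude-invariant;
- w1 (within-region synchrony) drives ReHo: reg_r is shared by the region's
  voxels, raising neighbourhood concordance;
- w2 (coupling to the region's network signal) drives RFCS: it raises the
  region's correlation with the other regions of its network. When w2 is
  implanted, w1 is adjusted to keep w1^2 + w2^2 constant so the within-region
  synchrony (ReHo) is unaffected.

The atlas parcels are surrounded by a background shell (label 0) of in-mask
voxels sharing one physiological component. Real brain masks contain much
tissue outside any atlas region; without it the global signal equals the
region-weighted mean of the ROI series exactly, and regressing it out forces
each region's residual covariances with all others to sum to ~0 — making the
signed mean-correlation (RFCS) structurally insensitive to any implant.

A residual leak remains from ReHo implants into RFCS (changing w1 changes
the region-mean variance that normalises the inter-regional correlations);
it is documented rather than compensated.

Group effects are stated in pooled-SD units of the corresponding
between-subject parameter (amplitude, synchrony, coupling or tissue level),
whose between-subject SDs are module defaults; because the regional features
are locally linear in those parameters, an implanted effect of d transfers
to approximately d pooled SDs in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import (
    AtlasParcellation,
    CohortManifest,
    MotionTrace,
    Volume4D,
    default_label_table,
    save_atlas,
    save_manifest,
    save_motion_trace,
    save_volume3d,
    save_volume4d,
)

__all__ = ["CohortSpec", "default_effects", "make_atlas", "simulate_subject",
           "simulate_cohort", "SubjectData"]

# generator baseline parameters (see module docstring)
BASELINE = 100.0        # additive offset so brain-mask support is well defined
AMP0 = 1.0              # baseline band-limited signal RMS
AMP_SD = 0.08           # between-subject SD of the regional amplitude
SYNC0 = 0.5             # baseline within-region synchrony weight w1
SYNC_SD = 0.05
COUPLING0 = 0.3         # baseline network-coupling weight w2
COUPLING_SD = 0.08
TISSUE_MEAN = 0.5       # baseline tissue-map level
TISSUE_SD = 0.05        # between-subject SD of the regional tissue level
TISSUE_SPATIAL_SD = 0.1  # SD of the smooth spatial noise on tissue maps
N_NETWORKS = 4          # independent network signals (round-robin regions)
BG_SHARE = 0.5          # weight of the shared physiological component in
                        # background-shell voxels (rest is voxel-private)
FREQ_RANGE = (0.015, 0.095)  # Hz, strictly inside the 0.01-0.1 Hz band
MOTION_STEP_SD = 0.01   # random-walk step of the motion trace
VIOLATION_TRANSLATION_MM = 3.0

FUNCTIONAL_CHANNELS = ("ALFF", "ReHo", "RFCS")
TISSUE_CHANNELS = ("GM", "WM", "CSF")


def default_effects() -> dict[str, tuple[tuple[str, float], ...]]:
    """Six implanted effects, one region per metric channel, +/-3 pooled SD.

    Signs follow the direction of the corresponding group differences
    reported for early Parkinson's disease: regional homogeneity and ALFF
    reduced in patients, connectivity strength and regional volumes raised.
    """
    return {
        "ReHo": (("ORBmid_R", -3.0),),
        "ALFF": (("ROL_L", -3.0),),
        "RFCS": (("MTG_R", 3.0),),
        "GM": (("PCG_R", 3.0),),
        "WM": (("PreCG_R", 3.0),),
        "CSF": (("THA_L", 3.0),),
    }


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``n_timepoints`` is the analysis length after the lead-in; the generator
    writes ``n_initial`` extra initial frames so the written series matches a
    390 s acquisition at tr = 2 s (195 frames) and the discard step is
    exercised. ``effects`` maps a metric channel to (region, effect-size)
    pairs in pooled-SD units, applied to the case group; regions are atlas
    abbreviations or label ids. ``background_margin`` is the thickness of
    the background (label 0) shell around the atlas parcels; those voxels
    are inside the brain mask and carry a shared physiological component,
    as the extra-atlas tissue of a real brain does, so the global signal
    is not an exact region-weighted mean of the ROI series.
    ``motion_violators`` lists subject indices (cohort-wide, cases first)
    whose motion files deliberately break the 2 mm exclusion rule.
    """

    n_cases: int = 19
    n_controls: int = 27
    grid: tuple[int, int, int] = (20, 20, 20)
    n_regions: int = 116
    background_margin: int = 1
    n_timepoints: int = 185
    n_initial: int = 10
    tr: float = 2.0
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    effects: dict[str, tuple[tuple[str | int, float], ...]] = field(
        default_factory=default_effects)
    noise_sd: float = 1.0
    seed: int = 0
    motion_violators: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        unknown = set(self.effects) - set(FUNCTIONAL_CHANNELS + TISSUE_CHANNELS)
        if unknown:
            raise ValueError(f"unknown effect channels: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_frames_written(self) -> int:
        return self.n_timepoints + self.n_initial


@dataclass
class SubjectData:
    """One simulated subject, in memory."""

    subject_id: str
    group: str
    bold: Volume4D
    tissues: dict[str, np.ndarray]
    motion: MotionTrace


# ---------------------------------------------------------------------------
# Atlas


def _balanced_factorization(n: int, grid: tuple[int, int, int]
                            ) -> tuple[int, int, int] | None:
    """Most cube-like (nx, ny, nz) with nx*ny*nz == n fitting the grid."""
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        for ny in range(1, n // nx + 1):
            if (n // nx) % ny:
                continue
            nz = n // (nx * ny)
            if nx > grid[0] or ny > grid[1] or nz > grid[2]:
                continue
            spread = max(nx, ny, nz) - min(nx, ny, nz)
            if best is None or spread < best[0]:
                best = (spread, (nx, ny, nz))
    return None if best is None else best[1]


def _bisect_boxes(origin: tuple[int, int, int], size: tuple[int, int, int],
                  n: int) -> list[tuple[tuple[int, int, int],
                                        tuple[int, int, int]]]:
    """Recursively split a box into n rectangular sub-boxes of similar size.

    Each step splits the longest axis at a position proportional to the
    region counts on either side, so parcels stay compact (near-cubic) and
    every parcel is a contiguous rectangular block.
    """
    if n == 1:
        return [(origin, size)]
    axis = int(np.argmax(size))
    n1 = n // 2
    cut = max(1, min(size[axis] - 1, round(size[axis] * n1 / n)))
    if size[axis] < 2:
        raise ValueError("grid too small to bisect further")
    size_a = list(size)
    size_a[axis] = cut
    origin_b = list(origin)
    origin_b[axis] += cut
    size_b = list(size)
    size_b[axis] -= cut
    return (_bisect_boxes(origin, tuple(size_a), n1)
            + _bisect_boxes(tuple(origin_b), tuple(size_b), n - n1))


def make_atlas(grid: tuple[int, int, int], n_regions: int,
               table: pd.DataFrame | None = None,
               margin: int = 0) -> AtlasParcellation:
    """Partition a grid into ``n_regions`` nonempty rectangular parcels.

    When a balanced block factorization fits the grid (e.g. 8 regions on a
    12^3 grid -> octants), a regular block lattice is used. Otherwise the
    grid is split by recursive proportional bisection into near-cubic
    rectangular blocks — keeping every parcel compact so voxel
    neighbourhoods stay mostly within one region, as they do for anatomical
    atlases. ``margin`` leaves a background (label 0) shell that many voxels
    thick around the parcels, emulating the brain tissue a real mask covers
    but an anatomical atlas does not. With ``n_regions=116`` the shipped
    116-entry label table is attached.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    full_grid = grid
    grid = tuple(g - 2 * margin for g in grid)
    if any(g < 1 for g in grid):
        raise ValueError("margin leaves no interior voxels")
    nvox = int(np.prod(grid))
    if n_regions > nvox:
        raise ValueError(f"{n_regions} regions do not fit {nvox} voxels")
    factors = _balanced_factorization(n_regions, grid)
    labels = np.zeros(grid, dtype=np.int32)
    if factors is not None:
        edges = [np.linspace(0, g, f + 1).astype(int)
                 for g, f in zip(grid, factors)]
        label = 1
        for ix in range(factors[0]):
            for iy in range(factors[1]):
                for iz in range(factors[2]):
                    labels[edges[0][ix]:edges[0][ix + 1],
                           edges[1][iy]:edges[1][iy + 1],
                           edges[2][iz]:edges[2][iz + 1]] = label
                    label += 1
    else:
        boxes = _bisect_boxes((0, 0, 0), grid, n_regions)
        for label, (o, s) in enumerate(boxes, 1):
            labels[o[0]:o[0] + s[0], o[1]:o[1] + s[1], o[2]:o[2] + s[2]] = label
    if (np.bincount(labels.ravel(), minlength=n_regions + 1)[1:] == 0).any():
        raise ValueError("grid too small: an atlas region came out empty")
    if margin:
        labels = np.pad(labels, margin, mode="constant", constant_values=0)
        assert labels.shape == full_grid
    if table is None:
        if n_regions == 116:
            table = default_label_table()
        else:
            table = pd.DataFrame({
                "label_id": np.arange(1, n_regions + 1),
                "name": [f"synthetic region {i}" for i in range(1, n_regions + 1)],
                "abbreviation": [f"R{i}" for i in range(1, n_regions + 1)],
            })
    return AtlasParcellation(labels=labels, table=table)


# ---------------------------------------------------------------------------
# Signals


def _band_signal(rng: np.random.Generator, n_frames: int, tr: float,
                 size: tuple[int, ...] = ()) -> np.ndarray:
    """Exactly unit-RMS, zero-mean band-limited noise (flat in-band spectrum).

    Synthesised in the frequency domain: every rFFT bin inside FREQ_RANGE
    gets unit amplitude and an independent random phase, so the spectrum is
    continuous across the band like real BOLD fluctuations. This maximises
    the temporal degrees of freedom of each series for a given record
    length, which keeps the sampling noise of inter-regional sample
    correlations small relative to the implanted coupling effects.

    Each series is standardised to its realised mean/SD so the mixing
    weights fully determine the variance shares; otherwise finite-sample
    fluctuations of the component variances dominate the between-subject
    spread of the derived metrics and drown the implanted effects.
    """
    freqs = np.fft.rfftfreq(n_frames, tr)
    in_band = (freqs >= FREQ_RANGE[0]) & (freqs <= FREQ_RANGE[1])
    n_bins = int(in_band.sum())
    phases = rng.uniform(0, 2 * np.pi, size=size + (n_bins,))
    spectrum = np.zeros(size + (len(freqs),), dtype=complex)
    spectrum[..., in_band] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_frames, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def _resolve_effects(spec: CohortSpec, atlas: AtlasParcellation
                     ) -> dict[str, dict[int, float]]:
    """Map effect specs to {channel: {positional region index: size}}."""
    abbrev_to_pos = {a: i for i, a in enumerate(atlas.abbreviations)}
    id_to_pos = {int(lid): i for i, lid in enumerate(atlas.region_ids)}
    resolved: dict[str, dict[int, float]] = {}
    for channel, entries in spec.effects.items():
        chan: dict[int, float] = {}
        for region, size in entries:
            if isinstance(region, str):
                if region not in abbrev_to_pos:
                    raise ValueError(f"unknown region {region!r}")
                chan[abbrev_to_pos[region]] = float(size)
            else:
                if int(region) not in id_to_pos:
                    raise ValueError(f"unknown region id {region}")
                chan[id_to_pos[int(region)]] = float(size)
        resolved[channel] = chan
    return resolved


def simulate_subject(spec: CohortSpec, group: str, atlas: AtlasParcellation,
                     rng: np.random.Generator, subject_id: str = "subject",
                     motion_violator: bool = False) -> SubjectData:
    """Simulate one subject's BOLD series, tissue maps and motion file."""
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    effects = _resolve_effects(spec, atlas)
    is_case = group == "case"
    n_frames = spec.n_frames_written
    n_regions = atlas.n_regions
    grid = spec.grid
    if atlas.labels.shape != grid:
        raise ValueError("atlas grid does not match the spec grid")

    # subject-level signal components; regions join one of N_NETWORKS
    # network signals round-robin, so the global mean carries only a
    # fraction of each network and global-signal regression cannot cancel
    # the inter-regional coupling wholesale (as it would a single shared
    # signal)
    reg_signals = _band_signal(rng, n_frames, spec.tr, size=(n_regions,))
    net_signals = _band_signal(rng, n_frames, spec.tr, size=(N_NETWORKS,))
    bg_signal = _band_signal(rng, n_frames, spec.tr)

    # per-region parameters with between-subject variability and implants
    z_amp = rng.normal(size=n_regions)
    z_sync = rng.normal(size=n_regions)
    z_coup = rng.normal(size=n_regions)
    amp = AMP0 * (1.0 + AMP_SD * z_amp)
    sync = SYNC0 + SYNC_SD * z_sync
    coup = np.clip(COUPLING0 + COUPLING_SD * z_coup, 0.02, 0.9)
    # extra coupling spread evenly over all networks: the RFCS implant adds
    # a component the target shares with every region (what the mean
    # inter-regional correlation measures), not just its own network
    xcoup = np.zeros(n_regions)
    if is_case:
        for pos, d in effects.get("ALFF", {}).items():
            amp[pos] += AMP0 * AMP_SD * d
        for pos, d in effects.get("ReHo", {}).items():
            sync[pos] += SYNC_SD * d
        for pos, d in effects.get("RFCS", {}).items():
            xcoup[pos] = COUPLING_SD * d
    amp = np.clip(amp, 0.05, None)
    # per-region coupling weights onto the N_NETWORKS network signals:
    # one-hot own-network baseline plus the implanted all-network component
    W = np.zeros((n_regions, N_NETWORKS))
    W[np.arange(n_regions), np.arange(n_regions) % N_NETWORKS] = coup
    W += (xcoup / np.sqrt(N_NETWORKS))[:, None]
    coup_power = (W**2).sum(axis=1)
    # keep within-region synchrony (w1^2 + sum of w2^2) unchanged by RFCS
    # implants so the implant does not leak into ReHo
    sync = np.sqrt(np.clip(sync**2 + coup**2 - coup_power, 0.0025, 0.9))
    total_shared = np.clip(sync**2 + coup_power, None, 0.95)
    w3 = np.sqrt(1.0 - total_shared)

    bold = np.empty(grid + (n_frames,))
    flat_labels = atlas.labels.reshape(-1)
    bold2d = bold.reshape(-1, n_frames)
    for pos, region_id in enumerate(atlas.region_ids):
        vox = np.flatnonzero(flat_labels == region_id)
        priv = _band_signal(rng, n_frames, spec.tr, size=(len(vox),))
        mix = (sync[pos] * reg_signals[pos]
               + W[pos] @ net_signals
               + w3[pos] * priv)
        noise = rng.normal(size=(len(vox), n_frames))
        # noise scales with amplitude so synchrony/coupling stay
        # amplitude-invariant (ALFF isolation)
        bold2d[vox] = (amp[pos] * mix
                       + (amp[pos] / AMP0) * spec.noise_sd * noise
                       + BASELINE)
    background = np.flatnonzero(flat_labels == 0)
    if background.size:
        # background-shell voxels: in-mask tissue outside the atlas, sharing
        # one physiological component. Because the global signal averages
        # these voxels too, it is not an exact region-weighted mean of the
        # ROI series — without this, global-signal regression forces the
        # residual inter-regional covariances of each region to sum to ~0
        # and the signed connectivity strength becomes degenerate.
        priv = _band_signal(rng, n_frames, spec.tr, size=(background.size,))
        mix = (BG_SHARE * bg_signal
               + np.sqrt(1.0 - BG_SHARE**2) * priv)
        noise = rng.normal(size=(background.size, n_frames))
        bold2d[background] = AMP0 * mix + spec.noise_sd * noise + BASELINE

    tissues: dict[str, np.ndarray] = {}
    for tissue in TISSUE_CHANNELS:
        level = TISSUE_MEAN + TISSUE_SD * rng.normal(size=n_regions)
        if is_case:
            for pos, d in effects.get(tissue, {}).items():
                level[pos] += TISSUE_SD * d
        tmap = np.zeros(np.prod(grid))
        for pos, region_id in enumerate(atlas.region_ids):
            tmap[flat_labels == region_id] = level[pos]
        spatial = ndimage.gaussian_filter(
            rng.normal(size=grid), sigma=1.5) * TISSUE_SPATIAL_SD
        tissues[tissue] = np.clip(tmap.reshape(grid) + spatial, 0.0, None)

    steps = rng.normal(scale=MOTION_STEP_SD, size=(n_frames, 6))
    params = np.cumsum(steps, axis=0)
    params = np.clip(params, -0.5, 0.5)
    if motion_violator:
        params[n_frames // 2, 0] = VIOLATION_TRANSLATION_MM
    motion = MotionTrace(params=params)

    vol = Volume4D(data=bold, voxel_size=spec.voxel_size, tr=spec.tr)
    return SubjectData(subject_id=subject_id, group=group, bold=vol,
                       tissues=tissues, motion=motion)


def simulate_cohort(spec: CohortSpec, out_dir: str | Path,
                    atlas: AtlasParcellation | None = None
                    ) -> tuple[CohortManifest, AtlasParcellation]:
    """Write a full cohort (volumes, tissue maps, motion files, atlas,
    manifest) under ``out_dir``; returns the manifest and the atlas.

    One global seed fans out to per-subject substreams, so cohorts are
    reproducible subject by subject.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if atlas is None:
        atlas = make_atlas(spec.grid, spec.n_regions,
                           margin=spec.background_margin)
    save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv",
               voxel_size=spec.voxel_size)

    groups = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    records = []
    case_i = ctrl_i = 0
    for i, (group, ss) in enumerate(zip(groups, streams)):
        if group == "case":
            case_i += 1
            sid = f"case_{case_i:02d}"
        else:
            ctrl_i += 1
            sid = f"control_{ctrl_i:02d}"
        subj = simulate_subject(spec, group, atlas,
                                np.random.default_rng(ss), subject_id=sid,
                                motion_violator=i in spec.motion_violators)
        paths = {
            "path_bold": out / f"{sid}_bold.nii.gz",
            "path_gm": out / f"{sid}_gm.nii.gz",
            "path_wm": out / f"{sid}_wm.nii.gz",
            "path_csf": out / f"{sid}_csf.nii.gz",
            "path_motion": out / f"{sid}_motion.txt",
        }
        save_volume4d(subj.bold, paths["path_bold"])
        for tissue, key in (("GM", "path_gm"), ("WM", "path_wm"),
                            ("CSF", "path_csf")):
            save_volume3d(subj.tissues[tissue], paths[key],
                          voxel_size=spec.voxel_size)
        save_motion_trace(subj.motion, paths["path_motion"])
        records.append({"subject_id": sid, "group": group,
                        **{k: str(v) for k, v in paths.items()}})
    manifest = CohortManifest(records=pd.DataFrame(records))
    save_manifest(manifest, out / "manifest.csv")
    return manifest, atlas
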
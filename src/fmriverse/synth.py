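"""Synthetic event-related fMRI cohorts with known ground truth.

Emulates a three-run stop-signal experiment: each subject has event-related
BOLD responses in a handful of active regions (go, stop_success, stop_fail
trial types), superimposed on a baseline with AR(1)-correlated temporal
noise, slow cosine drift, transient spikes, and a motion-coupled intensity
artifact concentrated at the brain edge.  Per-slice acquisition delays are
embedded in the signal so slice-timing correction is non-trivial.

The default geometry is desk-scale (20x20x12 voxels, 3 mm isotropic,
3 runs x 80 volumes at TR 2 s, 13 subjects) so that factorial pipeline runs
fit on a single CPU; the full acquisition geometry of the emulated study
(176 volumes/run) is reachable through :class:`SyntheticSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "TRIAL_TYPES",
    "ActiveRegion",
    "SyntheticSpec",
    "SubjectDataset",
    "Cohort",
    "generate_events",
    "generate_subject",
    "generate_cohort",
    "scope_masks",
    "brain_mask",
    "write_cohort",
    "desk_spec",
]

TRIAL_TYPES = ("go", "stop_success", "stop_fail")

#: extra tail (s) left free at the end of each run so late responses evolve
_RUN_TAIL = 12.0
#: temporal resolution (s) of the fine grid used for HRF convolution
_FINE_DT = 0.02


@dataclass(frozen=True)
class ActiveRegion:
    """A spherical activation focus with per-condition response amplitudes.

    ``responses`` maps trial types to peak percent-signal-change amplitudes;
    within the sphere the amplitude falls off with a cosine-squared taper so
    region edges are smooth.
    """

    name: str
    center: tuple[int, int, int]  # voxel indices
    radius_mm: float
    responses: Mapping[str, float]


def _default_regions() -> tuple[ActiveRegion, ...]:
    # Right-lateralised inhibition-related foci (positive for the
    # stop_success - go contrast) plus a go-driven motor focus on the left.
    return (
        ActiveRegion("r_inferior_frontal", (14, 13, 7), 7.5,
                     {"stop_success": 3.0, "stop_fail": 1.5}),
        ActiveRegion("r_temporal", (14, 6, 5), 7.5,
                     {"stop_success": 3.0, "stop_fail": 1.0, "go": 0.5}),
        ActiveRegion("l_motor", (5, 10, 8), 6.0,
                     {"go": 2.0, "stop_fail": 2.0}),
    )


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Amplitudes are percent signal change relative to ``baseline``; noise_sd,
    drift_amplitude and spike sizes are in raw signal units (baseline = 100).
    """

    n_subjects: int = 13
    n_runs: int = 3
    n_volumes_per_run: int = 80
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_slices: int = 12
    trial_counts: dict[str, int] = field(
        default_factory=lambda: {"go": 24, "stop_success": 8, "stop_fail": 8}
    )
    trial_duration: float = 1.0
    min_iti: float = 2.0
    active_regions: tuple[ActiveRegion, ...] = field(default_factory=_default_regions)
    baseline: float = 100.0
    noise_sd: float = 2.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 2.0
    spike_rate: float = 0.02
    spike_magnitude: float = 6.0
    motion_coupling: float = 1.0
    subject_amplitude_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def run_duration(self) -> float:
        return self.n_volumes_per_run * self.tr

    @property
    def affine(self) -> np.ndarray:
        """RAS+ voxel-to-world affine with the grid centred at the origin."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.voxel_size)
        return aff

    def validate(self) -> None:
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid axes must have at least 4 voxels")
        if self.n_slices != self.grid_shape[2]:
            raise ValueError("n_slices must equal the z extent of grid_shape")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        bad = set(self.trial_counts) - set(TRIAL_TYPES)
        if bad:
            raise ValueError(f"unknown trial types: {sorted(bad)}")
        for reg in self.active_regions:
            vals = list(reg.responses.values())
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"region {reg.name!r} has non-finite amplitude")
            if any(v < 0 for v in vals):
                raise ValueError(f"region {reg.name!r} has negative amplitude")


@dataclass
class SubjectDataset:
    """One subject's runs plus everything the analyses need to model them."""

    runs: list[np.ndarray]  # each (x, y, z, t)
    tr: float
    events: pd.DataFrame  # onset, duration, trial_type, run
    motion: np.ndarray  # (total volumes, 6): 3 translations mm, 3 rotations rad
    affine: np.ndarray
    mask: np.ndarray  # boolean brain mask
    truth: dict[str, np.ndarray]  # trial_type -> %-signal amplitude volume
    subject: int = 0

    def __post_init__(self) -> None:
        total = sum(r.shape[-1] for r in self.runs)
        if self.motion.shape != (total, 6):
            raise ValueError("motion rows must equal total volume count")
        if self.mask.shape != self.runs[0].shape[:3]:
            raise ValueError("mask shape must match volume spatial shape")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return sum(r.shape[-1] for r in self.runs)


@dataclass
class Cohort:
    """A list of subjects with shared geometry, group truth and scope masks."""

    subjects: list[SubjectDataset]
    spec: SyntheticSpec
    mask: np.ndarray
    affine: np.ndarray
    group_truth: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]  # left_hemi, right_hemi, and named ROIs

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def truth_positive(self, contrast: str = "stop_success_vs_go") -> np.ndarray:
        """Boolean volume of voxels with a positive ground-truth contrast."""
        a, b = contrast.split("_vs_")
        diff = self.group_truth[a] - self.group_truth[b]
        return (diff > 1e-9) & self.mask


# ---------------------------------------------------------------------------
# randomness plumbing: every draw is keyed by (seed, subject, run, purpose)
# so cohorts are bit-identical for a given spec.

def _rng(spec: SyntheticSpec, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    )


def generate_events(
    spec: SyntheticSpec, run: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Randomised, jittered event table for one run.

    Trials of all types are shuffled into a single order; onsets place each
    trial at least ``trial_duration + min_iti`` after the previous one, with
    the remaining run time distributed as random jitter.
    """
    if rng is None:
        rng = _rng(spec, 0, run, 1)
    counts = {t: int(spec.trial_counts.get(t, 0)) for t in TRIAL_TYPES}
    n = sum(counts.values())
    cols = {"onset": np.array([], float), "duration": np.array([], float),
            "trial_type": np.array([], object), "run": np.array([], int)}
    if n == 0:
        return pd.DataFrame(cols)
    spacing = spec.trial_duration + spec.min_iti
    required = n * spacing + _RUN_TAIL
    if required > spec.run_duration:
        raise ValueError(
            f"cannot pack {n} trials into a {spec.run_duration:.0f} s run; "
            f"at least {required:.0f} s required"
        )
    labels = np.concatenate([[t] * c for t, c in counts.items() if c > 0])
    labels = labels[rng.permutation(n)]
    slack = spec.run_duration - required
    gaps = rng.dirichlet(np.ones(n)) * slack
    onsets = np.arange(n) * spacing + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n, spec.trial_duration),
            "trial_type": labels,
            "run": np.full(n, run, dtype=int),
        }
    )


def _spm_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s), unit peak."""
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, 6.0, scale=1.0) - gamma_dist.pdf(t, 16.0, scale=1.0) / 6.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _region_amplitude_map(spec: SyntheticSpec, region: ActiveRegion) -> np.ndarray:
    """Cosine-tapered spherical profile, 1.0 at the centre, 0 beyond radius."""
    idx = np.indices(spec.grid_shape).astype(float)
    d2 = np.zeros(spec.grid_shape)
    for ax in range(3):
        d2 += ((idx[ax] - region.center[ax]) * spec.voxel_size[ax]) ** 2
    d = np.sqrt(d2)
    prof = np.where(d < region.radius_mm, np.cos(np.pi * d / (2 * region.radius_mm)) ** 2, 0.0)
    return prof


def brain_mask(spec: SyntheticSpec) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid."""
    idx = np.indices(spec.grid_shape).astype(float)
    c = (np.asarray(spec.grid_shape) - 1) / 2.0
    semi = np.asarray(spec.grid_shape) * np.array([0.45, 0.45, 0.42])
    rho2 = sum(((idx[ax] - c[ax]) / semi[ax]) ** 2 for ax in range(3))
    return rho2 <= 1.0


def _condition_signal(
    spec: SyntheticSpec, events: pd.DataFrame, trial_type: str
) -> np.ndarray:
    """HRF-convolved response per slice, shape (n_slices, n_volumes).

    Slice k of volume i is sampled at ``i*TR + k*TR/n_slices`` (ascending
    acquisition), which is what embeds the slice-timing confound.
    """
    n_t = spec.n_volumes_per_run
    t_fine = np.arange(0, spec.run_duration + 32.0, _FINE_DT)
    stick = np.zeros_like(t_fine)
    sel = events[events["trial_type"] == trial_type]
    for onset, dur in zip(sel["onset"], sel["duration"]):
        i0 = int(round(onset / _FINE_DT))
        i1 = max(i0 + 1, int(round((onset + dur) / _FINE_DT)))
        stick[i0:i1] += 1.0
    hrf = _spm_hrf(np.arange(0, 32.0, _FINE_DT))
    conv = signal.fftconvolve(stick, hrf)[: t_fine.size] * _FINE_DT
    out = np.empty((spec.n_slices, n_t))
    base_t = np.arange(n_t) * spec.tr
    for k in range(spec.n_slices):
        t_k = base_t + k * spec.tr / spec.n_slices
        out[k] = np.interp(t_k, t_fine, conv)
    return out


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, rho: float) -> np.ndarray:
    """AR(1) noise along the last axis with marginal standard deviation sd."""
    innov = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    if rho == 0.0:
        return innov
    out = signal.lfilter([1.0], [1.0, -rho], innov, axis=-1)
    return out


def _motion_params(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Slow random-walk head motion, restarted at each run (post-realignment)."""
    n = spec.n_volumes_per_run
    blocks = []
    for _ in range(spec.n_runs):
        steps = rng.standard_normal((n, 6)) * np.array([0.03] * 3 + [4e-4] * 3)
        walk = np.cumsum(steps, axis=0)
        walk -= walk[0]
        blocks.append(walk)
    return np.vstack(blocks)


def generate_subject(spec: SyntheticSpec, subject: int = 0) -> SubjectDataset:
    """Generate one subject: signal + AR(1) noise + drift + spikes + motion.

    With all noise terms at zero the voxel series at a region centre equals
    ``baseline * (1 + amplitude/100 * HRF-convolved stimulus)`` exactly.
    """
    spec.validate()
    mask = brain_mask(spec)
    n_vox = int(mask.sum())
    amp_rng = _rng(spec, subject, 0, 2)
    mult = 1.0 + spec.subject_amplitude_sd * amp_rng.standard_normal()
    mult = max(mult, 0.05)

    # ground-truth amplitude volumes (%, subject-specific)
    truth = {t: np.zeros(spec.grid_shape) for t in TRIAL_TYPES}
    for reg in spec.active_regions:
        prof = _region_amplitude_map(spec, reg)
        for t, amp in reg.responses.items():
            truth[t] += amp * mult * prof
    for t in truth:
        truth[t] *= mask

    motion = _motion_params(spec, _rng(spec, subject, 0, 3))
    # standardized motion for artifact coupling
    m_std = motion - motion.mean(axis=0)
    sds = m_std.std(axis=0)
    sds[sds == 0] = 1.0
    m_std = m_std / sds
    edge = mask & ~ndimage.binary_erosion(mask)
    edge_idx = np.flatnonzero(edge.ravel())
    w_rng = _rng(spec, subject, 0, 4)
    edge_w = w_rng.standard_normal((edge_idx.size, 6)) / np.sqrt(6.0)

    runs: list[np.ndarray] = []
    events_frames: list[pd.DataFrame] = []
    n_t = spec.n_volumes_per_run
    flat_mask = np.flatnonzero(mask.ravel())
    for run in range(spec.n_runs):
        ev = generate_events(spec, run, _rng(spec, subject, run, 1))
        events_frames.append(ev)
        vol = np.zeros(spec.grid_shape + (n_t,))
        # task signal, slice-time embedded
        sig_by_cond = {t: _condition_signal(spec, ev, t) for t in TRIAL_TYPES}
        for t in TRIAL_TYPES:
            amp = truth[t]  # (x, y, z), percent
            if not np.any(amp):
                continue
            # broadcast: per-slice time course scaled by the amplitude map
            for k in range(spec.n_slices):
                sl = amp[:, :, k]
                if not np.any(sl):
                    continue
                vol[:, :, k, :] += (
                    sl[:, :, None] / 100.0 * spec.baseline * sig_by_cond[t][k][None, None, :]
                )
        vol[mask] += spec.baseline

        noise_rng = _rng(spec, subject, run, 5)
        if spec.noise_sd > 0:
            vol[mask] += _ar1_noise(noise_rng, (n_vox, n_t), spec.noise_sd, spec.ar1_rho)
        if spec.drift_amplitude > 0:
            tgrid = np.arange(n_t) * spec.tr
            dur = spec.run_duration
            basis = np.stack(
                [np.cos(2 * np.pi * tgrid / (2 * dur)), np.cos(2 * np.pi * tgrid / dur)]
            )  # periods 2T and T, both >= 160 s at the default geometry
            coef = noise_rng.standard_normal((n_vox, 2)) * spec.drift_amplitude
            vol[mask] += coef @ basis
        if spec.spike_rate > 0 and spec.spike_magnitude > 0:
            spike_rng = _rng(spec, subject, run, 6)
            hits = np.flatnonzero(spike_rng.random(n_t) < spec.spike_rate)
            for ti in hits:
                sgn = 1.0 if spike_rng.random() < 0.5 else -1.0
                pattern = 0.5 + 0.5 * spike_rng.random(n_vox)
                flat = vol.reshape(-1, n_t)
                flat[flat_mask, ti] += sgn * spec.spike_magnitude * spec.noise_sd * pattern
        if spec.motion_coupling > 0 and edge_idx.size:
            m_run = m_std[run * n_t : (run + 1) * n_t]  # (n_t, 6)
            art = spec.motion_coupling * spec.noise_sd * (edge_w @ m_run.T)
            flat = vol.reshape(-1, n_t)
            flat[edge_idx] += art
        runs.append(vol)

    events = pd.concat(events_frames, ignore_index=True)
    return SubjectDataset(
        runs=runs,
        tr=spec.tr,
        events=events,
        motion=motion,
        affine=spec.affine,
        mask=mask,
        truth=truth,
        subject=subject,
    )


def _ellipsoid_mask(
    spec: SyntheticSpec, center_vox: Sequence[int], radii_mm: Sequence[float]
) -> np.ndarray:
    idx = np.indices(spec.grid_shape).astype(float)
    rho2 = np.zeros(spec.grid_shape)
    for ax in range(3):
        rho2 += (((idx[ax] - center_vox[ax]) * spec.voxel_size[ax]) / radii_mm[ax]) ** 2
    return rho2 <= 1.0


def scope_masks(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Hemisphere and ROI scope masks implied by the spec's geometry.

    Hemispheres split the brain at world x = 0 (the x = 0 plane, if any
    voxel centre falls on it, belongs to neither).  The two labelled ROI
    masks are disjoint ellipsoids in the right hemisphere around the
    frontal-like and temporal-like active regions.
    """
    mask = brain_mask(spec)
    idx = np.indices(spec.grid_shape).astype(float)
    xw = spec.affine[0, 0] * idx[0] + spec.affine[0, 3]
    masks = {
        "left_hemi": mask & (xw < 0),
        "right_hemi": mask & (xw > 0),
    }
    regions = {r.name: r for r in spec.active_regions}
    roi_sources = []
    if "r_inferior_frontal" in regions:
        roi_sources.append(("frontal_roi", regions["r_inferior_frontal"]))
    if "r_temporal" in regions:
        roi_sources.append(("temporal_roi", regions["r_temporal"]))
    for name, reg in roi_sources:
        roi = _ellipsoid_mask(spec, reg.center, [reg.radius_mm + 2.0] * 3) & mask
        masks[name] = roi & (xw > 0)
    return masks


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate all subjects plus group truth, hemisphere and ROI masks.

    Between-subject variability is a normal multiplicative amplitude factor
    N(1, subject_amplitude_sd).
    """
    if spec.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (random-effects analysis undefined)")
    subjects = [generate_subject(spec, s) for s in range(spec.n_subjects)]
    mask = brain_mask(spec)
    group_truth = {t: np.zeros(spec.grid_shape) for t in TRIAL_TYPES}
    for reg in spec.active_regions:
        prof = _region_amplitude_map(spec, reg)
        for t, amp in reg.responses.items():
            group_truth[t] += amp * prof
    for t in group_truth:
        group_truth[t] *= mask
    masks = scope_masks(spec)
    return Cohort(
        subjects=subjects,
        spec=spec,
        mask=mask,
        affine=spec.affine,
        group_truth=group_truth,
        masks=masks,
    )


# ---------------------------------------------------------------------------
# disk layout: BIDS-flavoured NIfTI + TSV + .par + JSON ground-truth sidecar

def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as NIfTI runs, events.tsv, motion .par and truth JSON."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    nib.save(
        nib.Nifti1Image(cohort.mask.astype(np.uint8), cohort.affine),
        outdir / "mask.nii.gz",
    )
    for name, m in cohort.masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), cohort.affine), outdir / f"{name}.nii.gz")
    for t, vol in cohort.group_truth.items():
        nib.save(nib.Nifti1Image(vol, cohort.affine), outdir / f"truth_{t}.nii.gz")
    for subj in cohort.subjects:
        sdir = outdir / f"sub-{subj.subject + 1:02d}"
        sdir.mkdir(exist_ok=True)
        for r, run in enumerate(subj.runs):
            img = nib.Nifti1Image(run.astype(np.float32), subj.affine)
            img.header.set_zooms(tuple(spec.voxel_size) + (spec.tr,))
            nib.save(img, sdir / f"sub-{subj.subject + 1:02d}_run-{r + 1}_bold.nii.gz")
            ev = subj.events[subj.events["run"] == r]
            ev[["onset", "duration", "trial_type"]].to_csv(
                sdir / f"sub-{subj.subject + 1:02d}_run-{r + 1}_events.tsv",
                sep="\t", index=False,
            )
            n_t = run.shape[-1]
            np.savetxt(
                sdir / f"sub-{subj.subject + 1:02d}_run-{r + 1}_motion.par",
                subj.motion[r * n_t : (r + 1) * n_t],
                fmt="%.8f",
            )
    sidecar = {
        "seed": spec.seed,
        "tr": spec.tr,
        "n_subjects": spec.n_subjects,
        "n_runs": spec.n_runs,
        "n_volumes_per_run": spec.n_volumes_per_run,
        "grid_shape": list(spec.grid_shape),
        "voxel_size": list(spec.voxel_size),
        "active_regions": [
            {
                "name": r.name,
                "center": list(r.center),
                "radius_mm": r.radius_mm,
                "responses": dict(r.responses),
            }
            for r in spec.active_regions
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return outdir


def desk_spec(**overrides) -> SyntheticSpec:
    """The default desk-scale spec, with keyword overrides."""
    return replace(SyntheticSpec(), **overrides)
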
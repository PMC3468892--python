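"""Factorial pipeline enumeration and execution with stage memoization.

The factor grid crosses four pre-processing factors (despiking,
slice-timing, normalization strategy, smoothing FWHM) with six
model-estimation factors (normalization/model order, high-pass,
autocorrelation, run concatenation, basis set, motion regression):
2*2*3*3 * 2*2*2*2*3*4 = 6,912 pipelines, and five thresholding regimes on
top of every pipeline's group Z map give 34,560 thresholded-map slots.

Pipelines are independent, deterministic work units: a pipeline's output
depends only on the cohort and its option assignment, never on scheduling
or on the cache, and Monte-Carlo cluster thresholds are seeded from the run
seed plus the regime, not from any worker state.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import model as mdl
from . import preprocess as pre
from . import thresholding as thr
from .synth import Cohort

__all__ = [
    "FactorGrid",
    "PipelineSpec",
    "MultiverseResult",
    "default_grid",
    "enumerate_pipelines",
    "run_pipeline",
    "run_multiverse",
]


@dataclass(frozen=True)
class FactorGrid:
    """Ordered analysis factors, each with an ordered option list."""

    factors: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for name, opts in self.factors:
            if len(opts) < 1:
                raise ValueError(f"factor {name!r} has no options")
            if len(set(opts)) != len(opts):
                raise ValueError(f"factor {name!r} has duplicate options")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def options(self, factor: str) -> tuple[str, ...]:
        for name, opts in self.factors:
            if name == factor:
                return opts
        raise KeyError(factor)

    @property
    def n_pipelines(self) -> int:
        n = 1
        for _, opts in self.factors:
            n *= len(opts)
        return n


def default_grid() -> FactorGrid:
    return FactorGrid(
        (
            ("despike", ("on", "off")),
            ("slice_timing", ("on", "off")),
            ("normalization", ("epi_template", "t1_template", "segmentation")),
            ("smoothing_fwhm", ("4", "8", "12")),
            ("order", ("normalize_first", "model_first")),
            ("highpass", ("cutoff_128s", "off")),
            ("autocorr", ("ar1", "off")),
            ("concat", ("on", "off")),
            ("basis", ("hrf", "fir_34_vs_baseline", "fir_interaction")),
            ("motion", ("m6", "m12", "m24", "none")),
        )
    )


@dataclass(frozen=True)
class PipelineSpec:
    """One option per factor; ``id`` is the canonical serialized form."""

    options: tuple[tuple[str, str], ...]

    @property
    def id(self) -> str:
        return "|".join(f"{k}={v}" for k, v in self.options)

    def __getitem__(self, factor: str) -> str:
        for k, v in self.options:
            if k == factor:
                return v
        raise KeyError(factor)

    def as_dict(self) -> dict[str, str]:
        return dict(self.options)

    @classmethod
    def from_id(cls, pipeline_id: str) -> "PipelineSpec":
        pairs = []
        for part in pipeline_id.split("|"):
            k, _, v = part.partition("=")
            if not k or not v:
                raise ValueError(f"malformed pipeline id segment {part!r}")
            pairs.append((k, v))
        return cls(tuple(pairs))


def enumerate_pipelines(
    grid: FactorGrid,
    constraints: Mapping[str, str | Sequence[str]] | None = None,
) -> list[PipelineSpec]:
    """Cartesian product of the grid in factor order, optionally constrained.

    ``constraints`` maps factor names to a forced option or an allowed
    subset; unknown factors or options raise.
    """
    allowed: dict[str, set[str]] = {}
    if constraints:
        for fac, val in constraints.items():
            opts = grid.options(fac) if fac in grid.names else None
            if opts is None:
                raise ValueError(f"unknown factor {fac!r} in constraints")
            vals = (val,) if isinstance(val, str) else tuple(val)
            for v in vals:
                if v not in opts:
                    raise ValueError(f"unknown option {v!r} for factor {fac!r}")
            allowed[fac] = set(vals)
    names = grid.names
    out = []
    for combo in itertools.product(*(opts for _, opts in grid.factors)):
        if all(combo[names.index(f)] in a for f, a in allowed.items()):
            out.append(PipelineSpec(tuple(zip(names, combo))))
    return out


class PipelineError(RuntimeError):
    """A stage failure inside one pipeline; carries a machine-readable record."""

    def __init__(self, pipeline_id: str, stage: str, message: str):
        super().__init__(f"[{pipeline_id}] {stage}: {message}")
        self.record = {"pipeline_id": pipeline_id, "stage": stage, "error": message}


@dataclass
class MultiverseResult:
    """Indexed stacks of Z maps and thresholded maps plus provenance."""

    grid: FactorGrid
    pipelines: list[PipelineSpec]
    methods: list[thr.ThresholdSpec]
    zmaps: np.ndarray  # (P, x, y, z), NaN outside mask
    thresholded: np.ndarray  # (P, M, x, y, z) boolean
    mask: np.ndarray
    affine: np.ndarray
    smoothness: np.ndarray  # (P, 3) per-axis FWHM mm
    threshold_details: list[list[thr.ThresholdSpec]]  # per pipeline, per method
    failures: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_pipelines(self) -> int:
        return len(self.pipelines)

    @property
    def n_thresholded(self) -> int:
        return len(self.pipelines) * len(self.methods)

    def pipeline_index(self, pipeline_id: str) -> int:
        for i, p in enumerate(self.pipelines):
            if p.id == pipeline_id:
                return i
        raise KeyError(pipeline_id)


# ---------------------------------------------------------------------------
# pipeline execution


def _template_mask(template: pre.Template) -> np.ndarray:
    return template.images["epi_template"] > 0


def _preprocessed_runs(
    cohort: Cohort,
    subj_index: int,
    spec: PipelineSpec,
    template: pre.Template,
    cache: dict | None,
) -> list[np.ndarray]:
    """Despike/slice-time/(normalize)/smooth one subject per the spec.

    Stage outputs are memoized on the upstream option prefix so pipelines
    sharing a prefix reuse one computation.
    """
    subj = cohort.subjects[subj_index]
    tr = cohort.spec.tr
    vs = cohort.spec.voxel_size

    key1 = ("prep", subj_index, spec["despike"], spec["slice_timing"])
    if cache is not None and key1 in cache:
        runs = cache[key1]
    else:
        runs = subj.runs
        if spec["despike"] == "on":
            runs = [pre.despike(r, tr) for r in runs]
        if spec["slice_timing"] == "on":
            runs = [pre.slice_time_correct(r, tr) for r in runs]
        if cache is not None:
            cache[key1] = runs

    key2 = key1 + (spec["normalization"], spec["smoothing_fwhm"], spec["order"])
    if cache is not None and key2 in cache:
        return cache[key2]
    fwhm = float(spec["smoothing_fwhm"])
    if spec["order"] == "normalize_first":
        runs_n, _ = pre.normalize(runs, spec["normalization"], template, mask=subj.mask)
        out = [pre.smooth(r, fwhm, vs) for r in runs_n]
    else:
        out = [pre.smooth(r, fwhm, vs) for r in runs]
    if cache is not None:
        cache[key2] = out
    return out


def _subject_contrast_map(
    cohort: Cohort,
    subj_index: int,
    spec: PipelineSpec,
    template: pre.Template,
    cache: dict | None,
) -> np.ndarray:
    """One subject's contrast-estimate volume(s) on the template grid.

    Returns (x, y, z) for t-type bases and (8, x, y, z) for the FIR
    interaction basis.
    """
    subj = cohort.subjects[subj_index]
    spec_syn = cohort.spec
    opts = mdl.ModelOptions(
        order=spec["order"],
        highpass=spec["highpass"],
        autocorr=spec["autocorr"],
        concat=spec["concat"],
        basis=spec["basis"],
        motion=spec["motion"],
    )
    runs = _preprocessed_runs(cohort, subj_index, spec, template, cache)
    native = spec["order"] == "model_first"
    fit_mask = subj.mask if native else _template_mask(template)
    run_lengths = [r.shape[-1] for r in runs]
    design = mdl.build_design(subj.events, opts, subj.motion, spec_syn.tr, run_lengths)

    def _fit_one(dm: mdl.DesignMatrix, Y: np.ndarray) -> np.ndarray:
        fit = mdl.fit_glm(Y, dm, autocorr=opts.autocorr)
        return mdl.contrast_estimate(fit, dm, opts.basis)

    if opts.concat == "on":
        Y = np.concatenate([r[fit_mask].T for r in runs], axis=0)
        est = _fit_one(design, Y)
    else:
        ests = [
            _fit_one(dm, runs[r][fit_mask].T) for r, dm in enumerate(design)
        ]
        est = np.mean(ests, axis=0)  # unweighted average across runs

    def _embed(values: np.ndarray) -> np.ndarray:
        vol = np.zeros(fit_mask.shape)
        vol[fit_mask] = values
        return vol

    if native:
        # transform estimated from the functional data, applied to the
        # per-subject contrast volume(s)
        xform = pre.estimate_normalization(
            runs, spec["normalization"], template, mask=subj.mask
        )
        warp = lambda v: pre.apply_normalization(v, xform, template)
    else:
        warp = lambda v: v
    if est.ndim == 1:
        return warp(_embed(est))
    return np.stack([warp(_embed(e)) for e in est])


def run_pipeline(
    cohort: Cohort,
    spec: PipelineSpec,
    contrast: str = "stop_success_vs_go",
    template: pre.Template | None = None,
    cache: dict | None = None,
    return_subject_maps: bool = False,
):
    """Execute one pipeline end to end, producing the group Z map.

    Stages: despike? -> slice-time? -> (normalize -> smooth -> model) or
    (smooth -> model -> normalize contrast maps) -> random-effects group
    test -> Z conversion.  Deterministic given the cohort and spec.
    """
    if template is None:
        template = pre.make_template(cohort.spec.grid_shape, cohort.spec.voxel_size)
    mask = _template_mask(template)
    try:
        subj_maps = [
            _subject_contrast_map(cohort, s, spec, template, cache)
            for s in range(cohort.n_subjects)
        ]
        if spec["basis"] == "fir_interaction":
            D = np.stack([m[:, mask] for m in subj_maps])  # (n, 8, v)
            F, dfn, dfd = mdl.group_hotelling(D)
            z = mdl.stat_to_z(F, dfd, kind="F", dfn=dfn)
            df_source = dfd
            scalar_maps = np.stack([m.mean(axis=0) for m in subj_maps])
        else:
            stack = np.stack([m[mask] for m in subj_maps])
            t, df_source = mdl.group_ttest(stack)
            z = mdl.stat_to_z(t, df_source, kind="t")
            scalar_maps = np.stack(subj_maps)
    except PipelineError:
        raise
    except Exception as exc:  # surfaced as a machine-readable failure record
        raise PipelineError(spec.id, "execute", str(exc)) from exc
    zvol = np.full(mask.shape, np.nan)
    zvol[mask] = z
    zmap = mdl.ZMap(values=zvol, contrast_id=contrast, pipeline_id=spec.id, df_source=df_source)
    if return_subject_maps:
        return zmap, scalar_maps
    return zmap


def run_multiverse(
    cohort: Cohort,
    grid: FactorGrid | None = None,
    methods: Sequence[thr.ThresholdSpec] | None = None,
    constraints: Mapping[str, str | Sequence[str]] | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    cache: bool = True,
    connectivity: int = 26,
    contrast: str = "stop_success_vs_go",
) -> MultiverseResult:
    """Run every pipeline in the (constrained) grid and threshold every map.

    Monte-Carlo cluster sizes are simulated once per (regime, rounded
    smoothness) pair and reused; failed pipelines are recorded and excluded
    from the stacks (their slots hold NaN / False).
    """
    grid = grid or default_grid()
    methods = list(methods) if methods is not None else thr.default_threshold_specs()
    pipelines = enumerate_pipelines(grid, constraints)
    if not pipelines:
        raise ValueError("empty pipeline set")
    template = pre.make_template(cohort.spec.grid_shape, cohort.spec.voxel_size)
    mask = _template_mask(template)
    shape = cohort.spec.grid_shape
    vs = cohort.spec.voxel_size
    P, M = len(pipelines), len(methods)
    zmaps = np.full((P,) + shape, np.nan)
    thresholded = np.zeros((P, M) + shape, dtype=bool)
    smoothness = np.full((P, 3), np.nan)
    details: list[list[thr.ThresholdSpec]] = [list(methods) for _ in range(P)]
    failures: list[dict] = []
    stage_cache: dict | None = {} if cache else None
    k_cache: dict[tuple, int] = {}

    for i, pspec in enumerate(pipelines):
        try:
            zmap, subj_maps = run_pipeline(
                cohort, pspec, contrast=contrast, template=template,
                cache=stage_cache, return_subject_maps=True,
            )
            resid = subj_maps - subj_maps.mean(axis=0, keepdims=True)
            fwhm = thr.estimate_smoothness(resid, mask, vs)
        except PipelineError as err:
            failures.append(err.record)
            continue
        zmaps[i] = zmap.values
        smoothness[i] = fwhm
        row: list[thr.ThresholdSpec] = []
        for j, tspec in enumerate(methods):
            use = tspec
            if tspec.method in thr.MC_METHODS:
                fkey = (tspec.method, tuple(np.round(fwhm, 1)))
                if fkey not in k_cache:
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            [int(seed) & 0x7FFFFFFF, j, int(round(float(np.mean(fwhm)) * 10))]
                        )
                    )
                    k_cache[fkey] = thr.mc_cluster_threshold(
                        mask, fwhm, tspec.voxel_p_uncorrected,
                        alpha=tspec.alpha_clusterwise, n_sims=n_sims,
                        connectivity=connectivity, rng=rng, voxel_size=vs,
                    )
                use = thr.with_cluster_k(tspec, k_cache[fkey])
            tmap = thr.apply_threshold(
                zmap.values, use, mask, fwhm_mm=fwhm, voxel_size=vs,
                connectivity=connectivity, pipeline_id=pspec.id,
            )
            thresholded[i, j] = tmap.significant
            row.append(use)
        details[i] = row

    config_repr = json.dumps(
        {
            "grid": [[n, list(o)] for n, o in grid.factors],
            "methods": [m.method for m in methods],
            "constraints": {k: sorted(v) if not isinstance(v, str) else v
                            for k, v in (constraints or {}).items()},
            "n_sims": n_sims,
            "seed": seed,
        },
        sort_keys=True,
    )
    provenance = {
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest()[:16],
        "seed": seed,
        "n_sims": n_sims,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_pipelines": P,
        "n_failures": len(failures),
    }
    return MultiverseResult(
        grid=grid,
        pipelines=pipelines,
        methods=methods,
        zmaps=zmaps,
        thresholded=thresholded,
        mask=mask,
        affine=template.affine,
        smoothness=smoothness,
        threshold_details=details,
        failures=failures,
        provenance=provenance,
    )
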
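"""Configuration, result persistence, and the reporting surface.

Configs are YAML with a strict schema (unknown keys are rejected before any
compute); reports are a manifest TSV, a JSON summary whose numbers fully
reproduce the narrative, and a Markdown narrative.  Volumes are written as
NIfTI-1 (.nii.gz) in RAS+ world millimetres.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import yaml

from . import metrics as mx
from .multiverse import FactorGrid, MultiverseResult, PipelineSpec, default_grid
from .synth import SyntheticSpec, scope_masks
from .thresholding import ALL_METHODS, ThresholdSpec, default_threshold_specs

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "save_zmap",
    "save_result",
    "load_result",
    "summarize_result",
    "write_report",
]

_SYNTH_KEYS = {
    f.name for f in dataclasses.fields(SyntheticSpec) if f.name != "active_regions"
}
_TOP_KEYS = {
    "seed", "synthetic", "grid", "constraints", "thresholds", "n_sims",
    "output_dir", "cache", "connectivity",
}


@dataclass
class RunConfig:
    """A validated multiverse run configuration with defaults filled in."""

    seed: int = 0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    grid: FactorGrid = field(default_factory=default_grid)
    constraints: dict[str, list[str]] = field(default_factory=dict)
    thresholds: list[ThresholdSpec] = field(default_factory=default_threshold_specs)
    n_sims: int = 1000
    output_dir: str = "multiverse_out"
    cache: bool = True
    connectivity: int = 26


def _validate_grid(raw: Mapping[str, Any]) -> FactorGrid:
    base = default_grid()
    factors = []
    for name, opts in base.factors:
        if name in raw:
            chosen = [str(v) for v in raw[name]]
            for v in chosen:
                if v not in opts:
                    raise ValueError(f"unknown option {v!r} for factor {name!r}")
            factors.append((name, tuple(chosen)))
        else:
            factors.append((name, opts))
    unknown = set(raw) - set(base.names)
    if unknown:
        raise ValueError(f"unknown factor in grid: {sorted(unknown)[0]!r}")
    return FactorGrid(tuple(factors))


def read_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    syn = dict(raw.get("synthetic") or {})
    unknown = set(syn) - _SYNTH_KEYS
    if unknown:
        raise ValueError(f"unknown synthetic key: {sorted(unknown)[0]!r}")
    syn.setdefault("seed", cfg.seed)
    for tup_key in ("grid_shape", "voxel_size"):
        if tup_key in syn:
            syn[tup_key] = tuple(syn[tup_key])
    cfg.synthetic = SyntheticSpec(**syn)
    if "grid" in raw and raw["grid"]:
        cfg.grid = _validate_grid(raw["grid"])
    if "constraints" in raw and raw["constraints"]:
        cons: dict[str, list[str]] = {}
        for fac, val in raw["constraints"].items():
            if fac not in cfg.grid.names:
                raise ValueError(f"unknown factor in constraints: {fac!r}")
            vals = [val] if isinstance(val, str) else [str(v) for v in val]
            for v in vals:
                if v not in cfg.grid.options(fac):
                    raise ValueError(f"unknown option {v!r} for factor {fac!r}")
            cons[fac] = vals
        cfg.constraints = cons
    if "thresholds" in raw and raw["thresholds"]:
        specs = []
        by_name = {s.method: s for s in default_threshold_specs()}
        for name in raw["thresholds"]:
            if name not in ALL_METHODS:
                raise ValueError(f"unknown thresholding method: {name!r}")
            specs.append(by_name[name])
        cfg.thresholds = specs
    for key in ("n_sims", "connectivity"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    if "output_dir" in raw:
        cfg.output_dir = str(raw["output_dir"])
    if "cache" in raw:
        cfg.cache = bool(raw["cache"])
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through read_config)."""
    syn = dataclasses.asdict(cfg.synthetic)
    syn.pop("active_regions", None)
    syn["grid_shape"] = list(cfg.synthetic.grid_shape)
    syn["voxel_size"] = list(cfg.synthetic.voxel_size)
    doc = {
        "seed": cfg.seed,
        "synthetic": syn,
        "grid": {name: list(opts) for name, opts in cfg.grid.factors},
        "constraints": {k: list(v) for k, v in cfg.constraints.items()},
        "thresholds": [s.method for s in cfg.thresholds],
        "n_sims": cfg.n_sims,
        "output_dir": cfg.output_dir,
        "cache": cfg.cache,
        "connectivity": cfg.connectivity,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# volumes and results on disk


def _save_nifti(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, np.float32), affine)
    nib.save(img, path)


def save_zmap(zmap, affine: np.ndarray, path: str | Path) -> None:
    """Write a ZMap as NIfTI-1 with provenance in the header + JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(zmap.values, np.float32), affine)
    img.header["descrip"] = zmap.pipeline_id[:79].encode()
    nib.save(img, path)
    sidecar = {
        "pipeline_id": zmap.pipeline_id,
        "contrast_id": zmap.contrast_id,
        "df_source": int(zmap.df_source),
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def save_result(result: MultiverseResult, path: str | Path) -> None:
    """Persist a MultiverseResult as an .npz plus a JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path.with_suffix(".npz"),
        zmaps=result.zmaps.astype(np.float32),
        thresholded=result.thresholded,
        mask=result.mask,
        affine=result.affine,
        smoothness=result.smoothness,
    )
    header = {
        "grid": [[n, list(o)] for n, o in result.grid.factors],
        "pipelines": [p.id for p in result.pipelines],
        "methods": [dataclasses.asdict(m) for m in result.methods],
        "threshold_details": [
            [dataclasses.asdict(s) for s in row] for row in result.threshold_details
        ],
        "failures": result.failures,
        "provenance": result.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))


def load_result(path: str | Path) -> MultiverseResult:
    path = Path(path)
    arrs = np.load(path.with_suffix(".npz"))
    header = json.loads(path.with_suffix(".json").read_text())
    grid = FactorGrid(tuple((n, tuple(o)) for n, o in header["grid"]))
    return MultiverseResult(
        grid=grid,
        pipelines=[PipelineSpec.from_id(pid) for pid in header["pipelines"]],
        methods=[ThresholdSpec(**m) for m in header["methods"]],
        zmaps=arrs["zmaps"].astype(float),
        thresholded=arrs["thresholded"],
        mask=arrs["mask"],
        affine=arrs["affine"],
        smoothness=arrs["smoothness"],
        threshold_details=[
            [ThresholdSpec(**s) for s in row] for row in header["threshold_details"]
        ],
        failures=header["failures"],
        provenance=header["provenance"],
    )


# ---------------------------------------------------------------------------
# metrics orchestration + report


def summarize_result(
    result: MultiverseResult,
    scopes: Mapping[str, np.ndarray] | None = None,
    synthetic_spec: SyntheticSpec | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Compute the full metric suite for one result.

    Returns ``(maps, summary)``: NaN-masked volumes (mean activation,
    analytic range, per-factor step ranges, significance proportion,
    discordance) and a JSON-ready summary (extent distributions, peak
    dispersion, correlations, counts).
    """
    if scopes is None:
        scopes = scope_masks(synthetic_spec) if synthetic_spec is not None else {}
    mask = result.mask
    maps: dict[str, np.ndarray] = {}
    summary: dict[str, Any] = {
        "n_pipelines": result.n_pipelines,
        "n_thresholded_maps": result.n_thresholded,
        "n_failures": len(result.failures),
        "provenance": result.provenance,
    }
    ok = ~np.all(np.isnan(result.zmaps.reshape(result.n_pipelines, -1)), axis=1)
    z_ok = result.zmaps[ok]
    if z_ok.shape[0] >= 2:
        rmaps = mx.analytic_range(z_ok, mask)
        maps["mean_activation"] = rmaps.mean_activation
        maps["analytic_range"] = rmaps.analytic_range
        summary["median_analytic_range"] = float(
            np.nanmedian(rmaps.analytic_range[mask])
        )
        try:
            summary["mean_vs_range_r"] = mx.map_correlations(
                rmaps.mean_activation, rmaps.analytic_range, mask
            )
        except ValueError:
            summary["mean_vs_range_r"] = None
        if np.all(ok):
            # effective grid: only the options actually realized (the run may
            # have been constrained to a sub-grid)
            realized = FactorGrid(
                tuple(
                    (fac, tuple(o for o in opts if any(p[fac] == o for p in result.pipelines)))
                    for fac, opts in result.grid.factors
                )
            )
            step_maps: dict[str, np.ndarray] = {}
            for fac, opts in realized.factors:
                if len(opts) < 2:
                    continue
                sr = mx.step_range(result.zmaps, realized, result.pipelines, fac, mask)
                step_maps[fac] = sr
                maps[f"step_range_{fac}"] = sr
            if len(step_maps) >= 2:
                summary["step_pairwise"] = mx.step_pairwise_correlation(step_maps, mask)
    if result.thresholded[ok].size:
        prop = mx.significance_proportion(result.thresholded[ok], mask)
        maps["significance_proportion"] = prop
        maps["discordance"] = mx.discordance(prop)
        summary["peak_significance_proportion"] = float(np.nanmax(prop))
        summary["max_discordance"] = float(np.nanmax(maps["discordance"]))
    summary["extent"] = mx.extent_summary(result)
    usable_scopes = {n: m for n, m in scopes.items() if np.any(m & mask)}
    if usable_scopes and z_ok.shape[0] >= 1:
        ok_pipes = [p for p, keep in zip(result.pipelines, ok) if keep]
        _, peak_summary = mx.peak_table(z_ok, ok_pipes, usable_scopes, result.affine)
        summary["peaks"] = peak_summary
    return maps, summary


def write_report(
    result: MultiverseResult,
    maps: Mapping[str, np.ndarray],
    summary: Mapping[str, Any],
    outdir: str | Path,
) -> Path:
    """Write manifest TSV, JSON summary and Markdown narrative.

    Every file written (including metric volumes) is listed in the
    manifest; the Markdown contains no number that is not also in the JSON.
    Re-running on the same result reproduces the report files byte for
    byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[tuple[str, str]] = []
    for name in sorted(maps):
        fname = f"{name}.nii.gz"
        _save_nifti(np.nan_to_num(maps[name], nan=0.0), result.affine, outdir / fname)
        files.append((name, fname))
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )
    files.append(("summary", "summary.json"))

    lines = [
        "# Multiverse report",
        "",
        f"Pipelines executed: {result.n_pipelines} "
        f"({len(result.failures)} failed); "
        f"thresholded-map slots: {result.n_thresholded}.",
        "",
    ]
    if result.failures:
        lines.append("## Failed pipelines")
        lines.extend(f"- `{f['pipeline_id']}`: {f['stage']}: {f['error']}" for f in result.failures)
        lines.append("")
    ext = summary.get("extent", {}).get("per_method", {})
    if ext:
        lines.append("## Significant-extent distribution (fraction of in-mask voxels)")
        lines.append("")
        lines.append("| method | median | min | max | n maps |")
        lines.append("|---|---|---|---|---|")
        for m, row in ext.items():
            lines.append(
                f"| {m} | {row['median']:.4f} | {row['min']:.4f} | "
                f"{row['max']:.4f} | {row['n_maps']} |"
            )
        lines.append("")
    if "median_analytic_range" in summary:
        lines.append(
            f"Median analytic range over in-mask voxels: "
            f"{summary['median_analytic_range']:.3f} Z units."
        )
    if summary.get("mean_vs_range_r") is not None:
        lines.append(
            f"Correlation of mean activation with analytic range across voxels: "
            f"r = {summary['mean_vs_range_r']:.3f}."
        )
    peaks = summary.get("peaks", {})
    if peaks:
        lines.append("")
        lines.append("## Peak-location dispersion")
        for scope, row in peaks.items():
            if "sd_mm" not in row:
                continue
            sd = row["sd_mm"]
            lines.append(
                f"- {scope}: {row['n_unique_locations']} unique locations over "
                f"{row['n_pipelines']} pipelines; SD (mm) = "
                f"({sd['x']:.1f}, {sd['y']:.1f}, {sd['z']:.1f})."
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    files.append(("report", "report.md"))

    manifest_lines = ["name\tpath"]
    manifest_lines += [f"{name}\t{fname}" for name, fname in files]
    manifest_lines.append("manifest\tmanifest.tsv")
    (outdir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return outdir
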
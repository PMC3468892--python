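"""Variability statistics over multiverse result stacks.

The quantitative side measures how much the group Z statistic moves as
analysis choices change: per-voxel mean activation, the analytic range
(max - min Z across pipelines), and the step-attributable range (mean
absolute pairwise Z difference between the options of one factor, averaged
over all settings of the remaining factors).  The qualitative side measures
agreement of significance calls: the per-voxel significance proportion and
the discordance index min(p, 1 - p).  Peak-location dispersion is
summarized per hemisphere and per ROI in world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multiverse import FactorGrid, MultiverseResult, PipelineSpec

__all__ = [
    "RangeMaps",
    "SignificanceMaps",
    "analytic_range",
    "step_range",
    "significance_proportion",
    "discordance",
    "peak_table",
    "map_correlations",
    "step_pairwise_correlation",
    "extent_summary",
]


@dataclass
class RangeMaps:
    mean_activation: np.ndarray
    analytic_range: np.ndarray


@dataclass
class SignificanceMaps:
    proportion: np.ndarray
    discordance: np.ndarray


def _masked(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.where(mask, vol, np.nan)


def analytic_range(zstack: np.ndarray, mask: np.ndarray) -> RangeMaps:
    """Per-voxel mean and max-min of Z over the pipeline axis (axis 0)."""
    if zstack.shape[0] < 2:
        raise ValueError("need at least 2 maps for a range")
    vals = zstack[:, mask]  # (P, v)
    mean = np.full(mask.shape, np.nan)
    rng = np.full(mask.shape, np.nan)
    mean[mask] = np.nanmean(vals, axis=0)
    rng[mask] = np.nanmax(vals, axis=0) - np.nanmin(vals, axis=0)
    return RangeMaps(mean, rng)


def step_range(
    zstack: np.ndarray,
    grid: FactorGrid,
    pipelines: Sequence[PipelineSpec],
    factor: str,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Step-attributable range for one factor.

    For each fixed setting of the other factors, |Z_a - Z_b| is computed
    for every unordered option pair (a, b) of the target factor; the result
    is the average over pairs and over other-factor settings, per voxel.
    The stack must cover the full grid restricted to the given pipelines'
    factor combinations.
    """
    opts = grid.options(factor)
    others = [f for f in grid.names if f != factor]
    index: dict[tuple, dict[str, int]] = {}
    for i, p in enumerate(pipelines):
        key = tuple(p[f] for f in others)
        index.setdefault(key, {})[p[factor]] = i
    gaps = [key for key, got in index.items() if set(got) != set(opts)]
    if gaps:
        raise ValueError(
            f"incomplete stack for factor {factor!r}: {len(gaps)} other-factor "
            f"settings are missing options (first: {gaps[0]})"
        )
    pair_list = list(combinations(opts, 2))
    acc = np.zeros(zstack.shape[1:])
    for got in index.values():
        for a, b in pair_list:
            acc += np.abs(zstack[got[a]] - zstack[got[b]])
    out = acc / (len(pair_list) * len(index))
    if mask is not None:
        out = _masked(out, mask)
    return out


def significance_proportion(thresholded: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel fraction of thresholded maps marking the voxel significant.

    ``thresholded`` stacks binary maps on the leading axis (or axes).
    """
    flat = thresholded.reshape(-1, *thresholded.shape[-3:])
    if flat.shape[0] < 1:
        raise ValueError("need at least 1 thresholded map")
    return _masked(flat.mean(axis=0), mask)


def discordance(proportion: np.ndarray) -> np.ndarray:
    """Discordance index min(p, 1-p): 0 at unanimity, 0.5 at a 50/50 split."""
    p = np.asarray(proportion, float)
    with np.errstate(invalid="ignore"):
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise ValueError("proportions must lie in [0, 1]")
    return np.minimum(p, 1.0 - p)


def peak_table(
    zstack: np.ndarray,
    pipelines: Sequence[PipelineSpec],
    scopes: Mapping[str, np.ndarray],
    affine: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    """Peak-activation coordinates per pipeline per scope, in world mm.

    The peak is the in-scope voxel of maximal Z; ties break to the lowest
    linear voxel index.  The summary counts distinct locations (coordinates
    rounded to 3 decimals) and reports per-axis SDs and extrema over
    pipelines, per scope.  All-NaN scopes yield a flagged absent row.
    """
    rows = []
    for name, m in scopes.items():
        if not np.any(m):
            raise ValueError(f"scope {name!r} is empty")
        flat_idx = np.flatnonzero(m.ravel())
        for i, p in enumerate(pipelines):
            vals = zstack[i].ravel()[flat_idx]
            if np.all(np.isnan(vals)):
                rows.append(
                    {"pipeline_id": p.id, "scope": name, "x": np.nan, "y": np.nan,
                     "z": np.nan, "peak_z": np.nan, "absent": True}
                )
                continue
            best = flat_idx[np.nanargmax(vals)]
            vox = np.array(np.unravel_index(best, zstack[i].shape))
            world = affine[:3, :3] @ vox + affine[:3, 3]
            rows.append(
                {"pipeline_id": p.id, "scope": name, "x": world[0], "y": world[1],
                 "z": world[2], "peak_z": zstack[i].ravel()[best], "absent": False}
            )
    table = pd.DataFrame(rows)
    summary: dict[str, dict] = {}
    for name in scopes:
        sub = table[(table["scope"] == name) & (~table["absent"])]
        if len(sub) == 0:
            summary[name] = {"n_pipelines": 0, "n_unique_locations": 0}
            continue
        coords = sub[["x", "y", "z"]].to_numpy()
        uniq = np.unique(np.round(coords, 3), axis=0)
        sd = coords.std(axis=0, ddof=1) if len(sub) > 1 else np.zeros(3)
        summary[name] = {
            "n_pipelines": int(len(sub)),
            "n_unique_locations": int(len(uniq)),
            "sd_mm": {ax: float(s) for ax, s in zip("xyz", sd)},
            "min_mm": {ax: float(v) for ax, v in zip("xyz", coords.min(axis=0))},
            "max_mm": {ax: float(v) for ax, v in zip("xyz", coords.max(axis=0))},
        }
    return table, summary


def map_correlations(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation between two maps over in-mask, finite voxels."""
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise ValueError("need >= 2 in-mask voxels with nonzero variance")
    return float(np.corrcoef(x, y)[0, 1])


def step_pairwise_correlation(
    range_maps: Mapping[str, np.ndarray], mask: np.ndarray
) -> dict:
    """Mean |r| (and implied mean R^2) over all unordered factor pairs."""
    names = list(range_maps)
    rs = []
    for a, b in combinations(names, 2):
        rs.append(abs(map_correlations(range_maps[a], range_maps[b], mask)))
    rs = np.asarray(rs)
    return {
        "mean_abs_r": float(rs.mean()),
        "mean_r2": float((rs**2).mean()),
        "n_pairs": int(rs.size),
    }


def extent_summary(result: MultiverseResult) -> dict:
    """Per-method and overall distribution of the significant-voxel fraction.

    The per-map ``prop_sig`` is the significant fraction of in-mask voxels;
    failed-pipeline slots (all-NaN Z) are excluded.
    """
    n_mask = int(result.mask.sum())
    ok = ~np.all(np.isnan(result.zmaps.reshape(result.n_pipelines, -1)), axis=1)
    per_method: dict[str, dict] = {}
    all_props: list[float] = []
    for j, tspec in enumerate(result.methods):
        props = result.thresholded[ok, j].reshape(int(ok.sum()), -1).sum(axis=1) / n_mask
        all_props.extend(props.tolist())
        per_method[tspec.method] = {
            "median": float(np.median(props)) if props.size else 0.0,
            "min": float(props.min()) if props.size else 0.0,
            "max": float(props.max()) if props.size else 0.0,
            "n_maps": int(props.size),
        }
    pooled = np.asarray(all_props)
    return {
        "per_method": per_method,
        "overall": {
            "median": float(np.median(pooled)) if pooled.size else 0.0,
            "min": float(pooled.min()) if pooled.size else 0.0,
            "max": float(pooled.max()) if pooled.size else 0.0,
            "n_maps": int(pooled.size),
        },
    }
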
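"""Single-subject GLM estimation factors and group-level statistics.

Covers the model-estimation side of the factor grid: HRF vs FIR basis sets,
motion-regressor schemes (6/12/24/none), discrete-cosine high-pass nuisance
columns (128 s cutoff), run concatenation, global AR(1) prewhitening, the
stop_success-vs-go contrast under each basis, random-effects group tests,
and the t/F -> Z conversion used for all downstream maps.

Conventions: scan ``i`` is timed at ``i * TR`` (the first acquired slice is
the slice-timing reference); high-pass filtering enters as DCT nuisance
regressors so filtering and model share one projection; the AR(1)
coefficient is a single value pooled over in-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

__all__ = [
    "ModelOptions",
    "DesignMatrix",
    "GLMFit",
    "ZMap",
    "canonical_hrf",
    "fir_basis",
    "motion_regressors",
    "build_design",
    "estimate_ar1",
    "fit_glm",
    "contrast_vector",
    "contrast_stat",
    "contrast_estimate",
    "group_ttest",
    "group_hotelling",
    "stat_to_z",
    "Z_CAP",
]

CONDITIONS = ("go", "stop_success", "stop_fail")
FIR_BINS = 8
#: sentinel cap for Z values arising from infinite / overflowing statistics
Z_CAP = 40.0
_FINE_DT = 0.1


@dataclass(frozen=True)
class ModelOptions:
    order: Literal["normalize_first", "model_first"] = "normalize_first"
    highpass: Literal["cutoff_128s", "off"] = "cutoff_128s"
    autocorr: Literal["ar1", "off"] = "ar1"
    concat: Literal["on", "off"] = "on"
    basis: Literal["hrf", "fir_34_vs_baseline", "fir_interaction"] = "hrf"
    motion: Literal["m6", "m12", "m24", "none"] = "m6"

    def __post_init__(self) -> None:
        allowed = {
            "order": ("normalize_first", "model_first"),
            "highpass": ("cutoff_128s", "off"),
            "autocorr": ("ar1", "off"),
            "concat": ("on", "off"),
            "basis": ("hrf", "fir_34_vs_baseline", "fir_interaction"),
            "motion": ("m6", "m12", "m24", "none"),
        }
        for name, opts in allowed.items():
            if getattr(self, name) not in opts:
                raise ValueError(f"{name} must be one of {opts}, got {getattr(self, name)!r}")


@dataclass
class DesignMatrix:
    """A (volumes x regressors) matrix with machine-readable column names."""

    matrix: np.ndarray
    names: list[str]
    condition_map: dict[str, list[int]]
    run_slices: list[slice]
    df_residual: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names must match matrix columns")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.names).to_csv(path, sep="\t", index=False)


@dataclass
class GLMFit:
    betas: np.ndarray  # (p, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    rho: float
    df: int
    xtx_inv: np.ndarray  # (p, p), from the (possibly whitened) design

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < -1e-12):
            raise ValueError("sigma2 must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class ZMap:
    """One group-level per-voxel Z volume for one pipeline and contrast."""

    values: np.ndarray
    contrast_id: str
    pipeline_id: str
    df_source: int


class ContrastStat(NamedTuple):
    values: np.ndarray  # per-voxel t or F
    kind: str  # "t" or "F"
    df: int
    dfn: int | None  # numerator df for F


# ---------------------------------------------------------------------------
# basis functions


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at ``tr``, scaled to unit peak.

    SPM parameterization: response gamma with shape 6, undershoot gamma with
    shape 16 (both scale 1 s), undershoot weighted 1/6; peak near 5 s,
    undershoot near 15 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0, duration, tr)
    h = stats.gamma.pdf(t, 6.0, scale=1.0) - stats.gamma.pdf(t, 16.0, scale=1.0) / 6.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _hrf_regressor(
    onsets: np.ndarray, durations: np.ndarray, tr: float, n_scans: int
) -> np.ndarray:
    """Boxcar stimulus convolved with the canonical HRF, sampled at scans."""
    t_fine = np.arange(0, n_scans * tr + 32.0, _FINE_DT)
    stick = np.zeros_like(t_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / _FINE_DT))
        i1 = max(i0 + 1, int(round((onset + dur) / _FINE_DT)))
        stick[i0:i1] += 1.0
    hrf = canonical_hrf(_FINE_DT)
    conv = np.convolve(stick, hrf)[: t_fine.size] * _FINE_DT
    scan_t = np.arange(n_scans) * tr
    return np.interp(scan_t, t_fine, conv)


def fir_basis(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    n_bins: int = FIR_BINS,
) -> dict[str, np.ndarray]:
    """Finite-impulse-response regressor blocks, one per condition.

    Bin ``b`` (1-based) of a condition is 1 at scans whose acquisition time
    falls in ``[onset + (b-1)*tr, onset + b*tr)``; overlapping trials sum.
    Conditions absent from ``events`` yield an all-zero block.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scan_t = np.arange(n_scans) * tr
    out: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        block = np.zeros((n_scans, n_bins))
        onsets = np.asarray(events.loc[events["trial_type"] == cond, "onset"], float)
        for onset in onsets:
            rel = scan_t - onset
            for b in range(n_bins):
                hit = (rel >= b * tr) & (rel < (b + 1) * tr)
                block[hit, b] += 1.0
        out[cond] = block
    return out


def motion_regressors(motion: np.ndarray, scheme: str) -> np.ndarray:
    """Expand 6 rigid-body parameters per the chosen scheme.

    m6 = raw; m12 = raw + one-lag time-shifted (first shifted row zero);
    m24 = raw + shifted + element-wise squares of both.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if scheme == "m6":
        return motion.copy()
    shifted = np.vstack([np.zeros((1, 6)), motion[:-1]])
    if scheme == "m12":
        return np.hstack([motion, shifted])
    if scheme == "m24":
        return np.hstack([motion, shifted, motion**2, shifted**2])
    raise ValueError(f"unknown motion scheme {scheme!r}")


def _dct_highpass(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """DCT nuisance columns with periods above ``cutoff`` seconds (SPM style)."""
    k_max = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


# ---------------------------------------------------------------------------
# design assembly


def _run_condition_block(
    events_run: pd.DataFrame, basis: str, tr: float, n_scans: int
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    names: list[str] = []
    cmap: dict[str, list[int]] = {}
    cols: list[np.ndarray] = []
    if basis == "hrf":
        for cond in CONDITIONS:
            sel = events_run[events_run["trial_type"] == cond]
            if len(sel) == 0:
                raise ValueError(f"no events for condition {cond!r}")
            reg = _hrf_regressor(
                np.asarray(sel["onset"], float), np.asarray(sel["duration"], float), tr, n_scans
            )
            cmap[cond] = [len(cols)]
            names.append(cond)
            cols.append(reg)
        return np.column_stack(cols), names, cmap
    # FIR bases
    blocks = fir_basis(events_run, tr, n_scans)
    for cond in CONDITIONS:
        if not np.any(blocks[cond]):
            raise ValueError(f"no events for condition {cond!r}")
        idx0 = len(cols) if not cols else sum(c.shape[1] if c.ndim == 2 else 1 for c in cols)
        cmap[cond] = list(range(idx0, idx0 + FIR_BINS))
        names.extend(f"{cond}_fir{b + 1:02d}" for b in range(FIR_BINS))
        cols.append(blocks[cond])
    return np.hstack([c if c.ndim == 2 else c[:, None] for c in cols]), names, cmap


def _prune_rank_deficient(
    X: np.ndarray, names: list[str], cmap: dict[str, list[int]]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Drop linearly dependent columns (pivoted QR); condition columns are protected."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    if len(keep) == X.shape[1]:
        return X, names, cmap
    protected = {i for idxs in cmap.values() for i in idxs}
    dropped = set(range(X.shape[1])) - set(keep)
    if dropped & protected:
        bad = [names[i] for i in sorted(dropped & protected)]
        raise ValueError(f"condition regressors are rank deficient: {bad}")
    remap = {old: new for new, old in enumerate(keep)}
    new_cmap = {c: [remap[i] for i in idxs] for c, idxs in cmap.items()}
    return X[:, keep], [names[i] for i in keep], new_cmap


def build_design(
    events: pd.DataFrame,
    options: ModelOptions,
    motion: np.ndarray,
    tr: float,
    run_lengths: Sequence[int],
) -> DesignMatrix | list[DesignMatrix]:
    """Assemble the design per the model options.

    ``concat='on'`` returns a single stacked matrix with per-run intercepts
    and per-run DCT drift blocks; ``concat='off'`` returns one matrix per
    run.  Onsets in ``events`` are relative to their own run's start.
    """
    run_lengths = [int(n) for n in run_lengths]
    if sum(run_lengths) != motion.shape[0]:
        raise ValueError("run_lengths must sum to the motion row count")
    n_runs = len(run_lengths)
    starts = np.concatenate([[0], np.cumsum(run_lengths)])

    per_run: list[tuple[np.ndarray, list[str], dict[str, list[int]]]] = []
    nuis: list[tuple[np.ndarray, list[str]]] = []
    for r in range(n_runs):
        ev_r = events[events["run"] == r] if "run" in events else events
        cond_X, cond_names, cmap = _run_condition_block(ev_r, options.basis, tr, run_lengths[r])
        per_run.append((cond_X, cond_names, cmap))
        blocks: list[np.ndarray] = []
        names: list[str] = []
        if options.motion != "none":
            m_r = motion[starts[r] : starts[r + 1]]
            mot = motion_regressors(m_r, options.motion)
            blocks.append(mot)
            names.extend(f"motion{j + 1:02d}" for j in range(mot.shape[1]))
        if options.highpass == "cutoff_128s":
            dct = _dct_highpass(run_lengths[r], tr)
            blocks.append(dct)
            names.extend(f"dct{j + 1:02d}" for j in range(dct.shape[1]))
        nuis.append((np.hstack(blocks) if blocks else np.zeros((run_lengths[r], 0)), names))

    if options.concat == "off":
        designs = []
        for r in range(n_runs):
            cond_X, cond_names, cmap = per_run[r]
            nX, nnames = nuis[r]
            X = np.hstack([cond_X, nX, np.ones((run_lengths[r], 1))])
            names = cond_names + nnames + ["intercept"]
            X, names, cmap = _prune_rank_deficient(X, names, cmap)
            designs.append(
                DesignMatrix(X, names, cmap, [slice(0, run_lengths[r])],
                             df_residual=run_lengths[r] - X.shape[1])
            )
        return designs

    # concatenated: shared condition columns, block-diagonal nuisance + intercepts
    n_total = sum(run_lengths)
    cond_cols = per_run[0][0].shape[1]
    cond_X = np.zeros((n_total, cond_cols))
    for r in range(n_runs):
        cond_X[starts[r] : starts[r + 1]] = per_run[r][0]
    cond_names, cmap = per_run[0][1], per_run[0][2]
    blocks = [cond_X]
    names = list(cond_names)
    for r in range(n_runs):
        nX, nnames = nuis[r]
        if nX.shape[1]:
            block = np.zeros((n_total, nX.shape[1]))
            block[starts[r] : starts[r + 1]] = nX
            blocks.append(block)
            names.extend(f"run{r + 1}_{nm}" for nm in nnames)
    for r in range(n_runs):
        ic = np.zeros((n_total, 1))
        ic[starts[r] : starts[r + 1]] = 1.0
        blocks.append(ic)
        names.append(f"intercept_run{r + 1}")
    X = np.hstack(blocks)
    X, names, cmap = _prune_rank_deficient(X, names, cmap)
    run_slices = [slice(int(starts[r]), int(starts[r + 1])) for r in range(n_runs)]
    return DesignMatrix(X, names, cmap, run_slices, df_residual=n_total - X.shape[1])


# ---------------------------------------------------------------------------
# estimation


def estimate_ar1(
    residuals: np.ndarray, run_slices: Sequence[slice] | None = None
) -> float:
    """Globally pooled lag-1 autocorrelation of residuals.

    ``residuals`` is (n_scans, n_voxels).  Lag products never cross run
    boundaries; zero-variance voxels are excluded from the pool.  The
    estimate is clipped to (-0.99, 0.99).
    """
    residuals = np.asarray(residuals, float)
    if residuals.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    var = residuals.var(axis=0)
    ok = var > 0
    if not np.any(ok):
        raise ValueError("all residual series have zero variance")
    r = residuals[:, ok] - residuals[:, ok].mean(axis=0)
    slices = run_slices or [slice(0, r.shape[0])]
    num = 0.0
    den = 0.0
    for sl in slices:
        seg = r[sl]
        num += float(np.sum(seg[1:] * seg[:-1]))
        den += float(np.sum(seg**2))
    rho = num / den if den > 0 else 0.0
    return float(np.clip(rho, -0.99, 0.99))


def _whiten(arr: np.ndarray, rho: float, run_slices: Sequence[slice]) -> np.ndarray:
    """Apply the AR(1) inverse square-root filter per run block."""
    if rho == 0.0:
        return arr
    out = arr.astype(float).copy()
    for sl in run_slices:
        seg = arr[sl]
        w = seg.copy().astype(float)
        w[0] = seg[0] * np.sqrt(1.0 - rho**2)
        w[1:] = seg[1:] - rho * seg[:-1]
        out[sl] = w
    return out


def fit_glm(
    Y: np.ndarray,
    design: DesignMatrix,
    autocorr: str = "off",
    rho: float | None = None,
) -> GLMFit:
    """OLS fit, optionally AR(1)-prewhitened with a pooled rho.

    ``Y`` is (n_scans, n_voxels).  With ``autocorr='ar1'`` and no explicit
    ``rho``, rho is estimated from the OLS residuals of this fit.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y rows must match design rows")
    if design.df_residual <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if autocorr not in ("ar1", "off"):
        raise ValueError("autocorr must be 'ar1' or 'off'")

    use_rho = 0.0
    if autocorr == "ar1":
        if rho is None:
            pinv0 = np.linalg.pinv(X)
            resid0 = Y - X @ (pinv0 @ Y)
            use_rho = estimate_ar1(resid0, design.run_slices)
        else:
            use_rho = float(rho)
    Xw = _whiten(X, use_rho, design.run_slices)
    Yw = _whiten(Y, use_rho, design.run_slices)
    pinv = np.linalg.pinv(Xw)
    betas = pinv @ Yw
    resid = Yw - Xw @ betas
    rss = np.sum(resid**2, axis=0)
    df = design.df_residual
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    return GLMFit(betas=betas, sigma2=sigma2, rho=use_rho, df=df, xtx_inv=xtx_inv)


# ---------------------------------------------------------------------------
# contrasts


def contrast_vector(design: DesignMatrix, basis: str) -> np.ndarray:
    """Contrast weights for stop_success vs go under the given basis.

    hrf -> (+1, -1) on the two condition columns; fir_34_vs_baseline -> the
    mean of FIR bins 3-4 of stop_success minus the same for go (weights
    +-1/2); fir_interaction -> an (8, p) matrix of pairwise bin differences.
    """
    p = design.matrix.shape[1]
    ss = design.condition_map["stop_success"]
    go = design.condition_map["go"]
    if basis == "hrf":
        c = np.zeros(p)
        c[ss[0]] = 1.0
        c[go[0]] = -1.0
        return c
    if basis == "fir_34_vs_baseline":
        c = np.zeros(p)
        for b in (2, 3):  # bins 3 and 4, 0-based
            c[ss[b]] = 0.5
            c[go[b]] = -0.5
        return c
    if basis == "fir_interaction":
        C = np.zeros((FIR_BINS, p))
        for b in range(FIR_BINS):
            C[b, ss[b]] = 1.0
            C[b, go[b]] = -1.0
        return C
    raise ValueError(f"unknown basis {basis!r}")


def contrast_estimate(fit: GLMFit, design: DesignMatrix, basis: str) -> np.ndarray:
    """Per-voxel contrast estimate: (v,) for t-type bases, (8, v) for FIR interaction."""
    c = contrast_vector(design, basis)
    return c @ fit.betas


def contrast_stat(fit: GLMFit, design: DesignMatrix, basis: str) -> ContrastStat:
    """Subject-level t (hrf, fir_34) or F (fir_interaction) statistic."""
    c = contrast_vector(design, basis)
    if c.ndim == 1:
        est = c @ fit.betas
        var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), 0.0)
        return ContrastStat(values=t, kind="t", df=fit.df, dfn=None)
    C = c
    est = C @ fit.betas  # (8, v)
    M = C @ fit.xtx_inv @ C.T  # (8, 8)
    Minv = np.linalg.pinv(M)
    quad = np.einsum("av,ab,bv->v", est, Minv, est)
    dfn = C.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(fit.sigma2 > 0, quad / (dfn * fit.sigma2), 0.0)
    return ContrastStat(values=np.maximum(F, 0.0), kind="F", df=fit.df, dfn=dfn)


# ---------------------------------------------------------------------------
# group stage


def group_ttest(contrast_maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t across subjects, per voxel; df = n - 1.

    Zero between-subject variance with a nonzero mean yields +-inf, which
    ``stat_to_z`` later caps at the Z sentinel.
    """
    maps = np.asarray(contrast_maps, float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t, n - 1


def group_hotelling(diff_maps: np.ndarray) -> tuple[np.ndarray, int, int]:
    """One-sample Hotelling T^2 -> F over per-subject FIR bin differences.

    ``diff_maps`` is (n_subjects, n_bins, n_voxels).  Returns (F, dfn, dfd)
    with dfn = n_bins and dfd = n_subjects - n_bins (requires n > n_bins).
    """
    D = np.asarray(diff_maps, float)
    n, p = D.shape[0], D.shape[1]
    if n <= p:
        raise ValueError(f"Hotelling group test needs more than {p} subjects, got {n}")
    xbar = D.mean(axis=0)  # (p, v)
    C = D - xbar[None]
    S = np.einsum("nav,nbv->vab", C, C) / (n - 1)  # (v, p, p)
    S += 1e-10 * np.eye(p)[None]
    rhs = np.moveaxis(xbar, -1, 0)[..., None]  # (v, p, 1)
    sol = np.linalg.solve(S, rhs)[..., 0]  # (v, p)
    t2 = n * np.einsum("vp,vp->v", np.moveaxis(xbar, -1, 0), sol)
    F = (n - p) / (p * (n - 1)) * t2
    return np.maximum(F, 0.0), p, n - p


def stat_to_z(
    stat: np.ndarray,
    df: int,
    kind: str = "t",
    dfn: int | None = None,
) -> np.ndarray:
    """Convert t or F statistics to Z values through matched tail areas.

    t: ``z = Phi^-1(F_t(t; df))`` computed tail-wise for numerical symmetry;
    F: ``z = Phi^-1(1 - p_F)`` one-sided.  Non-finite inputs propagate as
    NaN; infinities and overflow map to the +-``Z_CAP`` sentinel.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    stat = np.asarray(stat, float)
    z = np.full(stat.shape, np.nan)
    finite = np.isfinite(stat)
    if kind == "t":
        s = stat[finite]
        upper = s > 0
        zt = np.empty(s.shape)
        # mirror the tails so t -> z is exactly antisymmetric
        zt[upper] = -stats.norm.ppf(stats.t.sf(s[upper], df))
        zt[~upper] = stats.norm.ppf(stats.t.cdf(s[~upper], df))
        z[finite] = zt
        z[np.isposinf(stat)] = Z_CAP
        z[np.isneginf(stat)] = -Z_CAP
    elif kind == "F":
        if dfn is None:
            raise ValueError("F conversion requires numerator df")
        z[finite] = stats.norm.isf(stats.f.sf(stat[finite], dfn, df))
        z[np.isposinf(stat)] = Z_CAP
    else:
        raise ValueError("kind must be 't' or 'F'")
    return np.clip(z, -Z_CAP, Z_CAP)
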
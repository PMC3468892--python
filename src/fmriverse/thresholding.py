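"""Five significance-thresholding regimes for group Z maps.

Three Monte-Carlo cluster-extent corrections (uncorrected voxel thresholds
p < .01 / .001 / .0001, cluster size calibrated by null simulation to a 5%
cluster-wise false-positive rate), Benjamini-Hochberg FDR at q = .05, and a
Gaussian random-field-theory voxel threshold at corrected p = .05.  All
thresholding is one-sided on the positive (activation) tail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "ThresholdSpec",
    "ThresholdedMap",
    "default_threshold_specs",
    "estimate_smoothness",
    "simulate_null_zmap",
    "mc_cluster_threshold",
    "fdr_cutoff",
    "rft_cutoff",
    "apply_threshold",
    "with_cluster_k",
]

MC_METHODS = ("mc_p01", "mc_p001", "mc_p0001")
ALL_METHODS = MC_METHODS + ("fdr", "rft")
_MC_VOXEL_P = {"mc_p01": 0.01, "mc_p001": 0.001, "mc_p0001": 0.0001}

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ThresholdSpec:
    """One row of the thresholding-regime table.

    Monte-Carlo methods carry an uncorrected voxel p and a simulated cluster
    size; FDR and RFT carry a corrected p of 0.05 and no cluster size.
    """

    method: str
    voxel_p_uncorrected: float | None = None
    corrected_p: float | None = None
    cluster_k: int | None = None
    alpha_clusterwise: float = 0.05

    def __post_init__(self) -> None:
        if self.method in MC_METHODS:
            if self.voxel_p_uncorrected is None:
                raise ValueError(f"{self.method} requires an uncorrected voxel p")
            if self.corrected_p is not None:
                raise ValueError(f"{self.method} does not take a corrected p")
        elif self.method in ("fdr", "rft"):
            if self.corrected_p is None or self.voxel_p_uncorrected is not None:
                raise ValueError(f"{self.method} takes only a corrected p")
            if self.cluster_k is not None:
                raise ValueError(f"{self.method} does not use a cluster size")
        else:
            raise ValueError(f"unknown thresholding method {self.method!r}")


@dataclass
class ThresholdedMap:
    """Binary significance volume for one ZMap under one regime."""

    significant: np.ndarray
    spec: ThresholdSpec
    pipeline_id: str
    n_sig_voxels: int
    prop_sig: float


def default_threshold_specs() -> list[ThresholdSpec]:
    """The standard five regimes (cluster sizes still to be simulated)."""
    specs = [
        ThresholdSpec(m, voxel_p_uncorrected=_MC_VOXEL_P[m]) for m in MC_METHODS
    ]
    specs.append(ThresholdSpec("fdr", corrected_p=0.05))
    specs.append(ThresholdSpec("rft", corrected_p=0.05))
    return specs


# ---------------------------------------------------------------------------
# spatial smoothness


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size: Sequence[float],
) -> np.ndarray:
    """Per-axis FWHM (mm) from spatial first differences of residuals.

    Forman-style estimator: each residual volume is standardized within the
    mask; for a unit-variance Gaussian field the variance of neighbouring
    differences determines the lag-1 spatial correlation and hence the
    kernel sigma via ``sigma^2 = -1 / (4 ln(1 - v_d/2))``.  Estimates are
    averaged over volumes and floored at one voxel width per axis.
    """
    residuals = np.asarray(residuals, float)
    if residuals.ndim == 3:
        residuals = residuals[None]
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual volumes")
    if not np.any(np.abs(residuals) > 0):
        raise ValueError("all-zero residuals")
    voxel_size = np.asarray(voxel_size, float)
    fwhms = []
    for vol in residuals:
        sd = vol[mask].std()
        if sd == 0:
            continue
        v = vol / sd
        axis_fwhm = np.empty(3)
        for ax in range(3):
            m_pair = mask & np.roll(mask, -1, axis=ax)
            # drop the wrap-around face
            sl = [slice(None)] * 3
            sl[ax] = slice(0, mask.shape[ax] - 1)
            valid = np.zeros_like(mask)
            valid[tuple(sl)] = m_pair[tuple(sl)]
            d = np.roll(v, -1, axis=ax) - v
            vd = d[valid]
            if vd.size < 10:
                axis_fwhm[ax] = 1.0
                continue
            ratio = float(np.mean(vd**2)) / 2.0
            if ratio >= 1.0:
                axis_fwhm[ax] = 1.0  # spatially independent: floor at 1 voxel
                continue
            sigma2 = -1.0 / (4.0 * np.log(1.0 - ratio))
            axis_fwhm[ax] = max(np.sqrt(8.0 * np.log(2.0) * sigma2), 1.0)
        fwhms.append(axis_fwhm)
    if not fwhms:
        raise ValueError("all residual volumes have zero variance in the mask")
    return np.mean(fwhms, axis=0) * voxel_size


# ---------------------------------------------------------------------------
# Monte Carlo cluster-extent calibration


def simulate_null_zmap(
    mask: np.ndarray,
    fwhm_mm: float | Sequence[float],
    voxel_size: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One null Z volume: smoothed white noise standardized within the mask."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, float), (3,))
    noise = rng.standard_normal(mask.shape)
    sig = fwhm / (np.asarray(voxel_size, float) * np.sqrt(8.0 * np.log(2.0)))
    if np.any(sig > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sig, mode="constant", cval=0.0)
    vals = noise[mask]
    noise = (noise - vals.mean()) / vals.std()
    out = np.where(mask, noise, np.nan)
    return out


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.max(np.bincount(labels.ravel())[1:]))


def mc_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float | Sequence[float],
    voxel_p: float,
    alpha: float = 0.05,
    n_sims: int = 1000,
    connectivity: int = 26,
    rng: np.random.Generator | None = None,
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
) -> int:
    """Cluster-size threshold controlling the cluster-wise FPR at ``alpha``.

    Simulates ``n_sims`` null fields matched to the mask and smoothness,
    binarizes each at the one-sided z equivalent of ``voxel_p``, labels
    clusters, and returns the smallest k such that the fraction of
    simulations whose largest cluster reaches k is at most ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_sims < 200:
        raise ValueError("n_sims must be >= 200 for a stable tail estimate")
    if rng is None:
        rng = np.random.default_rng(0)
    structure = _STRUCTURES[connectivity]
    z_thr = stats.norm.isf(voxel_p)
    max_sizes = np.empty(n_sims, dtype=int)
    for i in range(n_sims):
        null = simulate_null_zmap(mask, fwhm_mm, voxel_size, rng)
        binary = np.nan_to_num(null, nan=-np.inf) > z_thr
        max_sizes[i] = _max_cluster_size(binary & mask, structure)
    top = int(max_sizes.max())
    for k in range(1, top + 2):
        if np.mean(max_sizes >= k) <= alpha:
            return k
    return top + 1


# ---------------------------------------------------------------------------
# FDR


def fdr_cutoff(p_values: np.ndarray, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up over in-mask p values.

    Returns the p cutoff (0.0 when nothing survives) and a boolean
    significance vector aligned with the input.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value set (empty mask?)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(sorted_p <= thresh)
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    cut = float(sorted_p[passing[-1]])
    return cut, p <= cut


# ---------------------------------------------------------------------------
# Gaussian random field theory


def _ec_3d(z: np.ndarray | float, resels: float) -> np.ndarray | float:
    """Expected Euler characteristic of a 3D excursion set (leading term)."""
    z = np.asarray(z, float)
    return (
        resels
        * (4.0 * np.log(2.0)) ** 1.5
        * (2.0 * np.pi) ** -2.0
        * (z**2 - 1.0)
        * np.exp(-(z**2) / 2.0)
    )


def rft_cutoff(
    mask: np.ndarray,
    fwhm_mm: Sequence[float] | float,
    voxel_size: Sequence[float],
    alpha: float = 0.05,
) -> float:
    """Voxel Z cutoff solving E[EC] = alpha, capped by Bonferroni.

    The resel count is the in-mask volume divided by the FWHM product; the
    root is bracketed on the decreasing branch of the EC density.  When the
    field is too rough for RFT to beat Bonferroni, the Bonferroni cutoff is
    returned (the SPM convention).
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, float), (3,))
    voxel_size = np.asarray(voxel_size, float)
    if np.any(fwhm < voxel_size - 1e-9):
        raise ValueError("fwhm must be at least one voxel per axis for RFT")
    n_vox = int(np.sum(mask))
    if n_vox == 0:
        raise ValueError("empty mask")
    resels = n_vox * float(np.prod(voxel_size)) / float(np.prod(fwhm))
    bonf = float(stats.norm.isf(alpha / n_vox))
    z_lo = np.sqrt(3.0)  # peak of the EC density
    if _ec_3d(z_lo, resels) <= alpha:
        return bonf
    if _ec_3d(40.0, resels) > alpha:
        raise ValueError(
            f"no RFT root in [sqrt(3), 40]: resels={resels:.3g}, alpha={alpha}"
        )
    z_rft = optimize.brentq(lambda z: _ec_3d(z, resels) - alpha, z_lo, 40.0, xtol=1e-10)
    return float(min(z_rft, bonf))


# ---------------------------------------------------------------------------
# application


def apply_threshold(
    zvalues: np.ndarray,
    spec: ThresholdSpec,
    mask: np.ndarray,
    fwhm_mm: Sequence[float] | float | None = None,
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
    connectivity: int = 26,
    pipeline_id: str = "",
) -> ThresholdedMap:
    """Binarize one Z volume under one regime.

    Monte-Carlo methods binarize at the voxel threshold and drop clusters
    smaller than the simulated ``cluster_k`` (which must already be set on
    the spec); FDR converts Z to one-sided p and applies BH at q = .05; RFT
    binarizes at the analytic cutoff.
    """
    z = np.where(mask, zvalues, np.nan)
    n_mask = int(mask.sum())
    if spec.method in MC_METHODS:
        if spec.cluster_k is None:
            raise ValueError(f"{spec.method} requires a simulated cluster_k")
        z_thr = stats.norm.isf(spec.voxel_p_uncorrected)
        binary = np.nan_to_num(z, nan=-np.inf) > z_thr
        labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
        sig = np.zeros_like(binary)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = np.flatnonzero(sizes >= spec.cluster_k)
            keep = keep[keep > 0]
            sig = np.isin(labels, keep)
    elif spec.method == "fdr":
        pv = stats.norm.sf(np.nan_to_num(z, nan=-np.inf)[mask])
        _, sig_flat = fdr_cutoff(pv, q=spec.corrected_p)
        sig = np.zeros(mask.shape, dtype=bool)
        sig[mask] = sig_flat
    elif spec.method == "rft":
        if fwhm_mm is None:
            raise ValueError("rft thresholding requires a smoothness estimate")
        cut = rft_cutoff(mask, fwhm_mm, voxel_size, alpha=spec.corrected_p)
        sig = np.nan_to_num(z, nan=-np.inf) > cut
    else:  # pragma: no cover - spec validation prevents this
        raise ValueError(f"unknown method {spec.method!r}")
    sig = sig & mask
    n_sig = int(sig.sum())
    return ThresholdedMap(
        significant=sig,
        spec=spec,
        pipeline_id=pipeline_id,
        n_sig_voxels=n_sig,
        prop_sig=n_sig / n_mask if n_mask else 0.0,
    )


def with_cluster_k(spec: ThresholdSpec, cluster_k: int) -> ThresholdSpec:
    """Return a copy of a Monte-Carlo spec with its simulated cluster size."""
    if spec.method not in MC_METHODS:
        raise ValueError("cluster sizes only apply to Monte-Carlo methods")
    return replace(spec, cluster_k=int(cluster_k))
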
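"""Pre-processing factors: despiking, slice-timing, normalization, smoothing.

All operators are deterministic and either shape-preserving or map onto the
declared template grid.  The spatial-normalization step is a documented
moment-matching *surrogate* (translation + per-axis scale, trilinear
resampling): it is NOT SPM's unified normalization, but gives three distinct
deterministic resamplings to a shared grid, which is all the multiverse
factor requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocOptions",
    "Template",
    "make_template",
    "despike",
    "phase_shift",
    "slice_time_correct",
    "estimate_normalization",
    "apply_normalization",
    "normalize",
    "smooth",
]

NORMALIZATION_STRATEGIES = ("epi_template", "t1_template", "segmentation")


@dataclass(frozen=True)
class PreprocOptions:
    despike: Literal["on", "off"] = "off"
    slice_timing: Literal["on", "off"] = "off"
    normalization: str = "epi_template"
    smoothing_fwhm: float = 8.0

    def __post_init__(self) -> None:
        if self.despike not in ("on", "off"):
            raise ValueError(f"despike must be on/off, got {self.despike!r}")
        if self.slice_timing not in ("on", "off"):
            raise ValueError(f"slice_timing must be on/off, got {self.slice_timing!r}")
        if self.normalization not in NORMALIZATION_STRATEGIES:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.smoothing_fwhm not in (4.0, 8.0, 12.0):
            raise ValueError("smoothing_fwhm must be one of 4, 8, 12 mm")


# ---------------------------------------------------------------------------
# despiking


def _legendre_basis(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)  # (n, order+1)


def despike(
    data: np.ndarray,
    tr: float,
    c1: float = 2.5,
    c2: float = 4.0,
) -> np.ndarray:
    """Compress transient spikes toward a smooth per-voxel baseline.

    A low-order Legendre trend (order ``2 + duration // 150 s``) is fitted to
    each voxel series; the residual scale is sigma = MAD / 0.6745.  Residuals
    with |r| > c1*sigma are mapped through the saturating curve
    ``c1 + (c2 - c1) * tanh((|r|/sigma - c1) / (c2 - c1))`` (bounded at
    c2*sigma); all other samples are returned unchanged.  Constant series
    (sigma = 0) pass through untouched.

    ``data`` may be any array with time on the last axis.
    """
    if not c2 > c1 > 0:
        raise ValueError("need c2 > c1 > 0")
    n_t = data.shape[-1]
    if n_t < 8:
        raise ValueError("series too short to despike (need >= 8 samples)")
    order = 2 + int((n_t * tr) // 150)
    basis = _legendre_basis(n_t, order)
    pinv = np.linalg.pinv(basis)
    flat = data.reshape(-1, n_t)
    coef = flat @ pinv.T
    trend = coef @ basis.T
    resid = flat - trend
    sigma = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1) / 0.6745
    out = flat.copy()
    # sigma==0 guard, with headroom for trend-fit round-off on constant series
    ok = sigma > 1e-10 * np.maximum(np.abs(flat).max(axis=1), 1.0)
    if np.any(ok):
        s = np.zeros_like(resid)
        s[ok] = resid[ok] / sigma[ok, None]
        spiky = np.abs(s) > c1
        spiky &= ok[:, None]
        s_new = np.sign(s) * (c1 + (c2 - c1) * np.tanh((np.abs(s) - c1) / (c2 - c1)))
        out[spiky] = (trend + s_new * sigma[:, None])[spiky]
    return out.reshape(data.shape)


# ---------------------------------------------------------------------------
# slice-timing correction


def phase_shift(series: np.ndarray, shift: float, tr: float) -> np.ndarray:
    """Evaluate ``x(t + shift)`` for series sampled at interval ``tr``.

    Frequency-domain phase ramp (time on the last axis); the DC term is
    untouched so the mean is preserved exactly.
    """
    n_t = series.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=tr)
    phase = np.exp(2j * np.pi * freqs * shift)
    if n_t % 2 == 0:
        # the Nyquist bin of a real series carries no phase; the proper
        # real-valued band-limited shift scales it by cos
        phase[-1] = np.cos(2 * np.pi * freqs[-1] * shift)
    spec = np.fft.rfft(series, axis=-1) * phase
    return np.fft.irfft(spec, n=n_t, axis=-1)


def slice_time_correct(
    run: np.ndarray,
    tr: float,
    slice_order: Sequence[int] | None = None,
    ref_slice: int = 0,
    slice_axis: int = 2,
) -> np.ndarray:
    """Resample every slice's time-series to the reference slice's time.

    Slice ``k`` (the k-th along ``slice_axis``) is assumed acquired at offset
    ``pos_k * TR / n_slices`` within each TR, where ``pos_k`` is the position
    of k in ``slice_order`` (default ascending).  The shift is applied as a
    frequency-domain phase ramp, which preserves each voxel's mean exactly
    (the DC term is untouched).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n_slices = run.shape[slice_axis]
    if slice_order is None:
        slice_order = list(range(n_slices))
    if sorted(slice_order) != list(range(n_slices)):
        raise ValueError("slice_order must be a permutation of slice indices")
    pos = np.empty(n_slices, dtype=int)
    for acq_index, k in enumerate(slice_order):
        pos[k] = acq_index
    dt_per_slice = tr / n_slices
    n_t = run.shape[-1]
    out = np.empty_like(run, dtype=float)
    ref_time = pos[ref_slice] * dt_per_slice
    for k in range(n_slices):
        sl = np.take(run, k, axis=slice_axis)
        # series sampled at t_i = i*TR + pos_k*dt; we want samples at
        # i*TR + ref_time, i.e. the series advanced by (ref_time - t_k)
        shifted = phase_shift(sl, ref_time - pos[k] * dt_per_slice, tr)
        idx = [slice(None)] * run.ndim
        idx[slice_axis] = k
        out[tuple(idx)] = shifted
    return out


# ---------------------------------------------------------------------------
# normalization surrogate


@dataclass
class Template:
    """A shared target grid with one canonical reference image per strategy."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    images: dict[str, np.ndarray] = field(default_factory=dict)


def make_template(
    shape: tuple[int, int, int],
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
) -> Template:
    """Canonical centred-ellipsoid template images for the three strategies.

    - ``epi_template``: near-uniform ellipsoid (like a mean functional);
    - ``t1_template``: radially profiled ellipsoid (like anatomy);
    - ``segmentation``: two-class weighted ellipsoid.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag(list(voxel_size) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_size)
    idx = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.array([0.45, 0.45, 0.42])
    rho = np.sqrt(sum(((idx[ax] - c[ax]) / semi[ax]) ** 2 for ax in range(3)))
    inside = rho <= 1.0
    images = {
        "epi_template": 100.0 * inside,
        "t1_template": 100.0 * np.clip(1.0 - rho**2, 0.0, None) * inside,
        "segmentation": 50.0 * inside + 50.0 * (rho < 0.6),
    }
    return Template(shape=shape, affine=affine, images=images)


def _moments(img: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted world-space centroid and per-axis SD."""
    w = np.clip(img, 0, None).astype(float)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot compute moments of an all-zero image")
    idx = np.indices(img.shape).astype(float).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    wf = w.ravel()
    c = (world * wf).sum(axis=1) / total
    sd = np.sqrt(((world - c[:, None]) ** 2 * wf).sum(axis=1) / total)
    return c, sd


def _source_reference(
    volumes: Sequence[np.ndarray], strategy: str, mask: np.ndarray | None
) -> np.ndarray:
    mean_func = np.mean([v.mean(axis=-1) if v.ndim == 4 else v for v in volumes], axis=0)
    if not np.any(mean_func):
        raise ValueError("all-zero source image; cannot normalize")
    if strategy == "epi_template":
        return mean_func
    if strategy == "t1_template":
        m = mask if mask is not None else mean_func > 0.5 * mean_func.max()
        dist = ndimage.distance_transform_edt(m)
        return 100.0 * dist / max(dist.max(), 1e-12)
    if strategy == "segmentation":
        m = mask if mask is not None else mean_func > 0.5 * mean_func.max()
        vals = mean_func[m]
        thr = vals.mean() if vals.size else 0.0
        weights = 1.0 + (mean_func > thr)
        return mean_func * weights
    raise ValueError(f"unknown normalization strategy {strategy!r}")


def estimate_normalization(
    volumes: Sequence[np.ndarray] | np.ndarray,
    strategy: str,
    template: Template,
    mask: np.ndarray | None = None,
    source_affine: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate the world-to-world affine ``x_tpl = S x_src + t``.

    Translation and per-axis scale are found by matching the intensity
    centroid and per-axis SD of a strategy-specific source reference image
    (mean functional / anatomical proxy / class-weighted functional) to the
    matching canonical template image.
    """
    vols = [volumes] if isinstance(volumes, np.ndarray) else list(volumes)
    if strategy not in template.images:
        raise ValueError(f"unknown normalization strategy {strategy!r}")
    src_ref = _source_reference(vols, strategy, mask)
    if source_affine is None:
        source_affine = template.affine  # same world frame by default
    c_src, sd_src = _moments(src_ref, source_affine)
    c_tpl, sd_tpl = _moments(template.images[strategy], template.affine)
    scale = np.clip(sd_tpl / np.maximum(sd_src, 1e-9), 0.7, 1.4)
    trans = c_tpl - scale * c_src
    xform = np.eye(4)
    xform[:3, :3] = np.diag(scale)
    xform[:3, 3] = trans
    return xform


def apply_normalization(
    volume: np.ndarray,
    xform: np.ndarray,
    template: Template,
    source_affine: np.ndarray | None = None,
) -> np.ndarray:
    """Trilinearly resample one 3D/4D volume onto the template grid."""
    if source_affine is None:
        source_affine = template.affine
    inv_world = np.linalg.inv(xform)
    vox_map = np.linalg.inv(source_affine) @ inv_world @ template.affine
    matrix = vox_map[:3, :3]
    offset = vox_map[:3, 3]
    if volume.ndim == 3:
        return ndimage.affine_transform(
            volume, matrix, offset=offset, output_shape=template.shape, order=1,
            mode="constant", cval=0.0,
        )
    n_t = volume.shape[-1]
    res = np.empty(template.shape + (n_t,))
    for t in range(n_t):
        res[..., t] = ndimage.affine_transform(
            volume[..., t], matrix, offset=offset, output_shape=template.shape,
            order=1, mode="constant", cval=0.0,
        )
    return res


def normalize(
    volumes: Sequence[np.ndarray] | np.ndarray,
    strategy: str,
    template: Template,
    mask: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Resample volume(s) onto the template grid by moment matching.

    Convenience wrapper around :func:`estimate_normalization` and
    :func:`apply_normalization`.  Returns the resampled volumes and the 4x4
    world-to-world transform.
    """
    vols = [volumes] if isinstance(volumes, np.ndarray) else list(volumes)
    xform = estimate_normalization(vols, strategy, template, mask)
    return [apply_normalization(v, xform, template) for v in vols], xform


# ---------------------------------------------------------------------------
# smoothing


def smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size: Sequence[float] = (3.0, 3.0, 3.0),
) -> np.ndarray:
    """Separable Gaussian smoothing; zero-padded boundaries, no renormalization.

    ``sigma_axis = fwhm / (voxel_size_axis * sqrt(8 ln 2))``; a 4D input is
    smoothed along the three spatial axes only.  ``fwhm_mm = 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sig = [fwhm_mm / (vs * np.sqrt(8.0 * np.log(2.0))) for vs in voxel_size]
    if volume.ndim == 4:
        sig = sig + [0.0]
    return ndimage.gaussian_filter(volume.astype(float), sigma=sig, mode="constant", cval=0.0)
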
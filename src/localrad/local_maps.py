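"""Seven local first-order parametric maps over a sliding square tissue unit.

Each in-ROI window centre gets the first-order statistics of the full w x w
window of intensities around it: Shannon entropy, mean, median, skewness,
kurtosis (excess), interquartile range and coefficient of variation.  A
centre is valid only if its window lies fully inside the image bounds and
the in-mask pixel fraction meets ``min_inmask_fraction`` (default 1.0, i.e.
windows fully inside the ROI, which keeps intestinal lumen and background
out of the statistics).

Conventions (all documented sentinels, chosen so the maps are finite
everywhere they are defined):

* skewness is the Fisher-Pearson moment coefficient m3 / m2^(3/2) with
  population (biased) moments; 0 on zero-variance windows;
* kurtosis is excess kurtosis m4 / m2^2 - 3, 0 on zero-variance windows;
* cv = population sd / mean, 0 when sd = 0 or |mean| < 1e-12;
* entropy is base-2 Shannon entropy of an equal-width histogram over the
  window's own [min, max] (shift- and scale-invariant); 0 when min = max;
* quantiles use linear interpolation (the same convention everywhere in the
  package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import PipelineConfig, RoiImageStack

__all__ = [
    "LocalMapSet",
    "window_size_px",
    "local_statistics",
    "compute_local_maps",
    "export_maps",
    "STAT_NAMES",
]

logger = logging.getLogger(__name__)

#: canonical order of the seven local statistics
STAT_NAMES = ("entropy", "mean", "median", "skewness", "kurtosis", "iqr", "cv")

_MEAN_GUARD = 1e-12


@dataclass
class LocalMapSet:
    """The seven per-slice parametric maps of one patient.

    ``maps[name][k]`` is a 2D float array for slice ``k`` with NaN at
    positions where the map is undefined; ``valid_masks[k]`` marks the
    window centres where all seven maps are defined.
    """

    maps: dict[str, list[np.ndarray]]
    valid_masks: list[np.ndarray]
    window_px: int

    @property
    def n_valid(self) -> int:
        return int(sum(m.sum() for m in self.valid_masks))


def window_size_px(tissue_unit_mm: float, pixel_spacing_mm: float) -> int:
    """Convert the physical tissue-unit side length to an odd pixel count.

    Returns the odd integer nearest to ``tissue_unit_mm / pixel_spacing_mm``,
    breaking ties toward the smaller odd integer.  The ratio must be >= 3:
    below that the window degenerates at the given resolution.
    """
    if tissue_unit_mm <= 0 or pixel_spacing_mm <= 0:
        raise ValueError("tissue_unit_mm and pixel_spacing_mm must be positive")
    ratio = tissue_unit_mm / pixel_spacing_mm
    if ratio < 3:
        raise ValueError(
            f"tissue unit {tissue_unit_mm} mm spans only {ratio:.2f} px at "
            f"{pixel_spacing_mm} mm spacing; need >= 3 px for a meaningful window"
        )
    lo = int(np.floor(ratio))
    if lo % 2 == 0:
        lo -= 1
    hi = lo + 2
    w = lo if (ratio - lo) <= (hi - ratio) else hi
    return max(w, 3)


def local_statistics(values, entropy_bins: int = 32) -> dict[str, float]:
    """Compute the seven first-order statistics of one sample.

    ``values`` is the multiset of intensities of one window (>= 9 values,
    i.e. at least a 3 x 3 window) or any pooled sample.  Returns a dict
    keyed by :data:`STAT_NAMES`.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 9:
        raise ValueError(f"need at least 9 values, got {x.size}")
    mean = float(np.mean(x))
    median = float(np.median(x))
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = float(q3 - q1)
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 > 0:
        m3 = float(np.mean(d**3))
        m4 = float(np.mean(d**4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
        sd = m2**0.5
    else:
        skewness = 0.0
        kurtosis = 0.0
        sd = 0.0
    if sd == 0.0:
        cv = 0.0
    elif abs(mean) < _MEAN_GUARD:
        logger.warning("cv undefined for near-zero mean %.3g; using sentinel 0", mean)
        cv = 0.0
    else:
        cv = sd / mean
    vmin, vmax = float(x.min()), float(x.max())
    if vmax == vmin:
        entropy = 0.0
    else:
        idx = ((x - vmin) / (vmax - vmin) * entropy_bins).astype(np.int64)
        np.clip(idx, 0, entropy_bins - 1, out=idx)
        counts = np.bincount(idx, minlength=entropy_bins)
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())
    return {
        "entropy": entropy,
        "mean": mean,
        "median": median,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "iqr": iqr,
        "cv": cv,
    }


def _windowed_stats(windows: np.ndarray, entropy_bins: int) -> dict[str, np.ndarray]:
    """Vectorised seven statistics over an (n_windows, w*w) array.

    Arithmetic mirrors :func:`local_statistics` exactly so the dense maps
    equal a naive per-window recomputation.
    """
    n, wsq = windows.shape
    mean = windows.mean(axis=1)
    median = np.median(windows, axis=1)
    q1, q3 = np.quantile(windows, [0.25, 0.75], axis=1)
    iqr = q3 - q1
    d = windows - mean[:, None]
    m2 = (d**2).mean(axis=1)
    m3 = (d**3).mean(axis=1)
    m4 = (d**4).mean(axis=1)
    pos = m2 > 0
    skewness = np.zeros(n)
    kurtosis = np.zeros(n)
    np.divide(m3, m2**1.5, out=skewness, where=pos)
    np.divide(m4, m2**2, out=kurtosis, where=pos)
    kurtosis[pos] -= 3.0
    sd = np.sqrt(m2)
    cv = np.zeros(n)
    cv_ok = (sd > 0) & (np.abs(mean) >= _MEAN_GUARD)
    np.divide(sd, mean, out=cv, where=cv_ok)
    n_zero_mean = int(((sd > 0) & ~cv_ok).sum())
    if n_zero_mean:
        logger.warning("cv sentinel 0 used at %d near-zero-mean windows", n_zero_mean)
    vmin = windows.min(axis=1)
    vmax = windows.max(axis=1)
    rng = vmax - vmin
    entropy = np.zeros(n)
    spread = rng > 0
    if spread.any():
        wv = windows[spread]
        scaled = (wv - vmin[spread, None]) / rng[spread, None] * entropy_bins
        idx = scaled.astype(np.int64)
        np.clip(idx, 0, entropy_bins - 1, out=idx)
        offset = np.arange(idx.shape[0], dtype=np.int64)[:, None] * entropy_bins
        counts = np.bincount(
            (idx + offset).ravel(), minlength=idx.shape[0] * entropy_bins
        ).reshape(idx.shape[0], entropy_bins)
        p = counts / wsq
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
        entropy[spread] = -(p * logp).sum(axis=1)
    return {
        "entropy": entropy,
        "mean": mean,
        "median": median,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "iqr": iqr,
        "cv": cv,
    }


def compute_local_maps(stack: RoiImageStack, config: PipelineConfig | None = None) -> LocalMapSet:
    """Slide the square tissue unit over every slice and map the statistics.

    A window centre is valid iff the window lies fully inside the image and
    the fraction of its pixels inside the ROI mask is at least
    ``config.min_inmask_fraction``.  With ``window_stride_px > 1`` centres
    are restricted to a stride-spaced grid (stride = window size reproduces
    non-overlapping tiling).
    """
    config = config or PipelineConfig()
    w = window_size_px(config.tissue_unit_mm, stack.pixel_spacing_mm)
    half = w // 2
    stride = config.window_stride_px
    maps: dict[str, list[np.ndarray]] = {name: [] for name in STAT_NAMES}
    valid_masks: list[np.ndarray] = []
    for img, msk in zip(stack.slices, stack.masks):
        H, W = img.shape
        valid = np.zeros((H, W), dtype=bool)
        if H >= w and W >= w:
            frac = sliding_window_view(msk, (w, w)).mean(axis=(2, 3))
            ok = frac >= config.min_inmask_fraction
            # a valid centre is itself an ROI pixel (valid_mask subset of ROI)
            ok &= msk[half : H - half, half : W - half]
            grid = np.zeros_like(ok)
            grid[::stride, ::stride] = True
            ok &= grid
            valid[half : H - half, half : W - half] = ok
        for name in STAT_NAMES:
            maps[name].append(np.full((H, W), np.nan))
        if valid.any():
            centres = np.argwhere(valid)
            view = sliding_window_view(img, (w, w))
            windows = view[centres[:, 0] - half, centres[:, 1] - half].reshape(-1, w * w)
            stats = _windowed_stats(windows, config.local_entropy_bins)
            for name in STAT_NAMES:
                maps[name][-1][valid] = stats[name]
        valid_masks.append(valid)
    result = LocalMapSet(maps=maps, valid_masks=valid_masks, window_px=w)
    if result.n_valid == 0:
        raise ValueError(
            f"no valid window centre on any slice with window {w} px and "
            f"min_inmask_fraction {config.min_inmask_fraction}; use a smaller "
            "tissue unit or lower min_inmask_fraction"
        )
    return result


def export_maps(
    mapset: LocalMapSet,
    stack: RoiImageStack,
    out_dir,
    *,
    formats: tuple[str, ...] = ("nifti",),
) -> list:
    """Export each parametric map for visual inspection.

    ``"nifti"`` writes one 3D volume per statistic with NaN at invalid
    centres; ``"png"`` writes one RGBA colourmap per statistic and slice
    (blue-white-red over the map's finite range, transparent at invalid
    centres).
    """
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    sp = stack.pixel_spacing_mm
    affine = np.diag([sp, sp, stack.slice_thickness_mm, 1.0])
    for name in STAT_NAMES:
        vol = np.stack(mapset.maps[name], axis=2)
        if "nifti" in formats:
            import nibabel as nib

            path = out_dir / f"map_{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), str(path))
            written.append(path)
        if "png" in formats:
            import imageio.v3 as iio

            finite = vol[np.isfinite(vol)]
            lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
            span = hi - lo if hi > lo else 1.0
            for k in range(vol.shape[2]):
                sl = vol[:, :, k]
                t = np.clip((sl - lo) / span, 0, 1)
                rgba = np.zeros(sl.shape + (4,), dtype=np.uint8)
                # blue (low) -> white (mid) -> red (high)
                rgba[..., 0] = np.clip(2 * t, 0, 1) * 255
                rgba[..., 2] = np.clip(2 * (1 - t), 0, 1) * 255
                rgba[..., 1] = np.minimum(rgba[..., 0], rgba[..., 2])
                rgba[..., 3] = np.where(np.isfinite(sl), 255, 0)
                path = out_dir / f"map_{name}_slice{k}.png"
                iio.imwrite(path, rgba)
                written.append(path)
    return written
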
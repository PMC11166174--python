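"""Voxel-wise relative-K_H parametric mapping of a dynamic PET image.

The map is built from frame averages only, in four steps: (1) average an
early frame block (apparent maximum uptake), (2) average the late frame
block, (3) subtract late from early (total efflux volume), (4) divide by
the early average.  For a voxel washing out mono-exponentially the result
is 1 - mean_late/mean_early, a strictly increasing function of the
underlying K_H, and it is invariant to global intensity scaling.

Frame blocks are 1-based inclusive index ranges (defaults 3-10 and 11-26
on the 26-frame schedule); the early/late time labels in the literature
are approximate, the indices are operational.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinetics import FrameSchedule, TimeActivityCurve, ValidationError

__all__ = [
    "DynamicImage",
    "RelativeKHMap",
    "relative_kh_map",
    "extract_roi_tac",
    "map_region_summary",
    "DEFAULT_EARLY_FRAMES",
    "DEFAULT_LATE_FRAMES",
]

#: 1-based inclusive frame ranges for the early-uptake and late-washout blocks.
DEFAULT_EARLY_FRAMES = (3, 10)
DEFAULT_LATE_FRAMES = (11, 26)
DEFAULT_MASK_THRESHOLD = 0.2  # SUV; below this, delivery is too low to map reliably


@dataclass
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) with its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != len(self.schedule):
            raise ValidationError(
                f"image has {self.data.shape[3]} frames but schedule has {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class RelativeKHMap:
    """Relative efflux-fraction map: (early - late)/early per voxel.

    Values are NaN outside the validity mask and deliberately not clipped:
    negative values mark net late accumulation (e.g. an irreversible,
    non-hydrolyzable tracer) and are flagged rather than hidden.
    """

    values: np.ndarray
    mask: np.ndarray
    n_masked_low_uptake: int
    early_frames: tuple[int, int] = DEFAULT_EARLY_FRAMES
    late_frames: tuple[int, int] = DEFAULT_LATE_FRAMES
    affine: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.values[self.mask] < 0))


def _frame_block(img: DynamicImage, frames: tuple[int, int]) -> np.ndarray:
    lo, hi = frames
    n = len(img.schedule)
    if not (1 <= lo <= hi <= n):
        raise ValidationError(f"frame range {frames} invalid for {n}-frame schedule")
    # plain (unweighted) mean of the frame images, the literal image-algebra
    # reading of "frames are averaged"; frame durations are not re-weighted
    return img.data[..., lo - 1:hi].mean(axis=3)


def relative_kh_map(
    img: DynamicImage,
    early_frames: tuple[int, int] = DEFAULT_EARLY_FRAMES,
    late_frames: tuple[int, int] = DEFAULT_LATE_FRAMES,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    smoothing_fwhm_mm: float | None = None,
) -> RelativeKHMap:
    """Compute the relative-K_H map from a dynamic image.

    Voxels whose early average is at or below ``mask_threshold`` are
    masked out (NaN) and counted.  Optional isotropic Gaussian smoothing
    (FWHM in mm) is applied to every frame before averaging; off by
    default.
    """
    if smoothing_fwhm_mm:
        sigma_vox = [smoothing_fwhm_mm / 2.3548 / v for v in img.voxel_size_mm]
        data = np.stack(
            [gaussian_filter(img.data[..., i], sigma=sigma_vox)
             for i in range(img.data.shape[3])], axis=-1)
        img = DynamicImage(data, img.schedule, img.voxel_size_mm, img.affine)
    early = _frame_block(img, early_frames)
    late = _frame_block(img, late_frames)
    mask = early > mask_threshold
    values = np.full(early.shape, np.nan)
    np.divide(early - late, early, out=values, where=mask)
    return RelativeKHMap(values, mask, int((~mask).sum()), tuple(early_frames),
                         tuple(late_frames), img.affine)


def extract_roi_tac(img: DynamicImage, mask: np.ndarray) -> TimeActivityCurve:
    """Unweighted mean TAC over the voxels of a boolean region mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.data.shape[:3]:
        raise ValidationError("mask grid does not match the image grid")
    if not mask.any():
        raise ValidationError("region mask is empty")
    return TimeActivityCurve(img.schedule, img.data[mask].mean(axis=0))


def map_region_summary(khmap: RelativeKHMap, masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-region mean/SD of map values restricted to the validity mask.

    Regions with no valid voxel get NaN statistics and flagged=True.
    """
    rows = []
    for name, m in masks.items():
        m = np.asarray(m).astype(bool)
        if m.shape != khmap.values.shape:
            raise ValidationError(f"mask {name!r} does not match the map grid")
        valid = m & khmap.mask
        n = int(valid.sum())
        vals = khmap.values[valid]
        rows.append({
            "region": name,
            "n_voxels": int(m.sum()),
            "n_valid": n,
            "mean": float(vals.mean()) if n else np.nan,
            "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
            "flagged": n == 0,
        })
    return pd.DataFrame(rows)
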
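"""In-memory containers for dynamic PET volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FrameSchedule

__all__ = ["DynamicImage", "resample_dynamic_image"]


@dataclass
class DynamicImage:
    """A 4D activity-concentration volume (kBq/mL) plus its frame schedule.

    ``data`` has shape ``(nx, ny, nz, n_frames)``; ``spacing_mm`` is the voxel
    pitch per spatial axis.  Each voxel's last axis is its time-activity curve.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic image must be 4D, got {self.data.ndim}D")
        if self.data.shape[-1] != self.schedule.n_frames:
            raise ValueError(
                f"image has {self.data.shape[-1]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be three positive values (mm)")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def resample_dynamic_image(image: DynamicImage, to: FrameSchedule) -> DynamicImage:
    """Temporally resample every voxel TAC onto another frame schedule.

    Linear interpolation at frame mid-times with clamping outside the source
    mid-time range, applied identically to all voxels (vectorised form of the
    per-TAC resampling used for kinetic classes).
    """
    src = image.schedule.mid_times_s
    tgt = to.mid_times_s
    # precompute interpolation brackets once; reuse across all voxels
    idx = np.searchsorted(src, tgt, side="left")
    idx = np.clip(idx, 1, src.size - 1) if src.size > 1 else np.zeros_like(idx)
    if src.size == 1:
        out = np.repeat(image.data, tgt.size, axis=-1)
        return DynamicImage(out, image.spacing_mm, to)
    lo, hi = idx - 1, idx
    w = (tgt - src[lo]) / (src[hi] - src[lo])
    w = np.clip(w, 0.0, 1.0)  # clamp extrapolation
    out = image.data[..., lo] * (1.0 - w) + image.data[..., hi] * w
    return DynamicImage(out, image.spacing_mm, to)
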
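"""Kinetic classes: reference tissue TACs with per-frame standard deviations.

A kinetic class (KC) summarises the typical dose-normalised time-activity
curve of one tissue across a cohort of dynamic scans: the across-scan mean
``mu`` per frame and the across-scan sample SD ``sigma`` per frame.  The SDs
act as per-frame weights in the Mahalanobis distance used for voxel
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .image import DynamicImage
from .schedule import FrameSchedule

__all__ = [
    "KineticClass",
    "KineticClassSet",
    "mean_last_frames_image",
    "extract_tac",
    "dose_normalize",
    "derive_kinetic_classes",
    "resample_tac",
    "resample_class_set",
]


@dataclass(frozen=True)
class KineticClass:
    """Mean dose-normalised TAC (kBq/mL per MBq injected) + per-frame SD."""

    tissue: str
    mu: np.ndarray
    sigma: np.ndarray
    schedule: FrameSchedule
    n_scans: int = 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, float)
        sigma = np.asarray(self.sigma, float)
        if mu.shape != sigma.shape or mu.size != self.schedule.n_frames:
            raise ValueError(
                f"class {self.tissue!r}: mu/sigma/schedule lengths disagree "
                f"({mu.size}, {sigma.size}, {self.schedule.n_frames})"
            )
        if np.any(sigma < 0):
            raise ValueError(f"class {self.tissue!r}: sigma must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class KineticClassSet:
    """Ordered set of classes on one shared schedule.

    The order is part of the contract: classification ties are broken in
    favour of the earlier class.
    """

    classes: tuple[KineticClass, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        classes = tuple(self.classes)
        if not classes:
            raise ValueError("class set must not be empty")
        names = [c.tissue for c in classes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate tissue names in class set: {names}")
        sched = classes[0].schedule
        for c in classes[1:]:
            if c.schedule != sched:
                raise ValueError("all classes must share one frame schedule")
        object.__setattr__(self, "classes", classes)

    @property
    def schedule(self) -> FrameSchedule:
        return self.classes[0].schedule

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(c.tissue for c in self.classes)

    def __getitem__(self, tissue: str) -> KineticClass:
        for c in self.classes:
            if c.tissue == tissue:
                return c
        raise KeyError(tissue)

    def subset(self, tissues) -> "KineticClassSet":
        """Retain only the named tissues, preserving the original order."""
        keep = set(tissues)
        missing = keep - set(self.tissues)
        if missing:
            raise KeyError(f"tissues not in class set: {sorted(missing)}")
        return KineticClassSet(
            tuple(c for c in self.classes if c.tissue in keep), self.provenance
        )

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "schedule": self.schedule.to_dict(),
            "classes": [
                {
                    "tissue": c.tissue,
                    "mu": c.mu.tolist(),
                    "sigma": c.sigma.tolist(),
                    "n_scans": c.n_scans,
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticClassSet":
        sched = FrameSchedule.from_dict(d["schedule"])
        classes = tuple(
            KineticClass(
                tissue=c["tissue"],
                mu=np.asarray(c["mu"], float),
                sigma=np.asarray(c["sigma"], float),
                schedule=sched,
                n_scans=int(c.get("n_scans", 0)),
            )
            for c in d["classes"]
        )
        return cls(classes, d.get("provenance", ""))


def mean_last_frames_image(image: DynamicImage, n: int = 3) -> np.ndarray:
    """Duration-weighted mean of the last ``n`` frames, per voxel.

    This is the late-uptake summary image (45-60 min p.i. for the built-in
    protocols) used both for drawing tissue VOIs and as the input to the A50%
    threshold segmentation and SUV statistics.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > image.n_frames:
        raise ValueError(f"requested last {n} frames of a {image.n_frames}-frame image")
    w = image.schedule.durations_s[-n:]
    return (image.data[..., -n:] * w).sum(axis=-1) / w.sum()


def extract_tac(image: DynamicImage, voi: np.ndarray) -> np.ndarray:
    """Per-frame spatial mean over a volume of interest."""
    voi = np.asarray(voi, bool)
    if voi.shape != image.shape3d:
        raise ValueError(f"VOI grid {voi.shape} does not match image {image.shape3d}")
    if not voi.any():
        raise ValueError("empty VOI")
    return image.data[voi].mean(axis=0)


def dose_normalize(tac: np.ndarray, dose_mbq: float) -> np.ndarray:
    """Divide a TAC by the injected dose (MBq)."""
    if dose_mbq <= 0:
        raise ValueError("dose must be positive")
    return np.asarray(tac, float) / dose_mbq


def derive_kinetic_classes(
    scans: list[tuple[DynamicImage, dict[str, np.ndarray], float]],
    provenance: str = "",
) -> KineticClassSet:
    """Derive a kinetic-class set from a cohort of scans with tissue VOIs.

    Each scan contributes one dose-normalised mean TAC per tissue; per tissue,
    ``mu`` is the across-scan mean and ``sigma`` the across-scan sample SD
    (n-1 denominator) at each frame.

    Parameters
    ----------
    scans
        List of ``(image, {tissue: voi mask}, injected dose MBq)`` tuples,
        all on one frame schedule, each with a VOI for every tissue.
    """
    if len(scans) < 2:
        raise ValueError("need at least two scans to derive classes")
    sched = scans[0][0].schedule
    tissues = list(scans[0][1].keys())
    per_tissue: dict[str, list[np.ndarray]] = {t: [] for t in tissues}
    for image, vois, dose in scans:
        if image.schedule != sched:
            raise ValueError("all scans must share one frame schedule")
        missing = set(tissues) - set(vois)
        extra = set(vois) - set(tissues)
        if missing or extra:
            raise ValueError(
                f"tissue VOIs inconsistent across scans (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        for t in tissues:
            per_tissue[t].append(dose_normalize(extract_tac(image, vois[t]), dose))
    classes = []
    for t in tissues:
        stack = np.vstack(per_tissue[t])
        classes.append(
            KineticClass(
                tissue=t,
                mu=stack.mean(axis=0),
                sigma=stack.std(axis=0, ddof=1),
                schedule=sched,
                n_scans=len(scans),
            )
        )
    return KineticClassSet(tuple(classes), provenance)


def resample_tac(
    values: np.ndarray, frm: FrameSchedule, to: FrameSchedule
) -> np.ndarray:
    """Resample a TAC onto another schedule.

    Linear interpolation of (mid-time, value) pairs at the target mid-times;
    target mid-times outside the source range take the nearest source value
    (clamped extrapolation).  Identical schedules return the input exactly.
    """
    values = np.asarray(values, float)
    if values.size != frm.n_frames:
        raise ValueError(f"TAC length {values.size} != schedule frames {frm.n_frames}")
    if to == frm:
        return values.copy()
    return np.interp(to.mid_times_s, frm.mid_times_s, values)


def resample_class_set(kcs: KineticClassSet, to: FrameSchedule) -> KineticClassSet:
    """Resample every class (mean and SD) onto a target schedule."""
    if to == kcs.schedule:
        return kcs
    return KineticClassSet(
        tuple(
            replace(
                c,
                mu=resample_tac(c.mu, kcs.schedule, to),
                sigma=resample_tac(c.sigma, kcs.schedule, to),
                schedule=to,
            )
            for c in kcs.classes
        ),
        kcs.provenance,
    )
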
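"""Kinetic-filtering segmentation: supervised voxel classification.

Every voxel of a dynamic scan is assigned to the kinetic class whose mean
TAC it is closest to in Mahalanobis distance,

    D_M = sqrt( sum_t ((p_t - mu_t) / sigma_t)^2 )

where p_t is the voxel activity at frame t and (mu_t, sigma_t) the class mean
and SD at that frame.  The per-frame SDs act as weights: frames where a class
is well determined contribute more.  Nine named preset variants (KF1-KF9)
bundle the practical adaptations needed to make the classifier work across
acquisition protocols: temporal smoothing, resampling direction, restricted
time windows, reduced class sets and reclassification rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np

from .image import DynamicImage, resample_dynamic_image
from .kinetic_classes import KineticClass, KineticClassSet, resample_class_set
from .schedule import FrameSchedule

__all__ = [
    "KFConfig",
    "LabelImage",
    "KFSegmentationResult",
    "load_presets",
    "get_preset",
    "mahalanobis_distance",
    "temporal_smooth",
    "restrict_time_window",
    "classify_voxels",
    "reclassify_within_mask",
    "segment_lesion_kf",
    "run_kf_preset",
]


@dataclass(frozen=True)
class KFConfig:
    """Settings of one kinetic-filtering variant.

    ``reclass_global`` relabels classified voxels everywhere (the original
    algorithm maps vertebrae to tumour because the two are kinetically
    indistinguishable); ``reclass_in_mask`` relabels only inside lesion masks,
    where liver or vertebrae labels are anatomically impossible.
    """

    name: str = "custom"
    kc_source: str = "hammersmith"
    temporal_smoothing: bool = False
    resample_direction: Literal["classes_to_scan", "scan_to_classes"] = "classes_to_scan"
    sigma_scale: float = 1.0
    time_window_min: tuple[float, float] | None = None
    class_subset: tuple[str, ...] | None = None
    omit_classes: tuple[str, ...] = ()
    reclass_global: Mapping[str, str] = field(default_factory=dict)
    reclass_in_mask: Mapping[str, str] = field(default_factory=dict)
    min_detect_voxels: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")
        if self.min_detect_voxels < 1:
            raise ValueError("min_detect_voxels must be at least 1")
        if self.time_window_min is not None:
            t0, t1 = self.time_window_min
            if not t0 < t1:
                raise ValueError("time window must have t0 < t1")

    def effective_tissues(self, kcs: KineticClassSet) -> tuple[str, ...]:
        if self.class_subset is not None:
            tissues = tuple(t for t in kcs.tissues if t in set(self.class_subset))
        else:
            tissues = tuple(t for t in kcs.tissues if t not in set(self.omit_classes))
        if not tissues:
            raise ValueError("class subset is empty")
        return tissues


def load_presets() -> dict[str, KFConfig]:
    """The shipped KF1-KF9 variant table (editable JSON resource)."""
    text = resources.files("fltseg").joinpath("data/kf_presets.json").read_text()
    raw = json.loads(text)
    presets = {}
    for name, cfg in raw.items():
        presets[name] = KFConfig(
            name=name,
            kc_source=cfg.get("kc_source", "hammersmith"),
            temporal_smoothing=cfg.get("temporal_smoothing", False),
            resample_direction=cfg.get("resample_direction", "classes_to_scan"),
            time_window_min=(
                tuple(cfg["time_window_min"]) if "time_window_min" in cfg else None
            ),
            omit_classes=tuple(cfg.get("omit_classes", ())),
            reclass_global=dict(cfg.get("reclass_global", {})),
            reclass_in_mask=dict(cfg.get("reclass_in_mask", {})),
            description=cfg.get("description", ""),
        )
    return presets


def get_preset(name: str) -> KFConfig:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown KF preset {name!r}; available: {sorted(presets)}"
        ) from None


@dataclass
class LabelImage:
    """3D integer classification with a label -> tissue-name table."""

    labels: np.ndarray
    table: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label image must be 3D")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.table):
            raise ValueError(f"labels {present - set(self.table)} missing from table")

    @property
    def name_to_index(self) -> dict[str, int]:
        return {n: i for i, n in self.table.items()}

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == self.name_to_index[tissue]

    def composition(self, within: np.ndarray | None = None) -> dict[str, int]:
        """Voxel count per tissue name, optionally restricted to a mask."""
        lab = self.labels if within is None else self.labels[np.asarray(within, bool)]
        counts = np.bincount(lab.ravel(), minlength=max(self.table) + 1)
        return {name: int(counts[i]) for i, name in self.table.items() if counts[i]}


@dataclass
class KFSegmentationResult:
    """Per-lesion outcome of a KF segmentation."""

    lesion_id: str
    voi: np.ndarray
    detected: bool
    n_voxels: int
    volume_cm3: float | None
    composition: dict[str, int]
    config_name: str


def mahalanobis_distance(
    p: np.ndarray,
    kc: KineticClass,
    sigma_scale: float = 1.0,
    frame_indices: np.ndarray | None = None,
) -> float:
    """Mahalanobis distance between one voxel TAC and one kinetic class.

    Restricting ``frame_indices`` implements time-window classification; all
    of ``p``, ``mu`` and ``sigma`` are subset identically.
    """
    p = np.asarray(p, float)
    if p.size != kc.mu.size:
        raise ValueError(f"TAC length {p.size} != class length {kc.mu.size}")
    sl = slice(None) if frame_indices is None else frame_indices
    mu, sigma = kc.mu[sl], sigma_scale * kc.sigma[sl]
    if np.any(sigma == 0):
        raise ValueError(
            f"class {kc.tissue!r} has zero SD in a frame in scope (degenerate class)"
        )
    return float(np.sqrt(np.sum(((p[sl] - mu) / sigma) ** 2)))


def temporal_smooth(image: DynamicImage) -> DynamicImage:
    """Average every frame with its previous and next frames.

    Edge frames average the two existing frames; a single-frame image is
    returned unchanged.
    """
    n = image.n_frames
    if n == 1:
        return DynamicImage(image.data.copy(), image.spacing_mm, image.schedule)
    d = image.data
    out = np.empty_like(d)
    out[..., 0] = (d[..., 0] + d[..., 1]) / 2.0
    out[..., -1] = (d[..., -2] + d[..., -1]) / 2.0
    if n > 2:
        out[..., 1:-1] = (d[..., :-2] + d[..., 1:-1] + d[..., 2:]) / 3.0
    return DynamicImage(out, image.spacing_mm, image.schedule)


def restrict_time_window(
    schedule: FrameSchedule, window_min: tuple[float, float]
) -> np.ndarray:
    """Indices of frames whose mid-times fall inside ``[t0, t1]`` minutes."""
    t0, t1 = window_min
    if not t0 < t1:
        raise ValueError("time window must have t0 < t1")
    mid = schedule.mid_times_min
    idx = np.flatnonzero((mid >= t0) & (mid <= t1))
    if idx.size == 0:
        raise ValueError(f"no frame mid-times inside window {window_min} min")
    return idx


def classify_voxels(
    image: DynamicImage,
    kcs: KineticClassSet,
    config: KFConfig,
    dose_mbq: float | None = None,
) -> LabelImage:
    """Assign every voxel to its nearest kinetic class.

    Kinetic classes are dose-normalised, so the scan must be too: pass the
    injected dose in ``dose_mbq`` to normalise here, or pass ``None`` if the
    image is already in dose-normalised units.

    Pipeline: resample (classes onto the scan schedule, or the scan onto the
    class schedule, per ``config.resample_direction``), restrict the class
    subset and time window, compute per-class Mahalanobis distances, take the
    per-voxel argmin (ties go to the earlier class in the set order), then
    apply the global reclassification map.
    """
    if dose_mbq is not None:
        if dose_mbq <= 0:
            raise ValueError("dose must be positive")
        image = DynamicImage(image.data / dose_mbq, image.spacing_mm, image.schedule)
    if config.resample_direction == "classes_to_scan":
        kcs = resample_class_set(kcs, image.schedule)
    elif config.resample_direction == "scan_to_classes":
        image = resample_dynamic_image(image, kcs.schedule)
    else:
        raise ValueError(f"unknown resample direction {config.resample_direction!r}")
    if image.schedule != kcs.schedule:
        raise ValueError("image and class schedules disagree after resampling")

    tissues = config.effective_tissues(kcs)
    kcs = kcs.subset(tissues)
    idx = (
        restrict_time_window(image.schedule, config.time_window_min)
        if config.time_window_min is not None
        else np.arange(image.n_frames)
    )
    flat = image.data.reshape(-1, image.n_frames)[:, idx]
    d2 = np.empty((flat.shape[0], len(kcs.classes)))
    for j, c in enumerate(kcs.classes):
        sigma = config.sigma_scale * c.sigma[idx]
        if np.any(sigma == 0):
            raise ValueError(
                f"class {c.tissue!r} has zero SD in a frame in scope (degenerate class)"
            )
        d2[:, j] = (((flat - c.mu[idx]) / sigma) ** 2).sum(axis=1)
    labels = d2.argmin(axis=1).astype(np.int16).reshape(image.shape3d)
    table = dict(enumerate(kcs.tissues))
    result = LabelImage(labels, table)
    if config.reclass_global:
        result = _apply_reclass(result, config.reclass_global, mask=None)
    return result


def _apply_reclass(
    labels: LabelImage, mapping: Mapping[str, str], mask: np.ndarray | None
) -> LabelImage:
    n2i = labels.name_to_index
    out = labels.labels.copy()
    for src, dst in mapping.items():
        if src not in n2i:
            continue  # source class absent (e.g. omitted); nothing to relabel
        if dst not in n2i:
            raise KeyError(f"reclassification target {dst!r} not in label table")
        hit = labels.labels == n2i[src]
        if mask is not None:
            hit &= mask
        out[hit] = n2i[dst]
    return LabelImage(out, dict(labels.table))


def reclassify_within_mask(
    labels: LabelImage, lesion_mask: np.ndarray, mapping: Mapping[str, str]
) -> LabelImage:
    """Apply a class -> class map only where ``lesion_mask`` is true."""
    lesion_mask = np.asarray(lesion_mask, bool)
    if lesion_mask.shape != labels.labels.shape:
        raise ValueError("lesion mask grid does not match label image")
    if not mapping:
        return LabelImage(labels.labels.copy(), dict(labels.table))
    return _apply_reclass(labels, mapping, lesion_mask)


def segment_lesion_kf(
    labels: LabelImage,
    lesion_mask: np.ndarray,
    config: KFConfig,
    spacing_mm: tuple[float, float, float] | None = None,
    lesion_id: str = "",
) -> KFSegmentationResult:
    """Extract the tumour VOI inside one lesion mask.

    In-mask reclassification (``config.reclass_in_mask``) is applied first;
    the VOI is then every tumour-labelled voxel inside the mask, and the
    lesion counts as detected when the VOI reaches ``min_detect_voxels``.
    """
    lesion_mask = np.asarray(lesion_mask, bool)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    relabelled = reclassify_within_mask(labels, lesion_mask, config.reclass_in_mask)
    voi = relabelled.mask("tumour") & lesion_mask
    n = int(voi.sum())
    volume = None
    if spacing_mm is not None:
        volume = n * float(np.prod(spacing_mm)) / 1000.0
    return KFSegmentationResult(
        lesion_id=lesion_id,
        voi=voi,
        detected=n >= config.min_detect_voxels,
        n_voxels=n,
        volume_cm3=volume,
        composition=relabelled.composition(within=lesion_mask),
        config_name=config.name,
    )


def run_kf_preset(
    image: DynamicImage,
    kcs_by_source: Mapping[str, KineticClassSet],
    lesion_masks: Mapping[str, np.ndarray],
    preset: str | KFConfig,
    dose_mbq: float | None = None,
) -> dict[str, KFSegmentationResult]:
    """Run one KF variant end to end on a dynamic scan.

    ``kcs_by_source`` maps class-set names (e.g. ``hammersmith``, ``vumc``)
    to the available sets; the preset selects one.  ``dose_mbq`` normalises
    the scan into the classes' dose-normalised units.  Returns one
    segmentation result per lesion mask.
    """
    config = get_preset(preset) if isinstance(preset, str) else preset
    if config.kc_source not in kcs_by_source:
        raise KeyError(
            f"preset {config.name} needs class source {config.kc_source!r}; "
            f"available: {sorted(kcs_by_source)}"
        )
    img = temporal_smooth(image) if config.temporal_smoothing else image
    labels = classify_voxels(img, kcs_by_source[config.kc_source], config, dose_mbq)
    return {
        lid: segment_lesion_kf(labels, m, config, image.spacing_mm, lesion_id=lid)
        for lid, m in lesion_masks.items()
    }
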
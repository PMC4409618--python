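"""4D digital phantom for dynamic FLT PET.

Generates synthetic dynamic scans with known tissue labels, lesion masks and
ground-truth time-activity curves (TACs), so that classification, segmentation
and repeatability statistics can all be validated against a known truth.

The tissue kinetics follow the qualitative behaviour of FLT: tumour and
vertebral bone marrow accumulate tracer irreversibly (monotone rising TACs),
the liver shows even higher uptake but reversible kinetics (peak then
decline, driven by FLT-glucuronide metabolism), the heart shows an early
vascular peak, and lung and soft tissue stay low and flat.  Amplitudes are
free parameters of the phantom, not calibrated to any particular scanner.

Frame noise is zero-mean Gaussian with a standard deviation proportional to
``sqrt(amplitude) / sqrt(frame duration)``, mimicking the count-statistics
behaviour of reconstructed PET (short early frames are noisy, long late
frames are smooth).  Reconstruction artefacts (e.g. FBP streaks) are not
simulated; the classifier is intended for OSEM-like, artefact-free noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .image import DynamicImage
from .schedule import FrameSchedule, builtin_schedules

__all__ = [
    "TISSUE_ORDER",
    "TissueModel",
    "Shape",
    "PhantomSpec",
    "PhantomOutput",
    "evaluate_tissue_tac",
    "generate_phantom",
    "generate_trt_pair",
    "default_tissue_models",
    "default_phantom_spec",
    "true_class_set",
]

#: canonical tissue order; also the classification tie-break order
TISSUE_ORDER = ("lung", "soft_tissue", "heart", "liver", "vertebrae", "tumour")

TacShape = Literal["flat", "accumulating", "reversible", "vascular"]


@dataclass(frozen=True)
class TissueModel:
    """Parametric TAC family for one tissue.

    ``amplitude_kbq_ml`` scales the curve; rate parameters are per minute.

    * ``flat`` — constant (lung, soft tissue).
    * ``accumulating`` — saturating monotone rise ``A·kt/(1+kt)``
      (tumour, vertebrae: irreversible kinetics).
    * ``reversible`` — normalised bi-exponential ``exp(-k_out·t) − exp(-k_in·t)``
      peaking then declining (liver).
    * ``vascular`` — gamma-variate bolus peak relaxing to a plateau (heart).
    """

    name: str
    tac_shape: TacShape
    amplitude_kbq_ml: float
    uptake_rate_per_min: float = 0.3
    peak_time_min: float = 1.0
    washout_rate_per_min: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude_kbq_ml < 0:
            raise ValueError("amplitude must be non-negative")
        if self.tac_shape == "reversible" and not (
            self.uptake_rate_per_min > self.washout_rate_per_min > 0
        ):
            raise ValueError("reversible kinetics need uptake rate > washout rate > 0")

    def curve(self, t_min: np.ndarray) -> np.ndarray:
        """Evaluate the noiseless TAC at times ``t_min`` (minutes p.i.)."""
        t = np.asarray(t_min, dtype=float)
        a = self.amplitude_kbq_ml
        if self.tac_shape == "flat":
            return np.full_like(t, a)
        if self.tac_shape == "accumulating":
            kt = self.uptake_rate_per_min * t
            return a * kt / (1.0 + kt)
        if self.tac_shape == "reversible":
            k_in = self.uptake_rate_per_min
            k_out = self.washout_rate_per_min
            raw = np.exp(-k_out * t) - np.exp(-k_in * t)
            t_peak = math.log(k_in / k_out) / (k_in - k_out)
            peak = math.exp(-k_out * t_peak) - math.exp(-k_in * t_peak)
            return a * raw / peak
        if self.tac_shape == "vascular":
            tp = self.peak_time_min
            bolus = (t / tp) * np.exp(1.0 - t / tp)
            kt = self.uptake_rate_per_min * t
            plateau = kt / (1.0 + kt)
            return a * (0.65 * bolus + 0.35 * plateau)
        raise ValueError(f"unknown TAC shape {self.tac_shape!r}")

    @property
    def peak_time(self) -> float:
        """Time (min) of the noiseless curve's maximum, where defined."""
        if self.tac_shape == "reversible":
            k_in = self.uptake_rate_per_min
            k_out = self.washout_rate_per_min
            return math.log(k_in / k_out) / (k_in - k_out)
        return self.peak_time_min


@dataclass(frozen=True)
class Shape:
    """A placed geometry: ``sphere`` (size = radius), ``box`` (size =
    half-extents) or ``ellipsoid`` (size = semi-axes), all in mm."""

    kind: Literal["sphere", "box", "ellipsoid"]
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def mask(self, grid_shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
        coords = np.meshgrid(
            *[(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)],
            indexing="ij",
        )
        d = [c - c0 for c, c0 in zip(coords, self.center_mm)]
        if self.kind == "sphere":
            r = self.size_mm[0]
            return d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= r**2
        if self.kind == "box":
            return (
                (np.abs(d[0]) <= self.size_mm[0])
                & (np.abs(d[1]) <= self.size_mm[1])
                & (np.abs(d[2]) <= self.size_mm[2])
            )
        if self.kind == "ellipsoid":
            return (
                (d[0] / self.size_mm[0]) ** 2
                + (d[1] / self.size_mm[1]) ** 2
                + (d[2] / self.size_mm[2]) ** 2
            ) <= 1.0
        raise ValueError(f"unknown shape kind {self.kind!r}")


def default_tissue_models() -> dict[str, TissueModel]:
    """Reference tissue set; amplitudes in kBq/mL at a nominal injected dose."""
    return {
        "lung": TissueModel("lung", "flat", 0.4),
        "soft_tissue": TissueModel("soft_tissue", "flat", 1.2),
        "heart": TissueModel("heart", "vascular", 3.5, uptake_rate_per_min=0.15,
                             peak_time_min=0.75),
        "liver": TissueModel("liver", "reversible", 9.0, uptake_rate_per_min=0.8,
                             washout_rate_per_min=0.02),
        "vertebrae": TissueModel("vertebrae", "accumulating", 7.0,
                                 uptake_rate_per_min=0.25),
        "tumour": TissueModel("tumour", "accumulating", 6.0,
                              uptake_rate_per_min=0.35),
    }


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom realisation."""

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    schedule: FrameSchedule
    tissues: dict[str, TissueModel]
    organs: list[tuple[str, Shape]]  # (tissue name, geometry); background fills the rest
    lesions: list[tuple[str, Shape]]  # (lesion id, geometry); tissue is tumour
    noise_level: float = 0.5
    dose_mbq: float = 364.0
    weight_kg: float = 75.0
    seed: int = 0
    rim_voxels: int = 2
    background_tissue: str = "lung"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")
        if self.rim_voxels < 0:
            raise ValueError("rim must be non-negative")


@dataclass
class PhantomOutput:
    """One generated phantom: image plus ground truth."""

    image: DynamicImage
    truth_labels: np.ndarray  # 3D int, indices into label_table order
    label_table: dict[int, str]
    lesion_masks: dict[str, np.ndarray]
    true_lesion_masks: dict[str, np.ndarray]
    true_tacs: dict[str, np.ndarray]  # per tissue, noiseless, kBq/mL
    spec: PhantomSpec


def evaluate_tissue_tac(model: TissueModel, schedule: FrameSchedule) -> np.ndarray:
    """Noiseless per-frame TAC: the curve point-evaluated at frame mid-times."""
    return model.curve(schedule.mid_times_min)


def _paint_labels(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, str], dict[str, np.ndarray]]:
    tissue_names = [t for t in TISSUE_ORDER if t in spec.tissues]
    for extra in spec.tissues:
        if extra not in tissue_names:
            tissue_names.append(extra)
    if spec.background_tissue not in tissue_names:
        raise ValueError(f"background tissue {spec.background_tissue!r} has no model")
    name_to_idx = {n: i for i, n in enumerate(tissue_names)}
    labels = np.full(spec.grid_shape, name_to_idx[spec.background_tissue], dtype=np.int16)
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    lesion_masks: dict[str, np.ndarray] = {}
    placements = [(name, shape, None) for name, shape in spec.organs] + [
        ("tumour", shape, lid) for lid, shape in spec.lesions
    ]
    for tissue, shape, lesion_id in placements:
        if tissue not in name_to_idx:
            raise ValueError(f"no tissue model for {tissue!r}")
        m = shape.mask(spec.grid_shape, spec.spacing_mm)
        if not m.any():
            raise ValueError(f"geometry for {lesion_id or tissue} covers no voxels")
        if (m & occupied).any():
            what = f"lesion {lesion_id}" if lesion_id else tissue
            raise ValueError(f"{what} overlaps a previously placed geometry")
        labels[m] = name_to_idx[tissue]
        occupied |= m
        if lesion_id is not None:
            lesion_masks[lesion_id] = m
    return labels, {i: n for n, i in name_to_idx.items()}, lesion_masks


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomOutput:
    """Generate one noisy phantom realisation.

    Every voxel's TAC is its tissue's noiseless TAC plus independent Gaussian
    noise with per-frame SD ``noise_level · sqrt(amplitude) / sqrt(duration_min)``.
    Lesion masks are the true lesions dilated by ``rim_voxels`` (the "tumour
    plus rim" regions an observer would draw around each lesion).
    """
    labels, label_table, true_lesions = _paint_labels(spec)
    sched = spec.schedule
    tacs = {name: evaluate_tissue_tac(m, sched) for name, m in spec.tissues.items()}

    data = np.empty(spec.grid_shape + (sched.n_frames,), dtype=float)
    noise_sd = np.empty_like(data)
    dur_min = sched.durations_s / 60.0
    for idx, name in label_table.items():
        m = labels == idx
        data[m] = tacs[name]
        noise_sd[m] = spec.noise_level * math.sqrt(spec.tissues[name].amplitude_kbq_ml)
    noise_sd /= np.sqrt(dur_min)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.noise_level > 0:
        data = data + rng.normal(0.0, 1.0, size=data.shape) * noise_sd

    masks = {
        lid: (
            ndimage.binary_dilation(m, iterations=spec.rim_voxels)
            if spec.rim_voxels > 0
            else m.copy()
        )
        for lid, m in true_lesions.items()
    }
    image = DynamicImage(data, spec.spacing_mm, sched)
    return PhantomOutput(image, labels, label_table, masks, true_lesions, tacs, spec)


def generate_trt_pair(
    spec: PhantomSpec, seeds: tuple[int, int]
) -> tuple[PhantomOutput, PhantomOutput]:
    """Paired test/retest realisations: identical anatomy and true kinetics,
    independent noise (the phantom analogue of two scans within a week)."""
    if seeds[0] == seeds[1]:
        raise ValueError("test and retest seeds must differ")
    return generate_phantom(spec, seed=seeds[0]), generate_phantom(spec, seed=seeds[1])


def default_phantom_spec(
    schedule: FrameSchedule | None = None,
    grid_shape: tuple[int, int, int] = (40, 40, 20),
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
    noise_level: float = 0.5,
    seed: int = 0,
) -> PhantomSpec:
    """A thorax-like layout: two tumour lesions in lung background, with
    heart, liver, vertebral column and a chest-wall soft-tissue slab."""
    if schedule is None:
        schedule = builtin_schedules()["vumc_trt_39"]
    organs = [
        ("heart", Shape("sphere", (50.0, 80.0, 40.0), (18.0, 18.0, 18.0))),
        ("liver", Shape("sphere", (110.0, 80.0, 40.0), (20.0, 20.0, 20.0))),
        ("vertebrae", Shape("box", (80.0, 130.0, 40.0), (8.0, 10.0, 38.0))),
        ("soft_tissue", Shape("box", (80.0, 18.0, 40.0), (60.0, 8.0, 38.0))),
    ]
    lesions = [
        ("lesion_a", Shape("sphere", (40.0, 44.0, 40.0), (11.0, 11.0, 11.0))),
        ("lesion_b", Shape("sphere", (120.0, 44.0, 40.0), (7.0, 7.0, 7.0))),
    ]
    return PhantomSpec(
        grid_shape=grid_shape,
        spacing_mm=spacing_mm,
        schedule=schedule,
        tissues=default_tissue_models(),
        organs=organs,
        lesions=lesions,
        noise_level=noise_level,
        seed=seed,
    )


def true_class_set(spec: PhantomSpec, sigma_frac: float = 0.1):
    """Kinetic classes matched to the phantom's true kinetics.

    Class means are the dose-normalised true tissue TACs; per-frame SDs are
    ``sigma_frac`` of the class mean with a floor at ``sigma_frac`` times the
    time-averaged mean, so no frame is degenerate.  Stands in for classes a
    site would derive from its own scan cohort.
    """
    from .kinetic_classes import KineticClass, KineticClassSet

    classes = []
    for name in TISSUE_ORDER:
        if name not in spec.tissues:
            continue
        mu = evaluate_tissue_tac(spec.tissues[name], spec.schedule) / spec.dose_mbq
        sigma = np.maximum(sigma_frac * mu, sigma_frac * mu.mean())
        classes.append(
            KineticClass(tissue=name, mu=mu, sigma=sigma, schedule=spec.schedule, n_scans=1)
        )
    return KineticClassSet(classes=classes, provenance="phantom_truth")
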
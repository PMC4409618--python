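"""End-to-end test-retest comparison pipeline.

Runs one KF preset and the A50% method on a test and a retest dynamic scan,
collects per-lesion volume and SUV statistics for both methods, and writes
the repeatability tables plus a machine-readable run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .a50 import A50Params, a50_segment
from .image import DynamicImage
from .io import (
    read_class_set,
    read_dynamic_image,
    read_label_image,
    write_label_image,
)
from .kf import KFConfig, classify_voxels, get_preset, run_kf_preset, temporal_smooth
from .kinetic_classes import KineticClassSet, mean_last_frames_image
from .metrics import LesionStats, compare_methods, suv_stats, volume_cm3

__all__ = ["ScanInputs", "StudyManifest", "analyse_scan", "run_pipeline", "mask_centroid_mm"]


@dataclass
class ScanInputs:
    """One dynamic scan plus the per-lesion masks and patient data."""

    image: DynamicImage
    lesion_masks: dict[str, np.ndarray]
    dose_mbq: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.weight_kg <= 0:
            raise ValueError("body weight must be positive")
        for lid, m in self.lesion_masks.items():
            if np.asarray(m).shape != self.image.shape3d:
                raise ValueError(f"lesion mask {lid!r} grid does not match the image")


@dataclass
class StudyManifest:
    """File-level description of a TRT study (parsed from JSON).

    Schema::

        {
          "kc_sets": {"hammersmith": "kc_h.json", "vumc": "kc_v.json"},
          "test":   {"image": "...nii.gz", "schedule": "...json" (optional),
                     "lesion_masks": "...nii.gz",
                     "lesion_labels": {"1": "lesion_a", ...},
                     "dose_mbq": 364.0, "weight_kg": 75.0},
          "retest": { ... same keys ... }
        }
    """

    kc_sets: dict[str, str]
    test: dict
    retest: dict
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        path = Path(path)
        d = json.loads(path.read_text())
        m = cls(
            kc_sets=d.get("kc_sets", {}),
            test=d.get("test", {}),
            retest=d.get("retest", {}),
            base_dir=path.parent,
        )
        m.validate()
        return m

    def validate(self) -> None:
        if not self.kc_sets:
            raise ValueError("manifest: no kinetic-class sets listed")
        for role, entry in (("test", self.test), ("retest", self.retest)):
            for key in ("image", "lesion_masks", "lesion_labels", "dose_mbq", "weight_kg"):
                if key not in entry:
                    raise ValueError(f"manifest: {role} entry is missing {key!r}")
            if not (isinstance(entry["dose_mbq"], (int, float)) and entry["dose_mbq"] > 0):
                raise ValueError(f"manifest: {role} dose must be a positive number")
            if not (isinstance(entry["weight_kg"], (int, float)) and entry["weight_kg"] > 0):
                raise ValueError(f"manifest: {role} weight must be a positive number")
        for p in self._paths():
            if not p.exists():
                raise FileNotFoundError(f"manifest references a missing file: {p}")

    def _paths(self):
        for rel in self.kc_sets.values():
            yield self.base_dir / rel
        for entry in (self.test, self.retest):
            yield self.base_dir / entry["image"]
            yield self.base_dir / entry["lesion_masks"]

    def load_kc_sets(self) -> dict[str, KineticClassSet]:
        return {name: read_class_set(self.base_dir / p) for name, p in self.kc_sets.items()}

    def load_scan(self, role: str) -> ScanInputs:
        entry = {"test": self.test, "retest": self.retest}[role]
        image = read_dynamic_image(
            self.base_dir / entry["image"],
            self.base_dir / entry["schedule"] if "schedule" in entry else None,
        )
        table = {int(k): v for k, v in entry["lesion_labels"].items()}
        masks = read_label_image(
            self.base_dir / entry["lesion_masks"], table, expected_grid=image.shape3d
        )
        return ScanInputs(image, masks, float(entry["dose_mbq"]), float(entry["weight_kg"]))


def mask_centroid_mm(mask: np.ndarray, spacing_mm) -> tuple[float, float, float]:
    """Centre of mass of a mask in the voxel-centre mm frame (A50% seed)."""
    idx = np.argwhere(np.asarray(mask, bool))
    if idx.size == 0:
        raise ValueError("empty mask has no centroid")
    c = idx.mean(axis=0)
    return tuple(float((ci + 0.5) * s) for ci, s in zip(c, spacing_mm))


def analyse_scan(
    scan: ScanInputs,
    kcs_by_source: dict[str, KineticClassSet],
    kf_preset: str | KFConfig,
    a50_params: A50Params = A50Params(),
) -> tuple[dict[str, list[LesionStats]], dict]:
    """Run the KF preset and A50% on one scan; per-method lesion stats.

    SUV statistics for both methods are computed on the duration-weighted
    mean of the last three frames (the 45-60 min p.i. uptake image).
    """
    late = mean_last_frames_image(scan.image, 3)
    spacing = scan.image.spacing_mm
    config = get_preset(kf_preset) if isinstance(kf_preset, str) else kf_preset

    kf_results = run_kf_preset(
        scan.image, kcs_by_source, scan.lesion_masks, config, dose_mbq=scan.dose_mbq
    )
    kf_stats, a50_stats = [], []
    extras: dict = {"kf": {}, "a50": {}}
    for lid, mask in scan.lesion_masks.items():
        r = kf_results[lid]
        if r.detected:
            sm, sx = suv_stats(late, r.voi, scan.dose_mbq, scan.weight_kg)
        else:
            sm = sx = float("nan")
        kf_stats.append(
            LesionStats(lid, f"KF:{config.name}", volume_cm3(r.voi, spacing), sm, sx, r.detected)
        )
        extras["kf"][lid] = {"n_voxels": r.n_voxels, "composition": r.composition}

        seed = mask_centroid_mm(mask, spacing)
        a = a50_segment(late, seed, spacing, a50_params, bounding_mask=mask)
        if a.detected and a.voi.any():
            sm, sx = suv_stats(late, a.voi, scan.dose_mbq, scan.weight_kg)
        else:
            sm = sx = float("nan")
        a50_stats.append(
            LesionStats(lid, "A50", a.volume_cm3, sm, sx, a.detected and bool(a.voi.any()))
        )
        extras["a50"][lid] = {
            "max": a.max_value,
            "background": a.background,
            "threshold": a.threshold,
            "leaked": a.leaked,
        }
    return {f"KF:{config.name}": kf_stats, "A50": a50_stats}, extras


def run_pipeline(
    manifest: StudyManifest,
    kf_preset: str | KFConfig = "KF1",
    a50_params: A50Params = A50Params(),
    out_dir: str | Path = "fltseg_out",
) -> dict:
    """Full TRT comparison: both scans, both methods, tables on disk.

    Writes per-lesion stats, TRT rows/summary/detection CSVs, the KF label
    image of each scan, and ``run_log.json`` recording every setting needed
    to reproduce the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = get_preset(kf_preset) if isinstance(kf_preset, str) else kf_preset
    kcs = manifest.load_kc_sets()
    if config.kc_source not in kcs:
        raise ValueError(
            f"pipeline: preset {config.name} needs KC source {config.kc_source!r}, "
            f"manifest provides {sorted(kcs)}"
        )

    per_role: dict[str, dict[str, list[LesionStats]]] = {}
    for role in ("test", "retest"):
        scan = manifest.load_scan(role)
        stats, extras = analyse_scan(scan, kcs, config, a50_params)
        per_role[role] = stats
        img = temporal_smooth(scan.image) if config.temporal_smoothing else scan.image
        labels = classify_voxels(img, kcs[config.kc_source], config, scan.dose_mbq)
        write_label_image(
            labels.labels, labels.table, out_dir / f"{role}_kf_labels.nii.gz",
            scan.image.spacing_mm,
        )
        rows = [asdict(s) for group in stats.values() for s in group]
        pd.DataFrame(rows).to_csv(out_dir / f"{role}_lesion_stats.csv", index=False)
        (out_dir / f"{role}_diagnostics.json").write_text(json.dumps(extras, indent=2))

    rows_df, summary, detection = compare_methods(per_role["test"], per_role["retest"])
    rows_df.to_csv(out_dir / "trt_rows.csv", index=False)
    summary.to_csv(out_dir / "trt_summary.csv", index=False)
    detection.to_csv(out_dir / "detection.csv", index=False)

    log = {
        "fltseg_version": __version__,
        "kf_config": {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, dict) else v)
            for k, v in asdict(config).items()
        },
        "a50_params": asdict(a50_params),
        "kc_sets": {k: str(manifest.base_dir / v) for k, v in manifest.kc_sets.items()},
        "inputs": {
            "test": {k: str(v) if isinstance(v, (str, Path)) else v for k, v in manifest.test.items()},
            "retest": {k: str(v) if isinstance(v, (str, Path)) else v for k, v in manifest.retest.items()},
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"rows": rows_df, "summary": summary, "detection": detection, "out_dir": out_dir}
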
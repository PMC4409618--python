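"""File I/O: NIfTI images, JSON schedules and class sets, CSV tables.

Conventions
-----------
* Images are NIfTI (.nii / .nii.gz); the affine is diagonal with the voxel
  spacing, and physical seed coordinates are in that voxel-centre mm frame.
* Frame schedules travel in JSON sidecars (keys ``starts_s``, ``durations_s``)
  rather than NIfTI timing headers, which are unreliable across tools.
* Readers validate rather than coerce: frame/schedule count mismatches and
  grid mismatches are errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import DynamicImage
from .kinetic_classes import KineticClassSet
from .phantom import PhantomOutput, PhantomSpec, Shape, TissueModel
from .schedule import FrameSchedule

__all__ = [
    "schedule_sidecar_path",
    "write_dynamic_image",
    "read_dynamic_image",
    "write_label_image",
    "read_label_image",
    "write_class_set",
    "read_class_set",
    "class_set_to_csv",
    "write_phantom",
    "phantom_spec_to_dict",
    "phantom_spec_from_dict",
]


def _affine(spacing_mm) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def _spacing_from_header(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def schedule_sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return p.with_name(stem + "_schedule.json")


def write_dynamic_image(image: DynamicImage, path: str | Path) -> Path:
    """Write a 4D NIfTI plus its ``*_schedule.json`` sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.data, _affine(image.spacing_mm)), path)
    sidecar = schedule_sidecar_path(path)
    sidecar.write_text(json.dumps(image.schedule.to_dict()))
    return path


def read_dynamic_image(
    path: str | Path, schedule_path: str | Path | None = None
) -> DynamicImage:
    """Read a 4D NIfTI and its frame schedule; the two must agree on N."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D dynamic image, got {data.ndim}D "
            "(use the static readers for 3D images)"
        )
    sidecar = Path(schedule_path) if schedule_path else schedule_sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"frame-schedule sidecar not found: {sidecar}")
    sched = FrameSchedule.from_dict(json.loads(sidecar.read_text()))
    if sched.n_frames != data.shape[-1]:
        raise ValueError(
            f"{path}: image has {data.shape[-1]} frames but schedule lists "
            f"{sched.n_frames}"
        )
    return DynamicImage(data, _spacing_from_header(img), sched)


def write_label_image(
    labels: np.ndarray, table: dict[int, str], path: str | Path,
    spacing_mm=(1.0, 1.0, 1.0),
) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, np.int16), _affine(spacing_mm)), path)
    schedule_sidecar_path(path).with_name(
        schedule_sidecar_path(path).name.replace("_schedule", "_labels")
    ).write_text(json.dumps({str(k): v for k, v in table.items()}))
    return path


def read_label_image(
    path: str | Path,
    label_table: dict[int, str],
    expected_grid: tuple[int, int, int] | None = None,
) -> dict[str, np.ndarray]:
    """Read an integer 3D label image into one binary mask per named label.

    A requested label absent from the image yields an empty mask (with a
    warning); non-integer voxel values are an error.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: label image must be 3D, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: label image has non-integer voxel values")
        data = data.astype(np.int32)
    if expected_grid is not None and data.shape != tuple(expected_grid):
        raise ValueError(
            f"{path}: label grid {data.shape} does not match image grid "
            f"{tuple(expected_grid)}"
        )
    masks = {}
    for value, name in label_table.items():
        m = data == value
        if not m.any():
            import warnings

            warnings.warn(f"{path}: label {value} ({name}) is empty", stacklevel=2)
        masks[name] = m
    return masks


def write_class_set(kcs: KineticClassSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(kcs.to_dict(), indent=2))
    return path


def read_class_set(path: str | Path) -> KineticClassSet:
    return KineticClassSet.from_dict(json.loads(Path(path).read_text()))


def class_set_to_csv(kcs: KineticClassSet, path: str | Path) -> Path:
    """One row per (class, frame): timing, mean and SD."""
    sched = kcs.schedule
    rows = []
    for c in kcs.classes:
        for i in range(sched.n_frames):
            rows.append(
                {
                    "tissue": c.tissue,
                    "frame_index": i,
                    "start_s": sched.starts_s[i],
                    "duration_s": sched.durations_s[i],
                    "mid_s": sched.mid_times_s[i],
                    "mu": c.mu[i],
                    "sigma": c.sigma[i],
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# --- phantom serialisation ---------------------------------------------------

def _shape_to_dict(s: Shape) -> dict:
    return {"kind": s.kind, "center_mm": list(s.center_mm), "size_mm": list(s.size_mm)}


def _shape_from_dict(d: dict) -> Shape:
    return Shape(d["kind"], tuple(d["center_mm"]), tuple(d["size_mm"]))


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "grid_shape": list(spec.grid_shape),
        "spacing_mm": list(spec.spacing_mm),
        "schedule": spec.schedule.to_dict(),
        "tissues": {
            n: {
                "tac_shape": t.tac_shape,
                "amplitude_kbq_ml": t.amplitude_kbq_ml,
                "uptake_rate_per_min": t.uptake_rate_per_min,
                "peak_time_min": t.peak_time_min,
                "washout_rate_per_min": t.washout_rate_per_min,
            }
            for n, t in spec.tissues.items()
        },
        "organs": [[n, _shape_to_dict(s)] for n, s in spec.organs],
        "lesions": [[lid, _shape_to_dict(s)] for lid, s in spec.lesions],
        "noise_level": spec.noise_level,
        "dose_mbq": spec.dose_mbq,
        "weight_kg": spec.weight_kg,
        "seed": spec.seed,
        "rim_voxels": spec.rim_voxels,
        "background_tissue": spec.background_tissue,
    }


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        spacing_mm=tuple(d["spacing_mm"]),
        schedule=FrameSchedule.from_dict(d["schedule"]),
        tissues={
            n: TissueModel(name=n, **{k: v for k, v in t.items()})
            for n, t in d["tissues"].items()
        },
        organs=[(n, _shape_from_dict(s)) for n, s in d["organs"]],
        lesions=[(lid, _shape_from_dict(s)) for lid, s in d["lesions"]],
        noise_level=d.get("noise_level", 0.5),
        dose_mbq=d.get("dose_mbq", 364.0),
        weight_kg=d.get("weight_kg", 75.0),
        seed=d.get("seed", 0),
        rim_voxels=d.get("rim_voxels", 2),
        background_tissue=d.get("background_tissue", "lung"),
    )


def write_phantom(out: PhantomOutput, outdir: str | Path) -> dict[str, Path]:
    """Write one phantom realisation: image, truth labels, lesion masks,
    true TACs and the generating spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = out.image.spacing_mm
    paths = {}
    paths["image"] = write_dynamic_image(out.image, outdir / "image.nii.gz")
    paths["truth_labels"] = Path(outdir / "truth_labels.nii.gz")
    nib.save(
        nib.Nifti1Image(out.truth_labels.astype(np.int16), _affine(spacing)),
        paths["truth_labels"],
    )
    (outdir / "truth_labels_table.json").write_text(
        json.dumps({str(k): v for k, v in out.label_table.items()})
    )
    lesion_label = np.zeros(out.truth_labels.shape, dtype=np.int16)
    lesion_table = {}
    for i, (lid, m) in enumerate(sorted(out.lesion_masks.items()), start=1):
        lesion_label[m] = i
        lesion_table[str(i)] = lid
    paths["lesion_masks"] = Path(outdir / "lesion_masks.nii.gz")
    nib.save(nib.Nifti1Image(lesion_label, _affine(spacing)), paths["lesion_masks"])
    (outdir / "lesion_masks_table.json").write_text(json.dumps(lesion_table))

    sched = out.image.schedule
    tac_df = pd.DataFrame(
        {
            "frame_index": np.arange(sched.n_frames),
            "start_s": sched.starts_s,
            "duration_s": sched.durations_s,
            "mid_s": sched.mid_times_s,
            **{name: tac for name, tac in out.true_tacs.items()},
        }
    )
    paths["true_tacs"] = Path(outdir / "true_tacs.csv")
    tac_df.to_csv(paths["true_tacs"], index=False)
    paths["spec"] = Path(outdir / "phantom_spec.json")
    paths["spec"].write_text(json.dumps(phantom_spec_to_dict(out.spec), indent=2))
    return paths
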
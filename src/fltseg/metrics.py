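"""Lesion statistics, SUV, and test-retest repeatability summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LesionStats",
    "volume_cm3",
    "suv_stats",
    "trt_variability",
    "compare_methods",
    "dice",
]


@dataclass(frozen=True)
class LesionStats:
    """Per-lesion, per-method measurement on one scan."""

    lesion_id: str
    method: str
    volume_cm3: float
    suv_mean: float
    suv_max: float
    detected: bool


def volume_cm3(voi: np.ndarray, spacing_mm: tuple[float, float, float]) -> float:
    """VOI volume: voxel count times voxel volume."""
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacing must be positive")
    return float(np.asarray(voi, bool).sum()) * float(np.prod(spacing_mm)) / 1000.0


def suv_stats(
    image3d: np.ndarray, voi: np.ndarray, dose_mbq: float, weight_kg: float
) -> tuple[float, float]:
    """Body-weight SUV mean and max over a VOI.

    The image is activity concentration in kBq/mL; SUV = concentration /
    (injected dose / body weight) with the usual 1 g/mL tissue-density
    convention, which reduces to ``kBq_per_mL * weight_kg / dose_MBq``.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    voi = np.asarray(voi, bool)
    if not voi.any():
        raise ValueError("empty VOI")
    suv = np.asarray(image3d, float)[voi] * weight_kg / dose_mbq
    return float(suv.mean()), float(suv.max())


def trt_variability(test: float, retest: float) -> float:
    """Percent test-retest variability.

    ``|test - retest| / mean(test, retest) * 100``; zero when the two agree,
    bounded by 200 for non-negative inputs, NaN when both measurements are 0.
    """
    m = (test + retest) / 2.0
    if m == 0:
        return float("nan")
    if m < 0:
        raise ValueError("TRT variability needs a positive mean measurement")
    return abs(test - retest) / m * 100.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two masks; 1.0 when both are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


_METRICS = ("volume_cm3", "suv_mean", "suv_max")


def compare_methods(
    test: dict[str, list[LesionStats]], retest: dict[str, list[LesionStats]]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Test-retest comparison across segmentation methods.

    Parameters
    ----------
    test, retest
        Per method, the per-lesion stats on the test / retest scan.

    Returns
    -------
    rows
        One row per (lesion, method, metric): test and retest values,
        absolute difference, percent variability.  Restricted to lesions
        detected by every method on both scans.
    summary
        Median and mean percent variability and absolute difference per
        method and metric.
    detection
        Per method: lesions detected on both scans, and total lesions.
    """
    methods = sorted(set(test) | set(retest))
    per_method_detected: dict[str, set[str]] = {}
    all_lesions: set[str] = set()
    indexed: dict[tuple[str, str, str], LesionStats] = {}
    for role, data in (("test", test), ("retest", retest)):
        for method, stats in data.items():
            for s in stats:
                indexed[(role, method, s.lesion_id)] = s
                all_lesions.add(s.lesion_id)
    for method in methods:
        per_method_detected[method] = {
            lid
            for lid in all_lesions
            if indexed.get(("test", method, lid), None) is not None
            and indexed.get(("retest", method, lid), None) is not None
            and indexed[("test", method, lid)].detected
            and indexed[("retest", method, lid)].detected
        }
    common = set.intersection(*per_method_detected.values()) if methods else set()

    rows = []
    for method in methods:
        for lid in sorted(common):
            s_t = indexed[("test", method, lid)]
            s_r = indexed[("retest", method, lid)]
            for metric in _METRICS:
                a, b = getattr(s_t, metric), getattr(s_r, metric)
                rows.append(
                    {
                        "lesion_id": lid,
                        "method": method,
                        "metric": metric,
                        "test": a,
                        "retest": b,
                        "abs_diff": abs(a - b),
                        "pct_variability": trt_variability(a, b),
                    }
                )
    rows_df = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "method", "metric", "test", "retest",
            "abs_diff", "pct_variability",
        ],
    )
    if rows_df.empty:
        import warnings

        warnings.warn("no lesions detected by all methods on both scans", stacklevel=2)
        summary = pd.DataFrame(
            columns=["method", "metric", "median_pct", "mean_pct",
                     "median_abs_diff", "mean_abs_diff", "n_lesions"]
        )
    else:
        g = rows_df.groupby(["method", "metric"], sort=True)
        summary = g.agg(
            median_pct=("pct_variability", "median"),
            mean_pct=("pct_variability", "mean"),
            median_abs_diff=("abs_diff", "median"),
            mean_abs_diff=("abs_diff", "mean"),
            n_lesions=("lesion_id", "nunique"),
        ).reset_index()
    detection = pd.DataFrame(
        [
            {
                "method": m,
                "n_detected_both": len(per_method_detected[m]),
                "n_lesions": len(all_lesions),
            }
            for m in methods
        ]
    )
    return rows_df, summary, detection
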
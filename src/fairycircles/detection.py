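"""Morphological detection of barren circles in grayscale rasters.

The pipeline mirrors classical structuring-element image analysis:
binarize (Otsu by default), open with a disk structuring element to erase
sub-circle speckle, label connected components (8-connectivity), then keep
components passing area, circularity and border filters. Everything is
deterministic: one declarative :class:`DetectionParams` profile replaces
per-image manual tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .geometry import CirclePattern
from .rasters import RasterImage

__all__ = [
    "DetectionParams",
    "DetectedCircle",
    "detect_circles",
    "evaluate_detection",
    "detections_to_dataframe",
    "write_detections_csv",
]


@dataclass(frozen=True)
class DetectionParams:
    """Declarative profile for one detection run.

    polarity: whether targets are brighter ("bright_circles") or darker
    ("dark_circles") than the background. threshold: "otsu" or a fixed
    float in (0, 1). se_radius_px: disk structuring-element radius for the
    morphological opening. Area band in m^2; circularity = 4 pi A / P^2
    (1 for a perfect disc). border_policy "exclude_touching" drops
    components whose area is censored by the image edge.
    """

    polarity: str = "bright_circles"
    threshold: str | float = "otsu"
    # strel radius must stay below the smallest target radius in pixels
    # (5th-pct diameter 3.2 m is 3.2 px radius at 0.5 m/px)
    se_radius_px: int = 2
    min_area_m2: float = 3.0
    max_area_m2: float = 200.0
    min_circularity: float = 0.6
    border_policy: str = "exclude_touching"

    def __post_init__(self) -> None:
        if self.polarity not in ("bright_circles", "dark_circles"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.border_policy not in ("exclude_touching", "keep"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if not self.min_area_m2 < self.max_area_m2:
            raise ValueError("min_area_m2 must be < max_area_m2")
        if self.se_radius_px < 1:
            raise ValueError("se_radius_px must be >= 1")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min_circularity must be in (0, 1]")


@dataclass(frozen=True)
class DetectedCircle:
    """One detected component, reported in world meters."""

    x_m: float
    y_m: float
    area_m2: float
    equivalent_diameter_m: float
    circularity: float
    pixel_count: int

    def as_dict(self) -> dict:
        return asdict(self)


def detect_circles(
    image: RasterImage, params: DetectionParams | None = None
) -> list[DetectedCircle]:
    """Run the morphological detection pipeline on a grayscale raster.

    Returns detections sorted by (y, x) centroid for determinism. An
    all-constant image yields an empty list, not an error.
    """
    if params is None:
        params = DetectionParams()
    arr = image.data
    if params.polarity == "dark_circles":
        arr = 1.0 - arr
    if np.ptp(arr) == 0:
        return []
    if params.threshold == "otsu":
        thr = threshold_otsu(arr)
    else:
        thr = float(params.threshold)
    binary = arr > thr
    opened = morphology.opening(binary, morphology.disk(params.se_radius_px))
    labels = measure.label(opened, connectivity=2)
    scale = image.pixel_scale
    n_rows, n_cols = image.shape
    out: list[DetectedCircle] = []
    for prop in measure.regionprops(labels):
        area_m2 = prop.area * scale**2
        if not (params.min_area_m2 <= area_m2 <= params.max_area_m2):
            continue
        if params.border_policy == "exclude_touching":
            r0, c0, r1, c1 = prop.bbox
            if r0 == 0 or c0 == 0 or r1 == n_rows or c1 == n_cols:
                continue
        perimeter = prop.perimeter
        circ = 1.0 if perimeter == 0 else min(
            1.0, 4.0 * np.pi * prop.area / perimeter**2
        )
        if circ < params.min_circularity:
            continue
        row_c, col_c = prop.centroid
        x_m, y_m = image.pixel_to_world(row_c, col_c)
        out.append(
            DetectedCircle(
                x_m=float(x_m),
                y_m=float(y_m),
                area_m2=float(area_m2),
                equivalent_diameter_m=float(2.0 * np.sqrt(area_m2 / np.pi)),
                circularity=float(circ),
                pixel_count=int(prop.area),
            )
        )
    out.sort(key=lambda d: (d.y_m, d.x_m))
    return out


def evaluate_detection(
    detected: Sequence[DetectedCircle],
    truth: CirclePattern,
    match_dist: float = 2.5,
) -> dict:
    """Score detections against a ground-truth pattern.

    Greedy one-to-one matching by ascending centroid distance, accepting
    pairs closer than ``match_dist`` (m). Returns precision, recall,
    area_bias_pct = 100 * (mean detected area - mean true area) / mean true
    area over matched pairs, and the match count. With empty truth, recall
    and bias are None.
    """
    if match_dist <= 0:
        raise ValueError("match_dist must be positive")
    n_det = len(detected)
    n_true = truth.n
    if n_true == 0:
        return {
            "precision": 1.0 if n_det == 0 else 0.0,
            "recall": None,
            "area_bias_pct": None,
            "n_matched": 0,
        }
    if n_det == 0:
        return {"precision": 1.0, "recall": 0.0, "area_bias_pct": None, "n_matched": 0}

    det_xy = np.array([[d.x_m, d.y_m] for d in detected])
    dist = cdist(det_xy, truth.centers)
    order = np.argsort(dist, axis=None)
    used_det: set[int] = set()
    used_true: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > match_dist:
            break
        if i in used_det or j in used_true:
            continue
        used_det.add(int(i))
        used_true.add(int(j))
        pairs.append((int(i), int(j)))
    n_match = len(pairs)
    true_areas = truth.areas
    if n_match:
        det_mean = np.mean([detected[i].area_m2 for i, _ in pairs])
        true_mean = np.mean([true_areas[j] for _, j in pairs])
        bias = float(100.0 * (det_mean - true_mean) / true_mean)
    else:
        bias = None
    return {
        "precision": n_match / n_det,
        "recall": n_match / n_true,
        "area_bias_pct": bias,
        "n_matched": n_match,
    }


def detections_to_dataframe(detected: Sequence[DetectedCircle]) -> pd.DataFrame:
    return pd.DataFrame(
        [d.as_dict() for d in detected],
        columns=[
            "x_m",
            "y_m",
            "area_m2",
            "equivalent_diameter_m",
            "circularity",
            "pixel_count",
        ],
    )


def write_detections_csv(detected: Sequence[DetectedCircle], path: str | Path) -> None:
    detections_to_dataframe(detected).to_csv(path, index=False)
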
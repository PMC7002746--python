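"""Watershed detection of luminal nuclei inside annotated duct regions.

Detection runs on the unmixed stain-amount maps.  Nuclear foreground is
the set of pixels whose raw total (hematoxylin + DAB) optical density and
whose Gaussian-smoothed total OD both reach the threshold, cleaned by a
1-pixel binary opening: the raw condition keeps nucleus outlines sharp
(thresholding only the smoothed image would dilate every object by a few
pixels, inflating areas and fusing neighbours), while the smoothed
condition and the opening suppress isolated noise speckle.  Seeds are
placed at well-separated maxima of the Euclidean distance transform of
that foreground and a seeded watershed splits touching nuclei; areas,
boundaries and mean stain ODs are measured per watershed object.

Detected objects then pass through three automated exclusion rules mirroring
standard manual curation of watershed output:

1. *merged* — area >= ``merge_area_multiple`` x the nominal nucleus area
   (incomplete separation; an object spanning two or more nuclei);
2. *fragment* — area < ``min_area_fraction`` x nominal (incorrect
   partitioning; a piece smaller than one nucleus);
3. *non_nucleus* — circularity ``4*pi*area/perimeter**2`` below
   ``min_circularity`` (shape incompatible with a nucleus).

Rules are evaluated in that order; the first match wins.  Only objects with
exclusion code ``none`` enter downstream ER quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon, box, mapping, shape as shapely_shape
from skimage import measure, morphology, segmentation
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .stains import ConcentrationMaps

__all__ = [
    "DetectionParams",
    "NucleusObject",
    "DuctRegion",
    "AnnotationError",
    "detect_nuclei",
    "apply_exclusion_rules",
    "read_annotations",
    "write_annotations",
    "objects_to_dataframe",
    "write_objects_csv",
    "read_objects_csv",
]

EXCLUSION_CODES = ("none", "merged", "fragment", "non_nucleus")


class AnnotationError(ValueError):
    """Raised for malformed or out-of-bounds duct annotations."""


@dataclass(frozen=True)
class DetectionParams:
    """Watershed cell-detection parameters (all lengths in micrometres)."""

    smoothing_sigma_um: float = 1.5
    od_threshold: float = 0.1
    expected_nucleus_area_um2: float = 40.0
    min_area_fraction: float = 0.5
    merge_area_multiple: float = 2.0
    min_circularity: float = 0.55
    min_seed_separation_um: float = 4.0

    def __post_init__(self) -> None:
        vals = (self.smoothing_sigma_um, self.od_threshold,
                self.expected_nucleus_area_um2, self.min_area_fraction,
                self.merge_area_multiple, self.min_seed_separation_um)
        if any(not v > 0 for v in vals):
            raise ValueError("detection parameters must be positive")
        if not self.min_area_fraction < 1.0 < self.merge_area_multiple:
            raise ValueError("need min_area_fraction < 1 < merge_area_multiple")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")


@dataclass
class NucleusObject:
    """One detected nucleus candidate with geometry and mean stain ODs."""

    label: int
    centroid: tuple[float, float]  #: (x, y) in pixel coordinates (x=column, y=row)
    area_um2: float
    circularity: float  #: 4*pi*area/perimeter^2, clamped to [0, 1]
    mean_hematoxylin_od: float
    mean_dab_od: float
    boundary: np.ndarray = field(repr=False)  #: (n, 2) closed polygon, (x, y) pixels
    exclusion_code: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_code not in EXCLUSION_CODES:
            raise ValueError(f"unknown exclusion code {self.exclusion_code!r}")
        if not self.area_um2 > 0:
            raise ValueError("nucleus area must be positive")
        if self.mean_hematoxylin_od < 0 or self.mean_dab_od < 0:
            raise ValueError("mean stain ODs must be non-negative")


@dataclass
class DuctRegion:
    """An annotated duct outline and the nuclei retained inside it."""

    region_id: str
    polygon: Polygon
    nuclei: list[NucleusObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise AnnotationError(f"region {self.region_id!r}: polygon is not simple")


def _object_boundary(mask: np.ndarray, offset_rc: tuple[int, int]) -> np.ndarray:
    """Marching-squares boundary of a binary object, as a closed (x, y) polygon."""
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    rows = contour[:, 0] + offset_rc[0] - 1.0
    cols = contour[:, 1] + offset_rc[1] - 1.0
    return np.column_stack([cols, rows])


def _polygon_length(poly_xy: np.ndarray) -> float:
    d = np.diff(poly_xy, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def detect_nuclei(
    maps: ConcentrationMaps,
    polygon: Polygon,
    params: DetectionParams = DetectionParams(),
) -> list[NucleusObject]:
    """Detect nucleus candidates inside one duct polygon.

    Returns measured objects with ``exclusion_code`` still set to ``"none"``;
    run :func:`apply_exclusion_rules` to classify them.  An empty foreground is
    not an error and yields an empty list.  A polygon lying outside the image,
    or smaller than one nominal nucleus, is rejected.
    """
    px = maps.pixel_size_um
    h, w = maps.shape
    if not polygon.intersects(box(0, 0, w - 1, h - 1)):
        raise AnnotationError("annotation polygon lies outside the image")
    if polygon.area * px * px < params.expected_nucleus_area_um2:
        raise AnnotationError("annotation polygon smaller than one nominal nucleus")

    xy = np.asarray(polygon.exterior.coords)
    region_mask = polygon2mask((h, w), xy[:, ::-1])  # polygon2mask wants (row, col)
    total = maps.hematoxylin + maps.dab
    sigma_px = params.smoothing_sigma_um / px
    smoothed = gaussian(total, sigma=sigma_px, preserve_range=True)
    # sharp raw-OD edges intersected with the smoothed mask: noise speckle is
    # suppressed (its smoothed OD stays low) without dilating nucleus outlines
    fg = (total >= params.od_threshold) & \
        (smoothed >= params.od_threshold) & region_mask
    fg = morphology.opening(fg, morphology.disk(1))
    if not fg.any():
        return []

    distance = ndi.distance_transform_edt(fg)
    sep_px = max(1, int(round(params.min_seed_separation_um / px)))
    seeds = peak_local_max(
        distance, min_distance=sep_px, exclude_border=False,
        labels=measure.label(fg),
    )
    if seeds.shape[0] == 0:
        return []
    markers = np.zeros((h, w), dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, seeds.shape[0] + 1)
    labels = segmentation.watershed(-distance, markers, mask=fg)

    objects: list[NucleusObject] = []
    out_label = 0
    for rp in measure.regionprops(labels):
        if rp.area < 3:  # sub-speckle remnants carry no measurable geometry
            continue
        minr, minc, _, _ = rp.bbox
        boundary = _object_boundary(rp.image, (minr, minc))
        perimeter = _polygon_length(boundary)
        area_px = float(rp.area)
        circularity = 1.0 if perimeter <= 0 else min(
            1.0, 4.0 * np.pi * area_px / perimeter ** 2
        )
        cy, cx = rp.centroid  # (row, col)
        if not Point(cx, cy).within(polygon):
            continue  # centroid outside the demarcated epithelium
        coords = tuple(rp.coords.T)
        out_label += 1
        objects.append(
            NucleusObject(
                label=out_label,
                centroid=(float(cx), float(cy)),
                area_um2=area_px * px * px,
                circularity=float(circularity),
                mean_hematoxylin_od=float(maps.hematoxylin[coords].mean()),
                mean_dab_od=float(maps.dab[coords].mean()),
                boundary=boundary,
            )
        )
    return objects


def apply_exclusion_rules(
    objects: list[NucleusObject],
    params: DetectionParams = DetectionParams(),
) -> tuple[list[NucleusObject], list[NucleusObject]]:
    """Assign exclusion codes and split objects into (retained, excluded).

    Rule order — merged, fragment, non_nucleus — with first match winning; the
    merged-area boundary is inclusive (exactly two nominal nuclei is merged).
    The two returned lists are disjoint and jointly cover the input.
    """
    nominal = params.expected_nucleus_area_um2
    retained: list[NucleusObject] = []
    excluded: list[NucleusObject] = []
    for obj in objects:
        if obj.area_um2 >= params.merge_area_multiple * nominal:
            code = "merged"
        elif obj.area_um2 < params.min_area_fraction * nominal:
            code = "fragment"
        elif obj.circularity < params.min_circularity:
            code = "non_nucleus"
        else:
            code = "none"
        obj.exclusion_code = code
        (retained if code == "none" else excluded).append(obj)
    return retained, excluded


# ---------------------------------------------------------------------------
# annotation and measurement I/O


def read_annotations(path) -> list[DuctRegion]:
    """Read duct outlines from a GeoJSON FeatureCollection of Polygon features."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot parse annotation file {path}: {exc}") from exc
    if payload.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    regions: list[DuctRegion] = []
    for i, feature in enumerate(payload.get("features", [])):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise AnnotationError(f"{path}: feature {i} is not a Polygon")
        try:
            poly = shapely_shape(geom)
        except Exception as exc:  # shapely raises a mix of error types
            raise AnnotationError(f"{path}: feature {i}: {exc}") from exc
        region_id = str(feature.get("properties", {}).get("region_id", f"region_{i}"))
        regions.append(DuctRegion(region_id=region_id, polygon=poly))
    return regions


def write_annotations(path, regions: list[DuctRegion]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"region_id": r.region_id},
            "geometry": mapping(r.polygon),
        }
        for r in regions
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def objects_to_dataframe(objects: list[NucleusObject], region_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [o.label for o in objects],
            "region_id": region_id,
            "x": [o.centroid[0] for o in objects],
            "y": [o.centroid[1] for o in objects],
            "area_um2": [o.area_um2 for o in objects],
            "circularity": [o.circularity for o in objects],
            "mean_h_od": [o.mean_hematoxylin_od for o in objects],
            "mean_dab_od": [o.mean_dab_od for o in objects],
            "exclusion_code": [o.exclusion_code for o in objects],
        }
    )


def write_objects_csv(path, frames: list[pd.DataFrame]) -> None:
    df = (pd.concat(frames, ignore_index=True) if frames
          else objects_to_dataframe([], ""))
    df.to_csv(path, index=False)


def read_objects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
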
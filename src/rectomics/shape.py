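"""3D and section-wise shape morphometry of wall and lumen masks.

Per case the extractor emits 198 features:

* 25 3D descriptors for each of the entire rectal wall (ERW) and lumen,
  derived from physical-space voxel moments (equivalent-ellipsoid and
  equivalent-sphere geometry) and from the 3D convex hull;
* 4 wall-minus-lumen differences of diameter-type descriptors;
* 72 slice-series features per structure: 18 per-section 2D descriptors,
  differenced between consecutive sections, then summarized by
  {mean, variance, skewness, excess kurtosis}.

All lengths are reported in mm and volumes in mm^3, using the header
spacing; dimensionless ratios (compactness, solidity, eccentricity, ...)
are therefore invariant to voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis as _kurtosis, skew as _skew
from skimage.measure import perimeter_crofton, regionprops

from .io import Mask

STRUCT_TAGS = {"entire_wall": "ERW", "lumen": "Lumen"}

SHAPE3D_NAMES = (
    # contour-type (principal-axis geometry)
    "axis_length_major", "axis_length_mid", "axis_length_minor",
    "eccentricity", "elongation",
    "eq_ellipsoid_d1", "eq_ellipsoid_d2", "eq_ellipsoid_d3",
    "eq_sphere_radius", "eq_sphere_perimeter", "flatness",
    "orientation_x", "orientation_y", "orientation_z",
    # region-type
    "compactness", "elongation_factor",
    "principal_moment_1", "principal_moment_2", "principal_moment_3",
    "roundness", "volume", "extent", "solidity", "convex_volume",
    "bbox_volume",
)

#: wall-minus-lumen differences of diameter-type descriptors
DIFF_NAMES = ("eq_sphere_radius", "eq_sphere_perimeter",
              "axis_length_major", "axis_length_minor")

SHAPE2D_NAMES = (
    "major_axis_length", "minor_axis_length", "convexity",
    "convex_perimeter", "eccentricity", "elongation", "equiv_diameter",
    "orientation", "perimeter", "area", "bbox_area", "compactness",
    "convex_area", "bbox_elongation", "extent", "filled_area",
    "roundness", "solidity",
)

SUMMARY_STATS = ("mean", "variance", "skewness", "kurtosis")


@dataclass(frozen=True)
class ShapeConfig:
    """Shape feature configuration; defaults satisfy 25*2 + 4 + 72*2 = 198."""

    shape3d: tuple[str, ...] = SHAPE3D_NAMES
    diffs: tuple[str, ...] = DIFF_NAMES
    shape2d: tuple[str, ...] = SHAPE2D_NAMES
    stats: tuple[str, ...] = SUMMARY_STATS
    #: "difference" summarizes the consecutive-section difference series
    #: (default); "raw" summarizes the per-section series directly.
    series_mode: str = "difference"

    @property
    def n_features(self) -> int:
        per_struct = len(self.shape3d) + len(self.shape2d) * len(self.stats)
        return 2 * per_struct + len(self.diffs)


DEFAULT_SHAPE_CONFIG = ShapeConfig()


# ---------------------------------------------------------------------------
# 3D descriptors
# ---------------------------------------------------------------------------

def shape_3d(mask: Mask) -> dict[str, float]:
    """25 3D shape descriptors of one structure (lengths in mm)."""
    vox = mask.voxels
    n = int(vox.sum())
    if n == 0:
        raise ValueError("empty mask")
    if n < 4:
        raise ValueError("mask too small for 3D moment descriptors")
    sp = np.asarray(mask.spacing)
    coords = np.argwhere(vox).astype(float) * sp  # mm, voxel centres
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / n
    cov += np.diag(sp**2) / 12.0  # continuous voxel correction
    lam, vec = np.linalg.eigh(cov)
    lam = lam[::-1]                 # descending principal moments (mm^2)
    vec = vec[:, ::-1]
    d = 2.0 * np.sqrt(5.0 * np.clip(lam, 0, None))  # equiv ellipsoid diameters
    r_eq = np.sqrt(5.0 * lam.mean())
    volume = n * float(np.prod(sp))
    proj = centred @ vec
    axis_len = proj.max(axis=0) - proj.min(axis=0) + sp.mean()
    axis_len = np.sort(axis_len)[::-1]
    hull = ConvexHull(coords)
    bbox = (coords.max(axis=0) - coords.min(axis=0)) + sp

    out = {
        "axis_length_major": axis_len[0],
        "axis_length_mid": axis_len[1],
        "axis_length_minor": axis_len[2],
        "eccentricity": float(np.sqrt(max(0.0, 1.0 - (d[2] / d[0]) ** 2))),
        "elongation": d[2] / d[0],
        "eq_ellipsoid_d1": d[0],
        "eq_ellipsoid_d2": d[1],
        "eq_ellipsoid_d3": d[2],
        "eq_sphere_radius": r_eq,
        "eq_sphere_perimeter": 4.0 * np.pi * r_eq**2,
        "flatness": d[2] / d[1] if d[1] > 0 else 0.0,
        "orientation_x": float(np.arccos(np.clip(abs(vec[0, 0]), 0, 1))),
        "orientation_y": float(np.arccos(np.clip(abs(vec[1, 0]), 0, 1))),
        "orientation_z": float(np.arccos(np.clip(abs(vec[2, 0]), 0, 1))),
        "compactness": volume / (4.0 / 3.0 * np.pi * r_eq**3),
        "elongation_factor": float(np.sqrt(lam[0] / lam[1])) if lam[1] > 0 else 0.0,
        "principal_moment_1": lam[0],
        "principal_moment_2": lam[1],
        "principal_moment_3": lam[2],
        "roundness": volume / (4.0 / 3.0 * np.pi * (hull.area / (4 * np.pi)) ** 1.5),
        "volume": volume,
        "extent": volume / float(np.prod(bbox)),
        "solidity": min(1.0, volume / hull.volume) if hull.volume > 0 else 0.0,
        "convex_volume": hull.volume,
        "bbox_volume": float(np.prod(bbox)),
    }
    return {k: float(v) for k, v in out.items()}


def interstructure_diffs(wall: Mask, lumen: Mask) -> dict[str, float]:
    """Wall-minus-lumen differences of the four diameter-type descriptors."""
    sw = shape_3d(wall)
    sl = shape_3d(lumen)
    return {f"diff.{name}": sw[name] - sl[name] for name in DIFF_NAMES}


# ---------------------------------------------------------------------------
# 2D section series
# ---------------------------------------------------------------------------

def _section_descriptors(sec: np.ndarray, dx: float, dy: float) -> dict[str, float]:
    s = float(np.sqrt(dx * dy))  # near-isotropic in-plane length scale
    pxarea = dx * dy
    props = regionprops(sec.astype(np.uint8))[0]
    perim = perimeter_crofton(sec, directions=4) * s
    pts = np.argwhere(sec).astype(float) * [dx, dy]
    if len(np.unique(pts[:, 0])) > 1 and len(np.unique(pts[:, 1])) > 1:
        hull_perim = ConvexHull(pts).area  # 2D hull "area" is its perimeter
    else:  # degenerate (collinear) section
        hull_perim = 2.0 * (pts.max(axis=0) - pts.min(axis=0)).sum()
    area = props.area * pxarea
    bbox_dims = (props.bbox[2] - props.bbox[0], props.bbox[3] - props.bbox[1])
    major = props.axis_major_length * s
    minor = props.axis_minor_length * s
    return {
        "major_axis_length": major,
        "minor_axis_length": minor,
        "convexity": hull_perim / perim if perim > 0 else 1.0,
        "convex_perimeter": hull_perim,
        "eccentricity": props.eccentricity,
        "elongation": minor / major if major > 0 else 1.0,
        "equiv_diameter": props.equivalent_diameter_area * s,
        "orientation": props.orientation,
        "perimeter": perim,
        "area": area,
        "bbox_area": bbox_dims[0] * bbox_dims[1] * pxarea,
        "compactness": 4 * np.pi * area / perim**2 if perim > 0 else 1.0,
        "convex_area": props.area_convex * pxarea,
        "bbox_elongation": min(bbox_dims) / max(bbox_dims),
        "extent": props.extent,
        "filled_area": props.area_filled * pxarea,
        "roundness": 4 * np.pi * area / hull_perim**2 if hull_perim > 0 else 1.0,
        "solidity": props.solidity,
    }


def section_series(mask: Mask) -> "np.recarray":
    """Table of 18 descriptors for every non-empty section of a mask.

    Empty sections inside the span are excluded from the series.  Returns
    a structured array with a ``section`` index field; requires the mask to
    occupy at least 2 sections.
    """
    dx, dy, _ = mask.spacing
    rows = []
    for sidx in range(mask.shape[2]):
        sec = mask.voxels[:, :, sidx]
        if not sec.any():
            continue
        row = {"section": sidx}
        row.update(_section_descriptors(sec, dx, dy))
        rows.append(row)
    if len(rows) < 2:
        raise ValueError("mask must occupy at least 2 sections")
    return pd.DataFrame(rows)


def _series_stats(x: np.ndarray) -> dict[str, float]:
    var = float(np.var(x, ddof=1))
    degenerate = var < 1e-20
    return {
        "mean": float(np.mean(x)),
        "variance": var,
        "skewness": 0.0 if degenerate else float(_skew(x)),
        "kurtosis": 0.0 if degenerate else float(_kurtosis(x, fisher=True)),
    }


def section_difference_stats(series, mode: str = "difference") -> dict[str, float]:
    """72 slice-series features: first-order statistics of the
    consecutive-section difference of each 2D descriptor (or of the raw
    series when ``mode='raw'``)."""
    out = {}
    for name in SHAPE2D_NAMES:
        x = np.asarray(series[name], dtype=float)
        if mode == "difference":
            x = np.diff(x)
        elif mode != "raw":
            raise ValueError(f"unknown series mode {mode!r}")
        if x.size < 2:
            raise ValueError(
                "difference series needs >= 3 sections (variance of a "
                "length-1 series is undefined)")
        st = _series_stats(x)
        for stat in SUMMARY_STATS:
            out[f"2d.{name}.{stat}"] = st[stat]
    return out


def extract_shape_features(wall: Mask, lumen: Mask,
                           config: ShapeConfig = DEFAULT_SHAPE_CONFIG,
                           ) -> dict[str, float]:
    """All 198 shape features of one case (wall + lumen)."""
    out: dict[str, float] = {}
    for mask in (wall, lumen):
        tag = STRUCT_TAGS[mask.role]
        for name, v in shape_3d(mask).items():
            out[f"3d.{name}.{tag}"] = v
    out.update(interstructure_diffs(wall, lumen))
    for mask in (wall, lumen):
        tag = STRUCT_TAGS[mask.role]
        series = section_series(mask)
        for name, v in section_difference_stats(series, config.series_mode).items():
            out[f"{name}.{tag}"] = v
    return out
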
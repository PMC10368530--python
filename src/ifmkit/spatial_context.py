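"""Tumor mask, invasive-margin geometry and compartment assignment.

The tumor region is smoothed from per-cell epithelial-marker calls with a
k-nearest-neighbor majority vote (k = 25 by default). The tumor-stroma
boundary is extracted by rasterizing the smoothed labels, applying a
morphological closing and tracing sub-pixel contours; every cell within
``margin_um`` (default 100) of the boundary on either side is assigned to
the invasive margin (IM), tumor-labeled cells deeper than that to the
tumor center (CT), and everything else to OUT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.measure import find_contours
from skimage.morphology import closing, disk
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "CompartmentMap",
    "build_tumor_mask",
    "assign_compartments",
    "region_fractions",
    "boundary_distance",
]

CT, IM, OUT = "CT", "IM", "OUT"


@dataclass
class CompartmentMap:
    labels: np.ndarray                 # per-cell CT/IM/OUT
    boundary: list                     # list of (N, 2) polylines in um (x, y)
    margin_width_um: float
    knn_k: int | None = None
    degenerate: bool = False
    distances_um: np.ndarray | None = None
    raster_um: float = 20.0

    def boundary_geojson(self) -> dict:
        return {
            "type": "MultiLineString",
            "coordinates": [poly.tolist() for poly in self.boundary],
        }


def build_tumor_mask(x, y, panck_pos, k: int = 25) -> np.ndarray:
    """Smooth per-cell tumor membership with a KNN majority vote.

    A cell is tumor-region if the majority of its ``k`` nearest cells
    (including itself, Euclidean distance in um) carry a positive
    epithelial call. Applied to every cell, not only positive ones.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    panck = np.asarray(panck_pos).astype(int)
    n = x.size
    if k > n:
        raise ValueError(f"k={k} exceeds cell count {n}")
    if panck.all():
        return np.ones(n, dtype=bool)
    if not panck.any():
        return np.zeros(n, dtype=bool)
    xy = np.column_stack([x, y])
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(xy, panck)
    return clf.predict(xy).astype(bool)


def _raster_boundary(x, y, tumor, raster_um, k_raster=7):
    """Rasterize tumor labels and trace sub-pixel contours.

    Each pixel carries the mean tumor indicator of its ``k_raster`` nearest
    cells (averaging damps boundary wiggle from point-set noise); the
    boundary is the 0.5 level-set contour after a morphological closing.
    """
    pad = 2 * raster_um
    x0, x1 = x.min() - pad, x.max() + pad
    y0, y1 = y.min() - pad, y.max() + pad
    nx = max(int(np.ceil((x1 - x0) / raster_um)), 4)
    ny = max(int(np.ceil((y1 - y0) / raster_um)), 4)
    gx = x0 + (np.arange(nx) + 0.5) * raster_um
    gy = y0 + (np.arange(ny) + 0.5) * raster_um
    gxx, gyy = np.meshgrid(gx, gy)
    tree = cKDTree(np.column_stack([x, y]))
    k = min(k_raster, x.size)
    _, nearest = tree.query(np.column_stack([gxx.ravel(), gyy.ravel()]), k=k)
    if k == 1:
        nearest = nearest[:, None]
    field = tumor[nearest].mean(axis=1).reshape(ny, nx)
    field = closing(field, disk(1))  # fills pinhole gaps in the label field
    # damp residual boundary wiggle from cell-sampling noise; the smoothing
    # length is ~2 pixels, well below the 100 um margin scale
    field = gaussian_filter(field, sigma=2.0)
    contours = find_contours(field, 0.5)
    polylines = []
    for c in contours:
        # contour coords are (row, col) in pixel units
        px = x0 + (c[:, 1] + 0.5) * raster_um
        py = y0 + (c[:, 0] + 0.5) * raster_um
        polylines.append(np.column_stack([px, py]))
    return polylines


def _densify(polylines, step):
    pts = []
    for poly in polylines:
        for p, q in zip(poly[:-1], poly[1:]):
            seg = np.linalg.norm(q - p)
            n = max(int(np.ceil(seg / step)), 1)
            t = np.linspace(0.0, 1.0, n, endpoint=False)
            pts.append(p[None] + t[:, None] * (q - p)[None])
        pts.append(poly[-1:][:])
    return np.vstack(pts) if pts else np.zeros((0, 2))


def boundary_distance(x, y, polylines, raster_um: float = 20.0) -> np.ndarray:
    """Distance from each cell to the nearest boundary polyline point."""
    pts = _densify(polylines, step=raster_um / 8.0)
    if pts.shape[0] == 0:
        return np.full(np.asarray(x).size, np.inf)
    tree = cKDTree(pts)
    d, _ = tree.query(np.column_stack([x, y]))
    return d


def assign_compartments(df: pd.DataFrame, tumor_label,
                        margin_um: float = 100.0,
                        raster_um: float = 20.0,
                        knn_k: int | None = None) -> CompartmentMap:
    """Assign every cell to CT, IM or OUT relative to the tumor boundary.

    The IM band overrides CT inside ``margin_um`` of the boundary (CT and
    IM are disjoint scoring regions). Degenerate inputs (no boundary, all
    tumor or all stroma) yield an all-CT or all-OUT map with a flag.
    """
    x = df["x_um"].values.astype(float)
    y = df["y_um"].values.astype(float)
    tumor = np.asarray(tumor_label).astype(bool)
    n = x.size
    if tumor.all() or not tumor.any():
        labels = np.where(tumor, CT, OUT).astype(object)
        return CompartmentMap(labels=labels, boundary=[],
                              margin_width_um=margin_um, knn_k=knn_k,
                              degenerate=True, raster_um=raster_um)
    polylines = _raster_boundary(x, y, tumor, raster_um)
    if not polylines:
        labels = np.where(tumor, CT, OUT).astype(object)
        return CompartmentMap(labels=labels, boundary=[],
                              margin_width_um=margin_um, knn_k=knn_k,
                              degenerate=True, raster_um=raster_um)
    d = boundary_distance(x, y, polylines, raster_um)
    labels = np.full(n, OUT, dtype=object)
    labels[tumor] = CT
    labels[d <= margin_um] = IM
    if margin_um <= 0:
        labels = np.where(tumor, CT, OUT).astype(object)
    return CompartmentMap(labels=labels, boundary=polylines,
                          margin_width_um=margin_um, knn_k=knn_k,
                          distances_um=d, raster_um=raster_um)


def region_fractions(comp: CompartmentMap, df: pd.DataFrame, markers,
                     call_suffix: str = "_pos") -> pd.DataFrame:
    """Marker-positive fraction per (specimen, marker, region in {CT, IM}).

    The denominator is all segmented cells in the region, regardless of
    type. Empty regions produce missing values (NaN), never zero, so the
    specimen drops out of downstream median computations.
    """
    out = []
    labels = np.asarray(comp.labels)
    for spec_id, idx in df.groupby("specimen_id").indices.items():
        for region in (CT, IM):
            in_region = idx[labels[idx] == region]
            denom = in_region.size
            for m in markers:
                col = f"{m}{call_suffix}"
                if col not in df.columns:
                    raise KeyError(f"missing call column {col!r}")
                if denom == 0:
                    frac = np.nan
                else:
                    frac = float(df[col].values[in_region].sum() / denom)
                out.append({
                    "specimen_id": spec_id, "marker": m, "region": region,
                    "positive_fraction": frac, "n_cells": denom,
                })
    return pd.DataFrame(out)
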
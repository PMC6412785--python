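"""Nucleus segmentation, per-cell counting, and the multinucleation rate.

The fluorescence nucleus channel is binarized (Otsu by default), holes
are filled, and connected components above a minimum area become
nucleus records.  Each nucleus is assigned to the cell whose region
contains its centroid — the programmatic analogue of judging parentage
on a phase-contrast/fluorescence overlay.  A cell with two or more
assigned nuclei is multinucleated, and the field-level rate is

    R_multi = 100 · N_multi / N_all   [%],

with N_all the number of cells holding at least one assigned nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border


class UndefinedRatioError(ZeroDivisionError):
    """R_multi is undefined: no cell holds an assigned nucleus."""


@dataclass(frozen=True)
class MultinucleationSummary:
    """Counts and rate of multinucleated cells for one condition × timepoint."""

    condition: str
    timepoint_h: float | None
    n_all: int
    n_multi: int
    r_multi: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_multi <= self.n_all:
            raise ValueError("need 0 <= n_multi <= n_all")


def segment_nuclei(image: np.ndarray, *,
                   threshold: float | str = "otsu",
                   min_area_um2: float = 20.0,
                   pixel_size_um: float = 0.664,
                   blur_sigma: float = 0.0,
                   fill_holes: bool = True,
                   connectivity: int = 2,
                   exclude_border: bool = False
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment nuclei from a single-channel fluorescence image.

    Returns a records table (``nucleus_id``, centroid, areas in px² and
    µm²) and a label mask whose labels 1..N are assigned in raster order
    of each nucleus's first pixel, so repeated runs are reproducible.

    ``threshold`` is ``'otsu'``, a fixed gray level, or
    ``('percentile', q)`` to threshold at the q-th intensity percentile.
    Components smaller than ``min_area_um2`` are treated as debris and
    dropped.  An empty or blank image yields an empty table, not an
    error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {img.shape}")
    if blur_sigma > 0:
        img = gaussian(img, sigma=blur_sigma, preserve_range=True)

    empty = (pd.DataFrame(columns=["nucleus_id", "centroid_row", "centroid_col",
                                   "area_px2", "area_um2"]),
             np.zeros(img.shape, dtype=np.uint16))
    if img.max() == img.min():
        return empty
    if threshold == "otsu":
        t = threshold_otsu(img)
    elif isinstance(threshold, tuple) and threshold[0] == "percentile":
        t = np.percentile(img, threshold[1])
    else:
        t = float(threshold)
    mask = img > t
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if exclude_border:
        mask = clear_border(mask)
    if not mask.any():
        return empty

    lab = sk_label(mask, connectivity=connectivity)
    min_area_px = min_area_um2 / pixel_size_um**2
    rows = []
    out = np.zeros(img.shape, dtype=np.uint16)
    next_id = 0
    for prop in regionprops(lab):  # regionprops is ordered by label = raster order
        if prop.area < min_area_px:
            continue
        next_id += 1
        out[lab == prop.label] = next_id
        rows.append({
            "nucleus_id": next_id,
            "centroid_row": prop.centroid[0],
            "centroid_col": prop.centroid[1],
            "area_px2": float(prop.area),
            "area_um2": float(prop.area) * pixel_size_um**2,
        })
    return pd.DataFrame(rows), out


def records_from_label_mask(nucleus_mask: np.ndarray,
                            pixel_size_um: float = 0.664) -> pd.DataFrame:
    """Nucleus records straight from a ground-truth label mask (no thresholding)."""
    rows = [{
        "nucleus_id": int(p.label),
        "centroid_row": p.centroid[0],
        "centroid_col": p.centroid[1],
        "area_px2": float(p.area),
        "area_um2": float(p.area) * pixel_size_um**2,
    } for p in regionprops(np.asarray(nucleus_mask))]
    return pd.DataFrame(rows)


def assign_nuclei_to_cells(nuclei: pd.DataFrame,
                           cells: np.ndarray | Mapping[int, Polygon | Sequence]
                           ) -> pd.DataFrame:
    """Assign each nucleus to the cell whose region contains its centroid.

    ``cells`` is either a label mask (0 = background) or a mapping of
    cell id → polygon (shapely ``Polygon`` or vertex sequence in
    ``(x, y)`` = (col, row) order).  Nuclei whose centroid falls in no
    cell get ``cell_id = 0`` (unassigned) and are excluded from counts.
    If overlapping polygons both claim a centroid, the lowest cell id
    wins and a warning is emitted.
    """
    out = nuclei.copy()
    cell_ids = np.zeros(len(out), dtype=int)
    if isinstance(cells, np.ndarray):
        mask = cells
        for i, (r, c) in enumerate(zip(out["centroid_row"], out["centroid_col"])):
            ri = int(round(r))
            ci = int(round(c))
            if 0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]:
                cell_ids[i] = int(mask[ri, ci])
    else:
        polys = {int(k): (v if isinstance(v, Polygon) else Polygon(v))
                 for k, v in cells.items()}
        for i, (r, c) in enumerate(zip(out["centroid_row"], out["centroid_col"])):
            pt = Point(c, r)  # polygons are (x, y) = (col, row)
            claims = sorted(k for k, poly in polys.items() if poly.contains(pt))
            if len(claims) > 1:
                warnings.warn(
                    f"nucleus {out['nucleus_id'].iloc[i]} centroid claimed by cells "
                    f"{claims}; assigning to lowest id {claims[0]}"
                )
            if claims:
                cell_ids[i] = claims[0]
    out["cell_id"] = cell_ids
    return out


def count_multinucleated(assignment: pd.DataFrame,
                         condition: str = "",
                         timepoint_h: float | None = None) -> MultinucleationSummary:
    """Count cells by assigned-nucleus number and compute R_multi.

    N_all counts cells with ≥ 1 assigned nucleus, N_multi those with
    ≥ 2; R_multi = 100·N_multi/N_all.
    """
    assigned = assignment[assignment["cell_id"] > 0]
    counts = assigned.groupby("cell_id").size()
    n_all = int(len(counts))
    if n_all == 0:
        raise UndefinedRatioError("no cell holds an assigned nucleus; R_multi undefined")
    n_multi = int((counts >= 2).sum())
    return MultinucleationSummary(condition=condition, timepoint_h=timepoint_h,
                                  n_all=n_all, n_multi=n_multi,
                                  r_multi=100.0 * n_multi / n_all)


def nuclei_count_histogram(assignment: pd.DataFrame) -> pd.DataFrame:
    """Histogram of nuclei per cell: columns ``n_nuclei``, ``n_cells``.

    Odd counts (3, 5, ...) pass through unmodified — cells with odd
    nucleus numbers arise when a multinucleated cell divides unevenly.
    """
    assigned = assignment[assignment["cell_id"] > 0]
    per_cell = assigned.groupby("cell_id").size()
    hist = per_cell.value_counts().sort_index()
    return pd.DataFrame({"n_nuclei": hist.index.astype(int),
                         "n_cells": hist.values.astype(int)})
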
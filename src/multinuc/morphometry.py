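"""Cell and nucleus morphometry: areas, best-fit-ellipse axes, circularity,
and nuclear-to-cytoplasmic (Wilson) area ratios.

Shape descriptors per region:

* area ``S`` — pixel count (mask) or shoelace area (polygon), scaled by
  the pixel size to µm²;
* ``M`` — full major-axis length of the best-fit ellipse, i.e. the
  ellipse sharing the region's second central moments (the standard
  moment-based definition used by common image-analysis software);
* circularity ``α``.  Two conventions are carried side by side:

  - ``roundness`` (default): α = 4S/(πM²), which is 1 for a disk and
    approaches 0 for a line-like region — matching the usual
    normalization statement;
  - ``literal_eq``: α = 4πS/M², the same quantity scaled by π² (π² for
    a disk).  The two are related exactly by α_literal = π²·α_roundness.

The Wilson ratio S_nucleus/S_cell is computed per nucleus and, for
multinucleated cells, also as the sum over all nuclei of the cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.measure import regionprops

CONVENTIONS = ("roundness", "literal_eq")


@dataclass(frozen=True)
class EllipseFit:
    """Best-fit ellipse of a region (moment-matched); lengths in px."""

    major_px: float
    minor_px: float
    orientation_rad: float


@dataclass(frozen=True)
class ComparisonStats:
    """Unpaired two-sided t-test between two groups of one metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool


def _as_mask(region: np.ndarray | Polygon | "list", shape: tuple[int, int] | None = None
             ) -> np.ndarray:
    """Coerce a region (boolean mask, shapely polygon, or (x, y) vertex
    sequence) to a boolean mask; polygons are rasterized."""
    if isinstance(region, np.ndarray) and region.dtype != object:
        return np.asarray(region, bool)
    poly = region if isinstance(region, Polygon) else Polygon(region)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    xs, ys = poly.exterior.coords.xy
    if shape is None:
        shape = (int(math.ceil(max(ys))) + 2, int(math.ceil(max(xs))) + 2)
    rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def region_area(region: np.ndarray | Polygon | "list",
                pixel_size_um: float = 1.0) -> float:
    """Area of a region in µm².

    Masks are counted pixel-wise; polygons use the exact shoelace area
    (via shapely), both scaled by ``pixel_size_um²``.
    """
    if isinstance(region, np.ndarray) and region.dtype != object:
        area_px = float(np.count_nonzero(region))
    else:
        poly = region if isinstance(region, Polygon) else Polygon(region)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        area_px = float(poly.area)
    if area_px <= 0:
        raise ValueError("region is empty; area undefined")
    return area_px * pixel_size_um**2


def best_fit_ellipse(region: np.ndarray | Polygon | "list") -> EllipseFit:
    """Moment-based best-fit ellipse of a region.

    The ellipse has the same second central moments as the pixel region;
    its axes come from the eigenvalues of the inertia tensor (for an
    ideal ellipse of semi-axes a ≥ b this returns exactly 2a and 2b).
    Polygons are rasterized first.
    """
    mask = _as_mask(region)
    area = int(np.count_nonzero(mask))
    if area < 5:
        raise ValueError(f"region too small for a moment ellipse ({area} px, need >= 5)")
    props = regionprops(mask.astype(np.uint8))[0]
    return EllipseFit(major_px=float(props.axis_major_length),
                      minor_px=float(props.axis_minor_length),
                      orientation_rad=float(props.orientation))


def circularity(S: float, M: float, convention: str = "roundness") -> float:
    """Circularity from area S and best-fit-ellipse major axis M.

    S and M must be in consistent units (px² with px, or µm² with µm).
    ``roundness``: 4S/(πM²) (disk → 1); ``literal_eq``: 4πS/M²
    (disk → π²).
    """
    if S <= 0 or M <= 0:
        raise ValueError("area and major axis must be positive")
    if convention == "roundness":
        return 4.0 * S / (math.pi * M**2)
    if convention == "literal_eq":
        return 4.0 * math.pi * S / M**2
    raise ValueError(f"unknown circularity convention {convention!r}; "
                     f"choose one of {CONVENTIONS}")


def compute_cell_metrics(cell_mask: np.ndarray,
                         nucleus_mask: np.ndarray,
                         assignment: pd.DataFrame,
                         pixel_size_um: float = 0.664,
                         convention: str = "roundness"
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-nucleus morphometry tables.

    ``assignment`` maps nucleus_id → cell_id (from
    :func:`multinuc.nuclei.assign_nuclei_to_cells`); label ids must match
    the masks.  Cells without any assigned nucleus are excluded with a
    warning (they cannot be classified mono/multi).  Both circularity
    conventions are reported; ``convention`` selects which fills the
    plain ``alpha_*`` columns.

    Returns
    -------
    cells_df
        One row per analyzed cell: S_cell, M_cell, α_cell, nucleus
        count, group (``mono``/``multi``), per-cell summed Wilson ratio.
    nuclei_df
        One row per assigned nucleus: S_nucleus, M_nucleus, α_nucleus,
        parent cell, group, per-nucleus Wilson ratio in %.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown circularity convention {convention!r}")
    cell_props = {p.label: p for p in regionprops(np.asarray(cell_mask))}
    nuc_props = {p.label: p for p in regionprops(np.asarray(nucleus_mask))}
    per_cell = assignment[assignment["cell_id"] > 0].groupby("cell_id")

    n_excluded = len(set(cell_props) - set(per_cell.groups))
    if n_excluded:
        warnings.warn(f"{n_excluded} cell(s) have no assigned nucleus and are excluded")

    cell_rows, nuc_rows = [], []
    for cell_id, sub in per_cell:
        if cell_id not in cell_props:
            warnings.warn(f"assignment references unknown cell id {cell_id}; skipped")
            continue
        cp = cell_props[cell_id]
        S_cell_px = float(cp.area)
        M_cell_px = float(cp.axis_major_length)
        alpha_cell_round = circularity(S_cell_px, M_cell_px, "roundness")
        n_nuc = len(sub)
        group = "multi" if n_nuc >= 2 else "mono"
        ratios = []
        for nid in sub["nucleus_id"]:
            npp = nuc_props.get(int(nid))
            if npp is None:
                warnings.warn(f"assignment references unknown nucleus id {nid}; skipped")
                continue
            S_n_px = float(npp.area)
            M_n_px = float(npp.axis_major_length)
            alpha_n_round = circularity(S_n_px, M_n_px, "roundness")
            ratio = 100.0 * S_n_px / S_cell_px
            ratios.append(ratio)
            nuc_rows.append({
                "nucleus_id": int(nid), "cell_id": int(cell_id), "group": group,
                "S_nucleus_px2": S_n_px,
                "S_nucleus_um2": S_n_px * pixel_size_um**2,
                "M_nucleus_px": M_n_px,
                "M_nucleus_um": M_n_px * pixel_size_um,
                "alpha_nucleus": (alpha_n_round if convention == "roundness"
                                  else math.pi**2 * alpha_n_round),
                "alpha_nucleus_roundness": alpha_n_round,
                "alpha_nucleus_literal": math.pi**2 * alpha_n_round,
                "ratio_pct": ratio,
            })
        cell_rows.append({
            "cell_id": int(cell_id), "group": group, "n_nuclei": n_nuc,
            "S_cell_px2": S_cell_px,
            "S_cell_um2": S_cell_px * pixel_size_um**2,
            "M_cell_px": M_cell_px,
            "M_cell_um": M_cell_px * pixel_size_um,
            "alpha_cell": (alpha_cell_round if convention == "roundness"
                           else math.pi**2 * alpha_cell_round),
            "alpha_cell_roundness": alpha_cell_round,
            "alpha_cell_literal": math.pi**2 * alpha_cell_round,
            "summed_ratio_pct": float(sum(ratios)),
        })
    return pd.DataFrame(cell_rows), pd.DataFrame(nuc_rows)


def group_compare(table: pd.DataFrame, metric: str,
                  group_col: str = "group",
                  groups: tuple[str, str] = ("mono", "multi"),
                  alpha: float = 0.05) -> ComparisonStats:
    """Unpaired two-sided t-test of one metric between two groups.

    Uses the pooled-variance (classical unpaired) t statistic.  The
    caller chooses the statistical unit by passing the appropriate
    table: the per-nucleus table for nuclear metrics (n = number of
    nuclei) and the per-cell table for cellular metrics (n = number of
    cells), which avoids pseudo-replication.
    """
    a = table.loc[table[group_col] == groups[0], metric].to_numpy(float)
    b = table.loc[table[group_col] == groups[1], metric].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonStats(
        metric=metric, group_a=groups[0], group_b=groups[1],
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=float(t), p=float(p), significant=bool(p < alpha),
    )
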
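"""Synthetic microscopy images with exact ground truth.

Two families of inputs are emulated, matching the two measurement arms
of the pipeline:

* **Droplet silhouettes** — a lateral view of a sessile water drop on a
  dish, rendered as a dark filled circular cap on a bright background.
  The cap is parameterized by the contact angle θ and the contact-line
  (base) radius a; the apex height is then h = a·tan(θ/2) and the
  silhouette circle has radius R = a/sin θ.  Truth records θ, h, R, a
  and the baseline row exactly.

* **Cell fields** — non-overlapping elliptical cells, each containing
  1–5 elliptical nuclei strictly inside it, mimicking a fluorescence
  nucleus channel plus manually outlined cells.  The multinucleated
  fraction, the nuclei-per-cell distribution, cell sizes, shape
  eccentricities and nucleus:cell area-ratio distributions are all
  controllable, and a truth table records every per-object quantity the
  downstream morphometry measures.

All randomness flows through ``numpy.random.default_rng(seed)``;
identical specs with identical seeds produce bit-identical images and
truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi


class ImageSizeError(ValueError):
    """Requested image is too small to contain the object."""


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap at the requested density."""


# --------------------------------------------------------------------------
# droplets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DropletSpec:
    """Parameters of one synthetic droplet silhouette.

    ``base_radius_px`` is the contact-line radius a (half-width of the
    drop at the dish surface).  For contact angles above 90° the
    silhouette bulges wider than the base; the image is sized for the
    full silhouette.
    """

    contact_angle_deg: float
    base_radius_px: float = 100.0
    image_size: tuple[int, int] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    margin_px: int = 10
    background_level: int = 52000
    droplet_level: int = 6000

    def __post_init__(self) -> None:
        if not 0.0 < self.contact_angle_deg < 180.0:
            raise ValueError("contact_angle_deg must be in (0, 180)")
        if self.base_radius_px < 10:
            raise ValueError("base_radius_px must be >= 10 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DropletTruth:
    """Exact geometry of a generated droplet."""

    theta_deg: float
    h_px: float
    circle_radius_px: float   # radius of the silhouette circle (what a circle fit recovers)
    base_radius_px: float     # contact-line radius (what the half-angle method uses)
    baseline_row: int
    center: tuple[float, float]  # (x, y) of the silhouette-circle center


def droplet_geometry(contact_angle_deg: float, base_radius_px: float) -> tuple[float, float]:
    """Return (h, R) of the spherical cap: h = a·tan(θ/2), R = a/sin θ."""
    th = math.radians(contact_angle_deg)
    h = base_radius_px * math.tan(th / 2.0)
    R = base_radius_px / math.sin(th)
    return h, R


def generate_droplet_image(spec: DropletSpec) -> tuple[np.ndarray, DropletTruth]:
    """Render a filled circular-cap silhouette and return it with truth.

    The droplet is dark on a bright background, as in a backlit lateral
    photograph.  Optional additive Gaussian pixel noise (``noise_sd`` in
    gray levels) is applied to the whole frame.
    """
    a = spec.base_radius_px
    h, R = droplet_geometry(spec.contact_angle_deg, a)
    half_w = R if spec.contact_angle_deg > 90.0 else a
    m = spec.margin_px
    need_rows = int(math.ceil(h)) + m + 6  # a few background rows below the baseline
    need_cols = int(math.ceil(2 * half_w)) + 2 * m
    if spec.image_size is None:
        nrows, ncols = need_rows, need_cols
    else:
        nrows, ncols = spec.image_size
        if nrows < need_rows or ncols < need_cols:
            raise ImageSizeError(
                f"image_size {spec.image_size} too small for the cap; "
                f"need at least ({need_rows}, {need_cols})"
            )
    baseline_row = nrows - 6
    cx = (ncols - 1) / 2.0
    cy = baseline_row - h + R  # circle center row (below apex; rows increase downward)

    rr, cc = np.mgrid[0:nrows, 0:ncols]
    inside = ((cc - cx) ** 2 + (rr - cy) ** 2 <= R**2) & (rr <= baseline_row)
    img = np.full((nrows, ncols), spec.background_level, dtype=float)
    img[inside] = spec.droplet_level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = DropletTruth(
        theta_deg=spec.contact_angle_deg, h_px=h, circle_radius_px=R,
        base_radius_px=a, baseline_row=baseline_row, center=(cx, cy),
    )
    return img, truth


# --------------------------------------------------------------------------
# cell fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellFieldSpec:
    """Parameters of one synthetic cell field.

    Area-ratio distributions are (mean, SD) in percent of the cell area:
    ``mono_ratio_pct`` constrains the single nucleus of mononuclear
    cells; for multinucleated cells ``ratio_mode`` selects whether each
    nucleus is drawn from ``per_nucleus_ratio_pct`` independently or the
    whole-cell sum is drawn from ``summed_ratio_pct`` and split among
    the nuclei.  Defaults are the measured nucleus:cell ratios of the
    study system 48 h after seeding.
    """

    n_cells: int = 100
    frac_multinucleated: float = 0.0
    nuclei_count_dist: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.80, 3: 0.15, 4: 0.04, 5: 0.01}
    )
    cell_area_um2: tuple[float, float] = (1600.0, 400.0)
    cell_area_bounds_um2: tuple[float, float] = (600.0, 3400.0)
    mono_ratio_pct: tuple[float, float] = (5.9, 2.1)
    per_nucleus_ratio_pct: tuple[float, float] = (2.4, 0.6)
    summed_ratio_pct: tuple[float, float] = (5.0, 1.3)
    ratio_mode: str = "per_nucleus"
    ratio_bounds_pct: tuple[float, float] = (0.4, 25.0)
    cell_eccentricity_range: tuple[float, float] = (0.2, 0.7)
    nucleus_eccentricity_range: tuple[float, float] = (0.0, 0.6)
    pixel_size_um: float = 0.664
    image_size: tuple[int, int] | None = None
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    boundary_perturbation: float = 0.0
    seed: int = 0
    nucleus_level: int = 22000
    background_level: int = 300

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.frac_multinucleated <= 1.0:
            raise ValueError("frac_multinucleated must be in [0, 1]")
        if self.ratio_mode not in ("per_nucleus", "summed"):
            raise ValueError("ratio_mode must be 'per_nucleus' or 'summed'")
        total = sum(self.nuclei_count_dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("nuclei_count_dist probabilities must sum to 1")
        if any(k < 2 for k in self.nuclei_count_dist):
            raise ValueError("multinucleated cells have >= 2 nuclei")
        if not 0.0 <= self.boundary_perturbation < 0.15:
            raise ValueError("boundary_perturbation must be small (< 0.15) to keep "
                             "truth areas within tolerance")


@dataclass
class CellFieldTruth:
    """Ground truth of a generated cell field.

    ``cells`` has one row per cell (areas, major axis, circularity,
    nucleus count, multinucleated flag); ``nuclei`` one row per nucleus
    (geometry plus parent cell and area ratio).  Areas and axes are the
    analytic ellipse values, stored in both px and µm; mask pixel counts
    agree with them within rasterization tolerance.
    """

    cells: pd.DataFrame
    nuclei: pd.DataFrame
    r_multi: float
    pixel_size_um: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Normal draws rejected outside [lo, hi] (exact truncated normal)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _axes_from_area_ecc(area_px: float, ecc: float) -> tuple[float, float]:
    """Semi-axes (a, b) of an ellipse with given area and eccentricity."""
    q = math.sqrt(1.0 - ecc**2)  # b/a
    a = math.sqrt(area_px / (math.pi * q))
    return a, a * q


def _ellipse_mask_block(a: float, b: float, phi: float, c_row: float, c_col: float,
                        shape: tuple[int, int],
                        perturb: tuple[np.ndarray, float] | None = None
                        ) -> tuple[slice, slice, np.ndarray]:
    """Boolean raster of an ellipse, returned as (row slice, col slice, block)."""
    rad = a * (1.0 + (perturb[1] if perturb else 0.0)) + 2.0
    r0 = max(int(math.floor(c_row - rad)), 0)
    r1 = min(int(math.ceil(c_row + rad)) + 1, shape[0])
    c0 = max(int(math.floor(c_col - rad)), 0)
    c1 = min(int(math.ceil(c_col + rad)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - c_row
    dx = cc - c_col
    # rotate into the ellipse frame; phi measured from the column axis
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    if perturb is None:
        block = rho2 <= 1.0
    else:
        coeffs, amp = perturb
        ang = np.arctan2(v / b, u / a)
        mod = np.zeros_like(ang)
        for k, (ck, sk) in enumerate(coeffs, start=2):
            mod += ck * np.cos(k * ang) + sk * np.sin(k * ang)
        block = np.sqrt(rho2) <= 1.0 + amp * mod
    return slice(r0, r1), slice(c0, c1), block


def generate_cell_field(spec: CellFieldSpec
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, CellFieldTruth]:
    """Generate (nucleus_image, cell_label_mask, nucleus_label_mask, truth).

    Exactly ``round(n_cells × frac_multinucleated)`` cells receive ≥ 2
    nuclei.  Cells are laid out on a jittered grid, which guarantees
    they never overlap; nuclei are placed by rejection sampling strictly
    inside their cell and pairwise disjoint.  The nucleus image is a
    bright-ellipse rendering with optional Gaussian blur and noise.

    Raises
    ------
    ImageSizeError
        If an explicit ``image_size`` cannot hold ``n_cells`` at the
        sampled sizes (the error names the minimum size).
    PlacementError
        If nuclei cannot be placed after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    n_multi = int(round(n * spec.frac_multinucleated))
    ps = spec.pixel_size_um

    # --- sample per-cell geometry ------------------------------------------
    areas_um2 = _truncated_normal(rng, *spec.cell_area_um2, *spec.cell_area_bounds_um2, n)
    areas_px = areas_um2 / ps**2
    eccs = rng.uniform(*spec.cell_eccentricity_range, n)
    phis = rng.uniform(0.0, math.pi, n)
    semi = np.array([_axes_from_area_ecc(A, e) for A, e in zip(areas_px, eccs)])

    multi_flag = np.zeros(n, dtype=bool)
    multi_flag[rng.permutation(n)[:n_multi]] = True

    ks = sorted(spec.nuclei_count_dist)
    pk = np.array([spec.nuclei_count_dist[k] for k in ks], dtype=float)
    pk /= pk.sum()
    n_nuclei = np.where(multi_flag, rng.choice(ks, size=n, p=pk), 1)

    # --- grid placement -----------------------------------------------------
    g = int(math.ceil(math.sqrt(n)))
    a_max = float(semi[:, 0].max()) * (1.0 + spec.boundary_perturbation)
    tile_min = int(math.ceil(2 * (a_max + 2.0)))
    if spec.image_size is None:
        nrows = ncols = g * tile_min
        tile_r = tile_c = float(tile_min)
    else:
        nrows, ncols = spec.image_size
        tile_r, tile_c = nrows / g, ncols / g
        if min(tile_r, tile_c) < tile_min:
            raise ImageSizeError(
                f"image_size {spec.image_size} cannot hold {n} cells of this size "
                f"without overlap; need at least ({g * tile_min}, {g * tile_min})"
            )
    centers = np.empty((n, 2))
    for i in range(n):
        ti, tj = divmod(i, g)
        pad = semi[i, 0] * (1.0 + spec.boundary_perturbation) + 1.0
        jr = (tile_r / 2.0 - pad)
        jc = (tile_c / 2.0 - pad)
        centers[i] = (
            (ti + 0.5) * tile_r + rng.uniform(-jr, jr),
            (tj + 0.5) * tile_c + rng.uniform(-jc, jc),
        )

    # --- nucleus sizes ------------------------------------------------------
    lo, hi = spec.ratio_bounds_pct
    nuc_ratios: list[np.ndarray] = []
    for i in range(n):
        k = int(n_nuclei[i])
        if not multi_flag[i]:
            r = _truncated_normal(rng, *spec.mono_ratio_pct, lo, hi, 1)
        elif spec.ratio_mode == "per_nucleus":
            r = _truncated_normal(rng, *spec.per_nucleus_ratio_pct, lo, hi, k)
        else:
            total = _truncated_normal(rng, *spec.summed_ratio_pct, lo, hi, 1)[0]
            w = rng.dirichlet(np.full(k, 25.0))  # near-even split with mild variation
            r = total * w
        nuc_ratios.append(r)

    # --- nucleus placement (rejection, strictly inside the cell) ------------
    cell_rows, nuc_rows = [], []
    nuc_geoms = []  # (a, b, phi, c_row, c_col) per nucleus, raster order by cell
    for i in range(n):
        A_cell, B_cell = semi[i]
        phi_c = phis[i]
        ratios = nuc_ratios[i]
        k = len(ratios)
        placed: list[tuple[float, float, float]] = []  # (row, col, circumradius)
        geoms: list[tuple[float, float, float, float, float]] = []
        for j in range(k):
            area_n = ratios[j] / 100.0 * areas_px[i]
            ecc_n = rng.uniform(*spec.nucleus_eccentricity_range)
            a_n, b_n = _axes_from_area_ecc(area_n, ecc_n)
            phi_n = rng.uniform(0.0, math.pi)
            ok = False
            for _ in range(400):
                # sample in the cell-ellipse frame, shrunk so the nucleus
                # circumcircle stays strictly inside the cell boundary
                sa, sb = A_cell - a_n - 1.5, B_cell - a_n - 1.5
                if sa <= 0 or sb <= 0:
                    break
                t = math.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * math.pi)
                u, v = sa * t * math.cos(ang), sb * t * math.sin(ang)
                cr = centers[i, 0] + u * math.sin(phi_c) + v * math.cos(phi_c)
                cc_ = centers[i, 1] + u * math.cos(phi_c) - v * math.sin(phi_c)
                # >= 3 px clearance between nuclei so 8-connected labeling
                # can never merge neighbours
                if all(math.hypot(cr - pr, cc_ - pc) > a_n + pa + 3.0
                       for pr, pc, pa in placed):
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place nucleus {j + 1}/{k} inside cell {i + 1}; "
                    "reduce nucleus ratios, counts, or cell eccentricity"
                )
            placed.append((cr, cc_, a_n))
            geoms.append((a_n, b_n, phi_n, cr, cc_))
        nuc_geoms.append(geoms)

    # --- rasterize ----------------------------------------------------------
    cell_mask = np.zeros((nrows, ncols), dtype=np.uint16)
    nucleus_mask = np.zeros((nrows, ncols), dtype=np.uint16)
    nuc_id = 0
    for i in range(n):
        A_cell, B_cell = semi[i]
        perturb = None
        if spec.boundary_perturbation > 0:
            coeffs = rng.normal(0.0, 1.0, (3, 2)) / math.sqrt(3.0)
            perturb = (coeffs, spec.boundary_perturbation)
        rs, cs, blk = _ellipse_mask_block(A_cell, B_cell, phis[i], centers[i, 0],
                                          centers[i, 1], (nrows, ncols), perturb)
        cell_mask[rs, cs][blk] = i + 1
        for (a_n, b_n, phi_n, cr, cc_) in nuc_geoms[i]:
            nuc_id += 1
            rs, cs, blk = _ellipse_mask_block(a_n, b_n, phi_n, cr, cc_, (nrows, ncols))
            nucleus_mask[rs, cs][blk] = nuc_id

    # --- truth tables -------------------------------------------------------
    cell_rows = []
    for i in range(n):
        A_cell, B_cell = semi[i]
        cell_rows.append({
            "cell_id": i + 1,
            "center_row": centers[i, 0], "center_col": centers[i, 1],
            "area_px2": areas_px[i], "area_um2": areas_um2[i],
            "major_px": 2 * A_cell, "major_um": 2 * A_cell * ps,
            "minor_px": 2 * B_cell, "minor_um": 2 * B_cell * ps,
            "orientation_rad": phis[i], "eccentricity": eccs[i],
            "circularity": B_cell / A_cell,
            "n_nuclei": int(n_nuclei[i]),
            "multinucleated": bool(multi_flag[i]),
            "summed_ratio_pct": float(np.sum(nuc_ratios[i])),
        })
    nuc_rows = []
    nuc_id = 0
    for i in range(n):
        for j, (a_n, b_n, phi_n, cr, cc_) in enumerate(nuc_geoms[i]):
            nuc_id += 1
            area_n_px = math.pi * a_n * b_n
            nuc_rows.append({
                "nucleus_id": nuc_id, "cell_id": i + 1,
                "center_row": cr, "center_col": cc_,
                "area_px2": area_n_px, "area_um2": area_n_px * ps**2,
                "major_px": 2 * a_n, "major_um": 2 * a_n * ps,
                "minor_px": 2 * b_n, "minor_um": 2 * b_n * ps,
                "orientation_rad": phi_n,
                "circularity": b_n / a_n,
                "ratio_pct": float(nuc_ratios[i][j]),
            })
    truth = CellFieldTruth(
        cells=pd.DataFrame(cell_rows),
        nuclei=pd.DataFrame(nuc_rows),
        r_multi=100.0 * n_multi / n,
        pixel_size_um=ps,
    )

    # --- render the fluorescence nucleus channel ----------------------------
    img = np.full((nrows, ncols), float(spec.background_level))
    jitter = rng.uniform(0.9, 1.1, max(nuc_id, 1))
    img[nucleus_mask > 0] = spec.nucleus_level
    for nid in range(1, nuc_id + 1):
        img[nucleus_mask == nid] = spec.nucleus_level * jitter[nid - 1]
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return img, cell_mask, nucleus_mask, truth


# --------------------------------------------------------------------------
# timecourses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One culture condition with its multinucleation trajectory.

    ``trajectory`` maps timepoint (hours) to the target percentage of
    multinucleated cells; an optional per-timepoint nuclei-count
    distribution models the drift toward higher counts at later times.
    """

    label: str
    trajectory: Mapping[float, float]
    nuclei_count_dists: Mapping[float, Mapping[int, float]] | None = None

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 100.0 for v in self.trajectory.values()):
            raise ValueError("trajectory percentages must lie in [0, 100]")


def generate_timecourse(conditions: Sequence[Condition],
                        base_spec: CellFieldSpec | None = None,
                        seed: int = 0) -> dict[tuple[str, float], tuple]:
    """One cell field per condition × timepoint.

    Returns a dict keyed by ``(condition label, timepoint_h)`` whose
    values are the ``generate_cell_field`` tuples.  Per-field seeds are
    spawned deterministically from ``seed`` so any single field can be
    regenerated in isolation.
    """
    base = base_spec if base_spec is not None else CellFieldSpec()
    out: dict[tuple[str, float], tuple] = {}
    idx = 0
    for cond in conditions:
        for t in sorted(cond.trajectory):
            child_seed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0]
                             % (2**31))
            kwargs = dict(
                frac_multinucleated=cond.trajectory[t] / 100.0,
                seed=child_seed,
            )
            if cond.nuclei_count_dists and t in cond.nuclei_count_dists:
                kwargs["nuclei_count_dist"] = dict(cond.nuclei_count_dists[t])
            out[(cond.label, t)] = generate_cell_field(replace(base, **kwargs))
            idx += 1
    return out


def timecourse_truth_table(fields: Mapping[tuple[str, float], tuple]) -> pd.DataFrame:
    """Aggregate truth R_multi per condition × timepoint into a tidy table."""
    rows = []
    for (label, t), (_, _, _, truth) in sorted(fields.items()):
        n_all = len(truth.cells)
        n_multi = int(truth.cells["multinucleated"].sum())
        rows.append({"condition": label, "timepoint_h": t, "n_all": n_all,
                     "n_multi": n_multi, "r_multi": truth.r_multi})
    return pd.DataFrame(rows)
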
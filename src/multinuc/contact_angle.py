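"""Sessile-drop contact-angle measurement from lateral silhouette images.

A water droplet resting on a dish is, at the ~5 µL scale, close to a
spherical cap.  Its lateral silhouette is therefore an arc of a circle.
The measurement chain implemented here mirrors the classical manual
procedure:

1. digitize points on the droplet edge (manually supplied, or extracted
   automatically from a binarized silhouette),
2. fit a circle ``x² + y² + Ax + By + C = 0`` to the points by linear
   least squares (the Kåsa normal equations), giving the radius
   ``r = sqrt(A²/4 + B²/4 − C)``,
3. measure the apex height ``h`` of the droplet above the dish surface,
4. apply the half-angle method, ``θ = 2·arctan(h/a)``, where ``a`` is the
   radius of the contact line (the chord the fitted circle cuts on the
   baseline), recovered from the fit as ``a = sqrt(h·(2r − h))``.

For a spherical cap the half-angle identity ``h = a·tan(θ/2)`` is exact
for every θ in (0°, 180°), so steps 2–4 recover the contact angle from
geometry alone.  Larger θ means a less hydrophilic (more hydrophobic)
surface.

Image convention: arrays are indexed ``(row, col)`` with rows increasing
downward; the dish surface is the ``baseline_row`` and the droplet
occupies rows above (smaller than) it.  Digitized points are ``(x, y)``
= ``(col, row)`` pairs, matching how edge coordinates are read off an
image viewer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops


class CircleFitError(ValueError):
    """Raised when a circle cannot be fitted (too few or collinear points)."""


class EmptySilhouetteError(ValueError):
    """Raised when no droplet foreground is found above the baseline."""


@dataclass(frozen=True)
class EdgePointSet:
    """Digitized droplet-edge coordinates.

    Parameters
    ----------
    points
        ``(n, 2)`` array of ``(x, y)`` pixel coordinates, ``n >= 3``.
    baseline_row
        Row (y) of the dish surface; all points must lie on or above it
        (``y <= baseline_row``).
    """

    points: np.ndarray
    baseline_row: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y) pairs")
        if pts.shape[0] < 3:
            raise CircleFitError(f"need at least 3 edge points, got {pts.shape[0]}")
        if np.any(pts[:, 1] > self.baseline_row + 1e-9):
            raise ValueError("edge points must lie on or above the baseline row")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle ``x² + y² + Ax + By + C = 0``.

    ``center = (−A/2, −B/2)`` and ``r = sqrt(A²/4 + B²/4 − C)``.
    ``rms_residual`` is the root-mean-square radial distance of the
    points from the fitted circle, in pixels.
    """

    A: float
    B: float
    C: float
    center: tuple[float, float] = field(init=False)
    r: float = field(init=False)
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        cx, cy = -self.A / 2.0, -self.B / 2.0
        r2 = self.A**2 / 4.0 + self.B**2 / 4.0 - self.C
        if not np.isfinite(r2) or r2 <= 0:
            raise CircleFitError("fitted parameters do not describe a real circle")
        object.__setattr__(self, "center", (cx, cy))
        object.__setattr__(self, "r", math.sqrt(r2))


@dataclass(frozen=True)
class DropletObservation:
    """One droplet's full measurement record."""

    source_id: str
    h: float
    fit: CircleFit
    base_radius: float
    theta_deg: float


def fit_circle(points: EdgePointSet | np.ndarray) -> CircleFit:
    """Fit a circle to edge points by linear least squares (Kåsa).

    Minimizes ``Σ (x² + y² + Ax + By + C)²`` by solving the 3×3 normal
    equations.  The solve is done on mean-centered coordinates (where the
    normal matrix is nearly diagonal) and the parameters are shifted
    back, which keeps the system well conditioned for points far from
    the image origin.

    Raises
    ------
    CircleFitError
        If fewer than 3 points are given or the points are (near)
        collinear, which makes the normal system singular.
    """
    pts = points.points if isinstance(points, EdgePointSet) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise CircleFitError(f"need at least 3 points to fit a circle, got {n}")

    mean = pts.mean(axis=0)
    u = pts[:, 0] - mean[0]
    v = pts[:, 1] - mean[1]

    # Kåsa normal equations in the centered frame (Σu = Σv = 0).
    M = np.array(
        [
            [np.sum(u * u), np.sum(u * v), 0.0],
            [np.sum(u * v), np.sum(v * v), 0.0],
            [0.0, 0.0, float(n)],
        ]
    )
    rhs = -np.array(
        [
            np.sum(u**3 + u * v**2),
            np.sum(u**2 * v + v**3),
            np.sum(u**2 + v**2),
        ]
    )
    # Collinear points make the upper 2x2 block singular.
    scale = np.sum(u * u) + np.sum(v * v)
    if scale <= 0 or np.linalg.cond(M) > 1e12:
        raise CircleFitError("edge points are collinear or degenerate; cannot fit a circle")
    a, b, c = np.linalg.solve(M, rhs)

    # Un-center: circle center in original coordinates.
    cx = -a / 2.0 + mean[0]
    cy = -b / 2.0 + mean[1]
    r2 = a**2 / 4.0 + b**2 / 4.0 - c
    if r2 <= 0:
        raise CircleFitError("degenerate fit: non-positive squared radius")
    r = math.sqrt(r2)

    dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(A=-2.0 * cx, B=-2.0 * cy, C=cx**2 + cy**2 - r2, rms_residual=rms)


def _binarize(image: np.ndarray, threshold: float | str = "otsu",
              foreground: str = "dark") -> np.ndarray:
    """Return a boolean droplet mask.

    ``foreground`` is ``'dark'`` (droplet darker than background, the
    usual backlit silhouette), ``'bright'``, or ``'auto'`` (pick the
    minority class).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    dark = img <= t
    if foreground == "dark":
        return dark
    if foreground == "bright":
        return ~dark
    return dark if dark.sum() <= dark.size / 2 else ~dark


def detect_baseline(mask: np.ndarray, method: str = "bottom") -> int:
    """Locate the dish-surface row of a droplet mask.

    ``'bottom'`` (default): the bottommost row containing foreground —
    correct for any contact angle since the silhouette ends at the dish.
    ``'max_width'``: the row of maximal foreground width — only valid
    for θ ≤ 90°, where the droplet is widest at the surface.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise EmptySilhouetteError("no foreground pixels found in the image")
    if method == "bottom":
        return int(rows[-1])
    if method == "max_width":
        widths = mask.sum(axis=1)
        return int(np.argmax(widths))
    raise ValueError(f"unknown baseline detection method: {method!r}")


def measure_height(image: np.ndarray, baseline_row: int, *,
                   threshold: float | str = "otsu",
                   foreground: str = "dark") -> float:
    """Apex height h of the droplet above the baseline, in pixel rows.

    h = baseline_row − topmost silhouette row (rows increase downward).
    """
    mask = _binarize(image, threshold, foreground)
    above = mask[: int(baseline_row) + 1]
    rows = np.flatnonzero(above.any(axis=1))
    if rows.size == 0:
        raise EmptySilhouetteError("no droplet silhouette found above the baseline")
    return float(baseline_row - rows[0])


def contact_angle(h: float, r: float) -> float:
    """Half-angle method: θ = 2·arctan(h/r), in degrees.

    ``r`` is the contact-line radius (half-width of the droplet at the
    dish surface); for a spherical cap the identity is exact for any
    contact angle in (0°, 180°).
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if h < 0:
        raise ValueError(f"height must be non-negative, got {h}")
    return math.degrees(2.0 * math.atan2(h, r))


def extract_edge_points(image: np.ndarray, baseline_row: int, *,
                        n_points: int = 20,
                        threshold: float | str = "otsu",
                        foreground: str = "dark") -> EdgePointSet:
    """Automatically digitize droplet-edge points from a silhouette image.

    The image is binarized, the largest connected foreground component
    above the baseline is kept, and for each of its rows the leftmost
    and rightmost foreground columns become candidate edge points.  The
    candidates are ordered along the arc (left flank down-up, apex,
    right flank up-down) and subsampled to ``n_points`` roughly uniform
    in arc position — the automated analogue of spotting points on the
    droplet edge by hand.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    mask = _binarize(image, threshold, foreground)
    mask = mask[: int(baseline_row) + 1]
    if not mask.any():
        raise EmptySilhouetteError("no droplet silhouette found above the baseline")
    lab = sk_label(mask, connectivity=2)
    largest = max(regionprops(lab), key=lambda p: p.area)
    mask = lab == largest.label

    rows = np.flatnonzero(mask.any(axis=1))
    left, right = [], []
    for i in rows:
        cols = np.flatnonzero(mask[i])
        left.append((float(cols[0]), float(i)))
        right.append((float(cols[-1]), float(i)))
    # Arc order: up the left flank (bottom to top), then down the right.
    arc = left[::-1] + right
    # Drop duplicated apex point if flanks meet in one pixel.
    ordered = [arc[0]]
    for p in arc[1:]:
        if p != ordered[-1]:
            ordered.append(p)
    idx = np.unique(np.round(np.linspace(0, len(ordered) - 1, n_points)).astype(int))
    pts = np.array([ordered[i] for i in idx], dtype=float)
    return EdgePointSet(points=pts, baseline_row=float(baseline_row))


def base_radius_from_fit(fit: CircleFit, h: float) -> float:
    """Contact-line radius from the fitted circle radius and the height.

    For a spherical cap of (fitted) circle radius r and apex height h,
    the chord on the baseline has half-width a = sqrt(h·(2r − h)).
    """
    if not 0 < h < 2 * fit.r:
        raise ValueError(
            f"height {h:.3g} px incompatible with fitted radius {fit.r:.3g} px "
            "(need 0 < h < 2r for a spherical cap)"
        )
    return math.sqrt(h * (2.0 * fit.r - h))


def measure_droplet(source: np.ndarray | EdgePointSet, *,
                    baseline_row: int | None = None,
                    baseline_method: str = "bottom",
                    n_points: int = 20,
                    threshold: float | str = "otsu",
                    foreground: str = "dark",
                    source_id: str = "") -> DropletObservation:
    """Full contact-angle measurement of one droplet.

    ``source`` may be a lateral silhouette image (edge points are then
    extracted automatically) or a pre-digitized :class:`EdgePointSet`.
    With an image, ``h`` is measured directly from the silhouette; with
    edge points alone, ``h`` is taken from the fitted circle's apex
    (``h = r − (center_y − baseline_row)``).
    """
    if isinstance(source, EdgePointSet):
        pts = source
        fit = fit_circle(pts)
        h = fit.r - (fit.center[1] - pts.baseline_row)
        if h <= 0:
            raise EmptySilhouetteError("fitted circle lies entirely below the baseline")
    else:
        image = np.asarray(source)
        if baseline_row is None:
            baseline_row = detect_baseline(
                _binarize(image, threshold, foreground), method=baseline_method
            )
        pts = extract_edge_points(image, baseline_row, n_points=n_points,
                                  threshold=threshold, foreground=foreground)
        fit = fit_circle(pts)
        h = measure_height(image, baseline_row, threshold=threshold,
                           foreground=foreground)
    a = base_radius_from_fit(fit, h)
    theta = contact_angle(h, a)
    return DropletObservation(source_id=source_id, h=float(h), fit=fit,
                              base_radius=a, theta_deg=theta)


def aggregate_by_group(observations: Sequence[DropletObservation],
                       groups: Iterable[str]) -> pd.DataFrame:
    """Per-group mean ± SD contact angle, as reported for dish types.

    SD uses the n−1 (sample) denominator; single-observation groups get
    SD 0 with a warning.
    """
    groups = list(groups)
    if len(groups) != len(observations):
        raise ValueError("one group label per observation is required")
    if not observations:
        raise ValueError("no observations to aggregate")
    df = pd.DataFrame({
        "group": groups,
        "theta_deg": [o.theta_deg for o in observations],
    })
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        sd = float(sub["theta_deg"].std(ddof=1)) if n > 1 else 0.0
        if n == 1:
            warnings.warn(f"group {g!r} has a single observation; SD set to 0")
        rows.append({"group": g, "n": n,
                     "mean_theta_deg": float(sub["theta_deg"].mean()),
                     "sd_theta_deg": sd})
    return pd.DataFrame(rows)
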
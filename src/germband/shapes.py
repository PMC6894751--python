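"""Per-cell shape descriptors and spatiotemporal heat maps.

Cell shapes are summarised by best-fit ellipses constrained to have the
same area and centroid as the cell outline; the free parameters (aspect
ratio and orientation) minimise the area of mismatch (symmetric
difference) between outline and ellipse.  From the fitted ellipse
follow the anisotropy ``ln(a/b)``, the orientation of the long axis
relative to AP, the composite axial shape elongation
``(orientation/45 - 1) * ln(a/b)`` (negative for AP-elongated cells,
positive for DV-elongated ones), and the projected AP/DV cell lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binned_statistic_2d
from shapely.geometry import Polygon

from .tracks import AxisFrame, EmbryoTracks, _parse_outline, _polygon_centroid

__all__ = [
    "FittedEllipse",
    "ShapeScore",
    "fit_cell_ellipse",
    "moment_ellipse",
    "axial_shape_elongation",
    "axis_projected_cell_length",
    "classify_interface_orientation",
    "spatiotemporal_heatmap",
    "shape_table",
]

_ELLIPSE_NGON = 128


@dataclass(frozen=True)
class FittedEllipse:
    """Area- and centroid-constrained best-fit ellipse of a cell outline."""

    centroid: tuple[float, float]
    a: float                 #: semi-major axis, μm
    b: float                 #: semi-minor axis, μm (a >= b)
    orientation_deg: float   #: major-axis angle to AP, degrees in [0, 180)
    mismatch_area: float     #: symmetric-difference area against the outline

    @property
    def anisotropy(self) -> float:
        """Elongation log-ratio ``ln(a/b) >= 0``."""
        return float(np.log(self.a / self.b))


@dataclass(frozen=True)
class ShapeScore:
    anisotropy: float
    orientation_deg: float   #: folded to [0, 90] relative to AP
    axial_elongation: float


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, theta_rad: float) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, _ELLIPSE_NGON, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    return Polygon(
        np.column_stack([cx + ct * x - st * y, cy + st * x + ct * y])
    )


def moment_ellipse(polygon: np.ndarray) -> tuple[float, float, float]:
    """Aspect log-ratio and orientation from the polygon's second moments.

    Returns ``(rho, theta_rad, area)`` where ``rho = ln(a/b)`` of the
    inertia-equivalent ellipse; used to initialise the mismatch fit.
    """
    p = np.asarray(polygon, dtype=float)
    c = _polygon_centroid(p)
    x, y = p[:, 0] - c[0], p[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cr = x * yn - xn * y
    area = 0.5 * cr.sum()
    # second area moments of a polygon about its centroid
    ixx = np.sum(cr * (y * y + y * yn + yn * yn)) / 12.0
    iyy = np.sum(cr * (x * x + x * xn + xn * xn)) / 12.0
    ixy = np.sum(cr * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]]) / area  # sign cancels for CW rings
    evals, evecs = np.linalg.eigh(cov)
    lam_small, lam_big = evals
    major = evecs[:, 1]
    theta = float(np.arctan2(major[1], major[0])) % np.pi
    rho = 0.25 * float(np.log(max(lam_big, 1e-300) / max(lam_small, 1e-300)))
    return rho, theta, float(abs(area))


def fit_cell_ellipse(polygon: np.ndarray) -> FittedEllipse:
    """Fit the constrained best-fit ellipse to a cell outline.

    The ellipse keeps the polygon's exact area and centroid; its aspect
    ratio and orientation minimise the symmetric-difference area,
    evaluated on a 128-gon approximation of the ellipse.  The optimiser
    is a Nelder-Mead refinement started from the second-moment ellipse,
    with fixed settings so results are deterministic.
    """
    p = np.asarray(polygon, dtype=float)
    if len(p) < 3:
        raise ValueError("outline needs at least 3 points")
    sp = Polygon(p)
    if not sp.is_simple or sp.area <= 0:
        raise ValueError("degenerate or self-intersecting outline")
    rho0, theta0, area = moment_ellipse(p)
    c = _polygon_centroid(p)
    r_eq = np.sqrt(area / np.pi)

    def mismatch(params: np.ndarray) -> float:
        rho, theta = abs(params[0]), params[1]
        a = r_eq * np.exp(rho / 2.0)
        b = r_eq * np.exp(-rho / 2.0)
        ell = _ellipse_polygon(c[0], c[1], a, b, theta)
        return sp.symmetric_difference(ell).area

    res = minimize(
        mismatch,
        x0=np.array([rho0, theta0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200},
    )
    rho = abs(float(res.x[0]))
    theta = float(res.x[1]) % np.pi
    return FittedEllipse(
        centroid=(float(c[0]), float(c[1])),
        a=float(r_eq * np.exp(rho / 2.0)),
        b=float(r_eq * np.exp(-rho / 2.0)),
        orientation_deg=float(np.degrees(theta)),
        mismatch_area=float(res.fun),
    )


def _fold_to_90(angle_deg: float) -> float:
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


def axial_shape_elongation(
    ellipse: FittedEllipse, axes: AxisFrame | None = None
) -> ShapeScore:
    """Composite score ``(orientation/45 - 1) * ln(a/b)``.

    Orientation is measured to the AP axis and folded into [0, 90], so
    the score is 0 for isotropic cells and for cells oriented at 45°,
    negative for AP-elongated and positive for DV-elongated cells.
    """
    axes = axes or AxisFrame()
    theta = np.deg2rad(ellipse.orientation_deg)
    major = np.array([np.cos(theta), np.sin(theta)])
    orient = axes.angle_to_ap(major)  # already in [0, 90]
    rho = ellipse.anisotropy
    return ShapeScore(
        anisotropy=rho,
        orientation_deg=orient,
        axial_elongation=(orient / 45.0 - 1.0) * rho,
    )


def axis_projected_cell_length(
    ellipse: FittedEllipse, axis: str, axes: AxisFrame | None = None
) -> float:
    """Diameter of the fitted ellipse along the AP or DV direction.

    The width of an ellipse along a unit direction at angle ``phi``
    from its major axis is ``2 sqrt(a^2 cos^2 phi + b^2 sin^2 phi)``.
    """
    axes = axes or AxisFrame()
    if axis not in ("AP", "DV"):
        raise ValueError("axis must be 'AP' or 'DV'")
    u = np.asarray(axes.ap if axis == "AP" else axes.dv, dtype=float)
    theta = np.deg2rad(ellipse.orientation_deg)
    major = np.array([np.cos(theta), np.sin(theta)])
    cphi = np.clip(abs(float(u @ major)), 0.0, 1.0)
    sphi2 = 1.0 - cphi * cphi
    return float(2.0 * np.sqrt(ellipse.a**2 * cphi * cphi + ellipse.b**2 * sphi2))


def classify_interface_orientation(
    endpoints: np.ndarray, axes: AxisFrame | None = None
) -> tuple[str, float]:
    """Classify an interface as AP- or DV-oriented.

    The vertex–vertex line at less than 45° from the AP axis is
    AP-oriented, at more than 45° DV-oriented; exactly 45° counts as
    DV-oriented (deterministic tie-break).
    """
    axes = axes or AxisFrame()
    ends = np.asarray(endpoints, dtype=float)
    vec = ends[1] - ends[0]
    if np.linalg.norm(vec) == 0:
        raise ValueError("zero-length interface has no orientation")
    angle = axes.angle_to_ap(vec)
    return ("AP" if angle < 45.0 else "DV"), angle


def spatiotemporal_heatmap(
    values: np.ndarray,
    dv_locations: np.ndarray,
    times_min: np.ndarray,
    time_bins: int = 30,
    dv_bins: int = 20,
    time_bin_min: float = 1.0,
    dv_bin_um: float = 3.0,
    dv_origin_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bin a per-cell measure into (time x DV-location) mean and N maps.

    Default grid: 30 one-minute time bins by 20 DV bins of 3 μm,
    DV location measured as distance from the ventral midline (the two
    mirrored halves pool together).  Samples outside the grid are
    dropped and counted in the returned spill count.

    Returns ``(mean_map, n_map, n_spilled)`` with shape
    ``(time_bins, dv_bins)``; empty bins hold NaN in the mean map.
    """
    values = np.asarray(values, dtype=float)
    t_edges = np.arange(time_bins + 1) * time_bin_min
    d_edges = dv_origin_um + np.arange(dv_bins + 1) * dv_bin_um
    mean_map, _, _, _ = binned_statistic_2d(
        times_min, dv_locations, values, statistic="mean", bins=[t_edges, d_edges]
    )
    n_map, _, _, _ = binned_statistic_2d(
        times_min, dv_locations, values, statistic="count", bins=[t_edges, d_edges]
    )
    inside = (
        (times_min >= t_edges[0]) & (times_min <= t_edges[-1])
        & (dv_locations >= d_edges[0]) & (dv_locations <= d_edges[-1])
    )
    return mean_map, n_map.astype(int), int(np.sum(~inside))


def shape_table(tracks: EmbryoTracks) -> "pd.DataFrame":
    """Fit ellipses for every (cell, frame) and tabulate all shape metrics."""
    import pandas as pd

    rows = []
    for _, row in tracks.cells.iterrows():
        poly = _parse_outline(row["outline"])
        ell = fit_cell_ellipse(poly)
        score = axial_shape_elongation(ell, tracks.axes)
        rows.append(
            {
                "frame": int(row["frame"]),
                "cell_id": int(row["cell_id"]),
                "a_um": ell.a,
                "b_um": ell.b,
                "orientation_deg": ell.orientation_deg,
                "anisotropy": score.anisotropy,
                "axial_elongation": score.axial_elongation,
                "ap_length_um": axis_projected_cell_length(ell, "AP", tracks.axes),
                "dv_length_um": axis_projected_cell_length(ell, "DV", tracks.axes),
            }
        )
    return pd.DataFrame(rows)
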
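"""Strain-rate decomposition on focal-cell domains.

Local deformation is quantified on small spatiotemporal domains — a
focal cell plus one corona of neighbours, followed over a 2-minute
window spanning five frames.  Three symmetric 2x2 tensors (proportion
per minute, AP = x) are derived per domain:

* **tissue** strain rate, from the relative motion of the member-cell
  centroids (a least-squares affine flow fit per frame pair, converted
  to a symmetric log-strain rate so rigid rotations contribute
  nothing);
* **cell-shape** strain rate, the area-weighted average of per-cell
  best-fit linear maps taking each outline to its successor;
* **intercalation** strain rate, defined as their difference — the
  part of tissue deformation produced by neighbours sliding past one
  another rather than by cells changing shape.

The module also projects tensors on the embryonic axes, synchronises
movies to the onset of extension (AP tissue strain rate first exceeding
0.01 /min), averages genotypes with within-embryo confidence intervals,
and forms the intercalation/tissue log-ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import AxisFrame, EmbryoTracks

__all__ = [
    "StrainRateDomain",
    "assemble_domains",
    "tissue_strain_rate",
    "cell_shape_strain_rate",
    "intercalation_strain_rate",
    "project_strain_rate",
    "synchronize_time_zero",
    "average_with_within_embryo_ci",
    "log_ratio_intercalation",
    "domain_table",
    "SynchronizationError",
]

WINDOW_FRAMES = 5  # two minutes at 30-s frames


class SynchronizationError(RuntimeError):
    """The AP tissue strain rate never exceeded the onset threshold."""


@dataclass
class StrainRateDomain:
    """A focal cell with one corona of neighbours over a 5-frame window."""

    focal: int
    frame: int                #: central frame of the window
    members: tuple[int, ...]  #: focal + corona cell ids
    tissue: np.ndarray
    shape: np.ndarray
    intercalation: np.ndarray


# ----------------------------------------------------------------------
# tensor machinery
# ----------------------------------------------------------------------
def _log_strain_from_map(F: np.ndarray, dt_min: float) -> np.ndarray:
    """Symmetric log-strain rate of a 2x2 linear map over ``dt_min``.

    Uses the right stretch ``U = sqrt(F^T F)`` of the polar
    decomposition, so any rotational part of ``F`` drops out exactly:
    ``rate = log(U) / dt``.
    """
    C = F.T @ F
    evals, evecs = np.linalg.eigh(C)
    if np.any(evals <= 0):
        raise np.linalg.LinAlgError("degenerate deformation map")
    logU = evecs @ np.diag(0.5 * np.log(evals)) @ evecs.T
    return logU / dt_min


def _fit_affine(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Least-squares 2x2 map F with p1 - c1 ~= F (p0 - c0) (centred OLS)."""
    q0 = p0 - p0.mean(axis=0)
    q1 = p1 - p1.mean(axis=0)
    A = q0.T @ q0
    B = q0.T @ q1
    if np.linalg.matrix_rank(A) < 2:
        raise np.linalg.LinAlgError("collinear points: velocity gradient is underdetermined")
    return np.linalg.solve(A, B).T


def tissue_strain_rate(
    centroids_by_frame: list[dict[int, np.ndarray]],
    members: tuple[int, ...],
    dt_min: float,
) -> np.ndarray:
    """Tissue strain rate from member-centroid motion over the window.

    A centred least-squares affine map is fitted from the member
    centroids in the first window frame to those in the last, and
    converted to a symmetric log-strain rate over the window duration
    (using the full window rather than single frame steps keeps the
    estimate robust to centroid tracking noise).  Requires at least
    three non-collinear centroids.
    """
    if len(members) < 3:
        raise np.linalg.LinAlgError("need at least 3 member cells")
    first, last = centroids_by_frame[0], centroids_by_frame[-1]
    span_min = (len(centroids_by_frame) - 1) * dt_min
    p0 = np.array([first[m] for m in members])
    p1 = np.array([last[m] for m in members])
    F = _fit_affine(p0, p1)
    return _log_strain_from_map(F, span_min)


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` points by arc length."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, closed[:, 0])
    out[:, 1] = np.interp(target, s, closed[:, 1])
    return out


def cell_shape_strain_rate(
    outlines_by_frame: list[dict[int, np.ndarray]],
    members: tuple[int, ...],
    dt_min: float,
    resample_points: int = 64,
) -> np.ndarray:
    """Area-weighted cell-shape strain rate of a domain.

    Per member cell and frame pair, a centred least-squares linear map
    is fitted over corresponding boundary points (vertex order gives the
    correspondence when counts match; otherwise both outlines are
    resampled to ``resample_points`` by arc length), converted to a
    symmetric log-strain rate, averaged over the window, and finally
    area-averaged over member cells.
    """
    per_cell = []
    weights = []
    for m in members:
        rates = []
        for f0, f1 in zip(outlines_by_frame[:-1], outlines_by_frame[1:]):
            p0, p1 = f0[m], f1[m]
            if len(p0) != len(p1):
                p0 = _resample_closed(p0, resample_points)
                p1 = _resample_closed(p1, resample_points)
            F = _fit_affine(p0, p1)
            rates.append(_log_strain_from_map(F, dt_min))
        per_cell.append(np.mean(rates, axis=0))
        x, y = outlines_by_frame[0][m][:, 0], outlines_by_frame[0][m][:, 1]
        weights.append(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    w = np.asarray(weights)
    return np.tensordot(w / w.sum(), np.array(per_cell), axes=1)


def intercalation_strain_rate(tissue: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Intercalation strain rate: tissue minus cell-shape, exactly."""
    return tissue - shape


# ----------------------------------------------------------------------
# domain assembly
# ----------------------------------------------------------------------
def assemble_domains(
    tracks: EmbryoTracks,
    frame: int,
    max_neighbour_distance_um: float | None = None,
) -> list[StrainRateDomain]:
    """Build and evaluate all strain-rate domains centred on ``frame``.

    The window spans frames ``frame-2 .. frame+2``; the corona is read
    from the interface table at the central frame.  Domains whose
    members are not tracked throughout the window are skipped, as are
    domains whose centroid fit is degenerate.  ``max_neighbour_distance_um``
    optionally drops domains containing implausibly distant "neighbours"
    (a tracking-sanity guard).
    """
    half = WINDOW_FRAMES // 2
    window = list(range(frame - half, frame + half + 1))
    all_frames = set(int(f) for f in tracks.frames())
    if not all(f in all_frames for f in window):
        return []
    cent = [tracks.centroids(f) for f in window]
    outl = [tracks.outlines(f) for f in window]
    adjacency = tracks.adjacency(frame)
    neighbours: dict[int, set[int]] = {}
    for pair in adjacency:
        a, b = tuple(pair)
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)

    dt_min = tracks.frame_interval_min
    domains = []
    for focal in sorted(cent[half]):
        members = (focal, *sorted(neighbours.get(focal, ())))
        if len(members) < 3:
            continue
        if not all(m in c for m in members for c in cent):
            continue  # lost from tracking within the window
        if max_neighbour_distance_um is not None:
            p = np.array([cent[half][m] for m in members])
            if np.max(np.linalg.norm(p - p[0], axis=1)) > max_neighbour_distance_um:
                continue
        try:
            tissue = tissue_strain_rate(cent, members, dt_min)
            shape = cell_shape_strain_rate(outl, members, dt_min)
        except np.linalg.LinAlgError:
            continue
        domains.append(
            StrainRateDomain(
                focal=focal,
                frame=frame,
                members=members,
                tissue=tissue,
                shape=shape,
                intercalation=intercalation_strain_rate(tissue, shape),
            )
        )
    return domains


def project_strain_rate(tensor: np.ndarray, axes: AxisFrame | None = None) -> tuple[float, float]:
    """AP and DV components ``e_ap . S . e_ap`` and ``e_dv . S . e_dv``."""
    axes = axes or AxisFrame()
    ap = np.asarray(axes.ap)
    dv = np.asarray(axes.dv)
    return float(ap @ tensor @ ap), float(dv @ tensor @ dv)


def domain_table(
    tracks: EmbryoTracks,
    frames: list[int] | None = None,
    max_neighbour_distance_um: float | None = None,
) -> pd.DataFrame:
    """Per-domain strain-rate table over the requested central frames."""
    if frames is None:
        half = WINDOW_FRAMES // 2
        fr = tracks.frames()
        frames = [int(f) for f in fr if fr.min() + half <= f <= fr.max() - half]
    rows = []
    for f in frames:
        for d in assemble_domains(tracks, f, max_neighbour_distance_um):
            row = {"frame": f, "focal": d.focal, "n_members": len(d.members)}
            for name, T in (
                ("tissue", d.tissue), ("shape", d.shape), ("intercalation", d.intercalation)
            ):
                ap, dv = project_strain_rate(T, tracks.axes)
                row[f"{name}_xx"] = T[0, 0]
                row[f"{name}_xy"] = T[0, 1]
                row[f"{name}_yy"] = T[1, 1]
                row[f"{name}_ap"] = ap
                row[f"{name}_dv"] = dv
            rows.append(row)
    return pd.DataFrame(rows)


def synchronize_time_zero(
    ap_series: pd.Series | np.ndarray,
    threshold: float = 0.01,
) -> int:
    """First frame whose AP tissue strain rate strictly exceeds threshold.

    ``ap_series`` is the per-frame tissue-median AP strain rate; the
    returned frame defines time zero of germband extension.
    """
    arr = np.asarray(ap_series, dtype=float)
    idx = np.flatnonzero(arr > threshold)
    if len(idx) == 0:
        raise SynchronizationError(
            f"AP strain rate never exceeded {threshold} /min"
        )
    if isinstance(ap_series, pd.Series):
        return int(ap_series.index[idx[0]])
    return int(idx[0])


def median_ap_series(domains: pd.DataFrame) -> pd.Series:
    """Per-frame median AP tissue strain rate across domains."""
    return domains.groupby("frame")["tissue_ap"].median()


def average_with_within_embryo_ci(
    table: pd.DataFrame,
    value: str,
    embryo: str = "embryo",
    frame: str = "frame",
) -> pd.DataFrame:
    """Cross-embryo mean series with a within-embryo confidence ribbon.

    Per frame: the mean of per-embryo means, and an indicative 95% CI
    half-width ``1.96 sqrt(pooled_var / n)`` where ``pooled_var`` is the
    mean of the within-embryo variances and ``n`` the total number of
    samples at that frame.  The pooled variance and ``n`` are returned
    as columns so alternative normalisations can be formed.
    """
    out = []
    for f, sub in table.groupby(frame):
        by_embryo = sub.groupby(embryo)[value]
        means = by_embryo.mean()
        variances = by_embryo.var(ddof=1).fillna(0.0)
        n = len(sub)
        pooled = float(variances.mean())
        half = 1.96 * np.sqrt(pooled / n) if n > 0 else np.nan
        out.append(
            {
                frame: f,
                "mean": float(means.mean()),
                "ci_half_width": half,
                "pooled_within_var": pooled,
                "n_samples": n,
                "n_embryos": len(means),
            }
        )
    return pd.DataFrame(out)


def log_ratio_intercalation(domains: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-domain ``ln(intercalation_AP / tissue_AP)``.

    Log-ratio space is closer to linear for averaging the proportion of
    extension accounted for by intercalation.  Domains where either AP
    component is non-positive are excluded; the exclusion count is
    returned alongside the series.
    """
    ok = (domains["intercalation_ap"] > 0) & (domains["tissue_ap"] > 0)
    series = np.log(domains.loc[ok, "intercalation_ap"] / domains.loc[ok, "tissue_ap"])
    return series, int((~ok).sum())
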
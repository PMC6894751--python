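"""Tracked-cell data model, file I/O, validation and synthetic generators.

The tabular schema mirrors what a segmentation-and-tracking pipeline
produces from an embryo movie: per frame, every cell has a stable id, a
centroid, a polygonal outline (μm) and temporal links; every cell–cell
interface has its incident cell pair, endpoint coordinates and temporal
links.  Frames are 30 s apart by default and an axis frame records the
AP/DV directions and the ventral-midline position.

Two generators provide ground-truth inputs for the analysis modules:
an affine-flow generator (cells advected by a prescribed velocity
gradient; the imposed tensor is the oracle for strain-rate recovery)
and a scripted-T1 generator (junctions shrink, hold a four-way vertex,
and regrow between the orthogonal pair; the script is the oracle for
neighbour-exchange detection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from shapely.geometry import Polygon

__all__ = [
    "AxisFrame",
    "EmbryoTracks",
    "TracksValidationError",
    "ScriptedT1",
    "generate_affine_flow_tracks",
    "generate_scripted_t1_lattice",
    "hex_lattice_patch",
]

CELL_COLUMNS = ["frame", "cell_id", "x", "y", "outline", "cell_type", "prev_id", "next_id"]
INTERFACE_COLUMNS = [
    "frame", "interface_id", "cell_a", "cell_b",
    "x1", "y1", "x2", "y2", "prev_id", "next_id",
]

#: interfaces at or below this length (μm) count as "no contact"
CONTACT_EPS = 1e-9


class TracksValidationError(ValueError):
    """A tracks table violates the schema or a geometric invariant."""


@dataclass(frozen=True)
class AxisFrame:
    """Embryonic axis frame: AP and DV unit vectors plus the midline.

    DV location of a point is its distance from the ventral midline,
    ``|r . dv - midline_y|``; mirroring about the midline leaves it
    unchanged, so the two halves of the embryo pool together.
    """

    ap: tuple[float, float] = (1.0, 0.0)
    dv: tuple[float, float] = (0.0, 1.0)
    midline_y: float = 0.0

    def __post_init__(self) -> None:
        ap, dv = np.asarray(self.ap), np.asarray(self.dv)
        if abs(np.linalg.norm(ap) - 1) > 1e-9 or abs(np.linalg.norm(dv) - 1) > 1e-9:
            raise ValueError("axis vectors must be unit length")
        if abs(float(ap @ dv)) > 1e-9:
            raise ValueError("axis vectors must be orthogonal")

    def dv_location(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return np.abs(xy @ np.asarray(self.dv) - self.midline_y)

    def angle_to_ap(self, vec: np.ndarray) -> float:
        """Angle of an undirected line to the AP axis, degrees in [0, 90]."""
        v = np.asarray(vec, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero-length vector has no orientation")
        c = abs(float(v @ np.asarray(self.ap))) / n
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _format_outline(poly: np.ndarray) -> str:
    return ";".join(f"{float(x)!r} {float(y)!r}" for x, y in poly)


def _parse_outline(s: str) -> np.ndarray:
    pts = [tuple(map(float, p.split())) for p in s.split(";")]
    return np.asarray(pts, dtype=float)


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cr = x * yn - xn * y
    a = 0.5 * cr.sum()
    return np.array([np.sum((x + xn) * cr), np.sum((y + yn) * cr)]) / (6.0 * a)


@dataclass
class EmbryoTracks:
    """Tracked cells and interfaces of one (real or synthetic) embryo."""

    cells: pd.DataFrame
    interfaces: pd.DataFrame
    frame_interval_s: float = 30.0
    axes: AxisFrame = field(default_factory=AxisFrame)

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    def frames(self) -> np.ndarray:
        return np.unique(self.cells["frame"].to_numpy())

    # -- per-frame lookups ---------------------------------------------
    def centroids(self, frame: int) -> dict[int, np.ndarray]:
        sub = self.cells[self.cells["frame"] == frame]
        return {
            int(c): np.array([x, y])
            for c, x, y in zip(sub["cell_id"], sub["x"], sub["y"])
        }

    def outlines(self, frame: int) -> dict[int, np.ndarray]:
        sub = self.cells[self.cells["frame"] == frame]
        return {int(c): _parse_outline(o) for c, o in zip(sub["cell_id"], sub["outline"])}

    def adjacency(self, frame: int) -> set[frozenset]:
        """Cell pairs in contact at a frame (zero-length interfaces excluded)."""
        sub = self.interfaces[self.interfaces["frame"] == frame]
        ln = np.hypot(sub["x2"] - sub["x1"], sub["y2"] - sub["y1"])
        ok = ln.to_numpy() > CONTACT_EPS
        return {
            frozenset((int(a), int(b)))
            for a, b, keep in zip(sub["cell_a"], sub["cell_b"], ok)
            if keep
        }

    def interface_endpoints(self, frame: int) -> dict[frozenset, np.ndarray]:
        sub = self.interfaces[self.interfaces["frame"] == frame]
        return {
            frozenset((int(a), int(b))): np.array([[x1, y1], [x2, y2]])
            for a, b, x1, y1, x2, y2 in zip(
                sub["cell_a"], sub["cell_b"], sub["x1"], sub["y1"], sub["x2"], sub["y2"]
            )
        }

    def interface_length(self, frame: int, pair: frozenset) -> float | None:
        ends = self.interface_endpoints(frame).get(pair)
        if ends is None:
            return None
        return float(np.linalg.norm(ends[1] - ends[0]))

    # -- validation ----------------------------------------------------
    def validate(self, check_outlines: bool = True) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise TracksValidationError(f"cells table missing column {col!r}")
        for col in INTERFACE_COLUMNS:
            if col not in self.interfaces.columns:
                raise TracksValidationError(f"interfaces table missing column {col!r}")

        ids_by_frame = {
            int(f): set(sub["cell_id"].astype(int))
            for f, sub in self.cells.groupby("frame")
        }
        for idx, row in self.interfaces.iterrows():
            f = int(row["frame"])
            present = ids_by_frame.get(f, set())
            for key in ("cell_a", "cell_b"):
                if int(row[key]) not in present:
                    raise TracksValidationError(
                        f"interface row {idx}: {key}={int(row[key])} not tracked at frame {f}"
                    )

        if check_outlines:
            for idx, row in self.cells.iterrows():
                poly = _parse_outline(row["outline"])
                if len(poly) < 3:
                    raise TracksValidationError(f"cell row {idx}: outline has <3 points")
                sp = Polygon(poly)
                if not sp.is_simple or sp.area <= 0:
                    raise TracksValidationError(
                        f"cell row {idx}: outline polygon is not simple"
                    )
                c = _polygon_centroid(poly)
                if np.linalg.norm(c - np.array([row["x"], row["y"]])) > 1e-6:
                    raise TracksValidationError(
                        f"cell row {idx}: centroid differs from polygon centroid"
                    )

        # temporal links: a link must point at a row in the adjacent frame
        frames = sorted(ids_by_frame)
        for idx, row in self.cells.iterrows():
            f = int(row["frame"])
            for key, df in (("prev_id", -1), ("next_id", +1)):
                target = int(row[key])
                if target < 0:
                    continue
                if target not in ids_by_frame.get(f + df, set()):
                    raise TracksValidationError(
                        f"cell row {idx}: broken temporal link {key} -> {target}"
                    )

    # -- file I/O ------------------------------------------------------
    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(path / "cells.csv", index=False)
        self.interfaces.to_csv(path / "interfaces.csv", index=False)
        header = {
            "frame_interval_s": self.frame_interval_s,
            "ap_vector": list(self.axes.ap),
            "dv_vector": list(self.axes.dv),
            "midline_y": self.axes.midline_y,
            "unit": "um",
        }
        (path / "header.json").write_text(json.dumps(header, indent=1))

    @classmethod
    def read(cls, path: str | Path, validate: bool = True) -> "EmbryoTracks":
        path = Path(path)
        cells = pd.read_csv(path / "cells.csv", dtype={"outline": str, "cell_type": str})
        interfaces = pd.read_csv(
            path / "interfaces.csv",
            dtype={"interface_id": str, "prev_id": str, "next_id": str},
        )
        interfaces[["prev_id", "next_id"]] = interfaces[["prev_id", "next_id"]].fillna("")
        header = json.loads((path / "header.json").read_text())
        tracks = cls(
            cells=cells,
            interfaces=interfaces,
            frame_interval_s=header["frame_interval_s"],
            axes=AxisFrame(
                ap=tuple(header["ap_vector"]),
                dv=tuple(header["dv_vector"]),
                midline_y=header["midline_y"],
            ),
        )
        if validate:
            tracks.validate()
        return tracks


# ----------------------------------------------------------------------
# hexagonal patch (non-periodic) used by both generators
# ----------------------------------------------------------------------
def hex_lattice_patch(
    rows: int, cols: int, side: float = 2.0
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Patch of pointy-top regular hexagons with shared vertices.

    Returns vertex positions and ``cell_id -> CCW vertex-id loop``.
    Cells are indexed row-major (``cid = row * cols + col``); horizontal
    neighbours within a row share a vertical (DV-oriented) junction.
    """
    s = float(side)
    ang = np.deg2rad(np.arange(30, 360, 60))
    hexv = s * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    key_of: dict[tuple[int, int], int] = {}
    positions: list[np.ndarray] = []
    cells: dict[int, list[int]] = {}

    def vertex_at(p: np.ndarray) -> int:
        key = (int(round(p[0] / (s * np.sqrt(3) / 2) * 2)), int(round(p[1] / (0.5 * s))))
        if key not in key_of:
            key_of[key] = len(positions)
            positions.append(p)
        return key_of[key]

    for j in range(rows):
        for i in range(cols):
            c = np.array([np.sqrt(3) * s * (i + 0.5 * (j % 2)), 1.5 * s * j])
            cells[j * cols + i] = [vertex_at(c + hv) for hv in hexv]
    return np.array(positions), cells


def _shared_edges(cells: dict[int, list[int]]) -> dict[frozenset, tuple[int, int]]:
    """Interior edges -> (vertex ids); keyed by the incident cell pair."""
    seen: dict[frozenset, list[tuple[int, tuple[int, int]]]] = {}
    for cid, loop in cells.items():
        n = len(loop)
        for k in range(n):
            v1, v2 = loop[k], loop[(k + 1) % n]
            seen.setdefault(frozenset((v1, v2)), []).append((cid, (v1, v2)))
    out: dict[frozenset, tuple[int, int]] = {}
    for e, holders in seen.items():
        if len(holders) == 2:
            pair = frozenset((holders[0][0], holders[1][0]))
            out[pair] = holders[0][1]
    return out


def _tables_from_frames(
    frame_polys: list[dict[int, np.ndarray]],
    frame_edges: list[dict[frozenset, np.ndarray]],
    frame_interval_s: float,
    axes: AxisFrame,
    centroid_noise: np.ndarray | None = None,
    cell_type: str = "ectoderm",
) -> EmbryoTracks:
    """Assemble cells/interfaces tables from per-frame geometry."""
    n_frames = len(frame_polys)
    cell_rows = []
    for f, polys in enumerate(frame_polys):
        for ci, (cid, poly) in enumerate(sorted(polys.items())):
            c = _polygon_centroid(poly)
            if centroid_noise is not None:
                c = c + centroid_noise[f, ci]
            cell_rows.append(
                {
                    "frame": f,
                    "cell_id": cid,
                    "x": c[0],
                    "y": c[1],
                    "outline": _format_outline(poly),
                    "cell_type": cell_type,
                    "prev_id": cid if f > 0 else -1,
                    "next_id": cid if f < n_frames - 1 else -1,
                }
            )
    iface_rows = []
    pair_frames: dict[frozenset, set[int]] = {}
    for f, edges in enumerate(frame_edges):
        for pair in edges:
            pair_frames.setdefault(pair, set()).add(f)
    for f, edges in enumerate(frame_edges):
        for pair, ends in sorted(edges.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            iid = f"{a}-{b}"
            iface_rows.append(
                {
                    "frame": f,
                    "interface_id": iid,
                    "cell_a": a,
                    "cell_b": b,
                    "x1": ends[0][0],
                    "y1": ends[0][1],
                    "x2": ends[1][0],
                    "y2": ends[1][1],
                    "prev_id": iid if (f - 1) in pair_frames[pair] else "",
                    "next_id": iid if (f + 1) in pair_frames[pair] else "",
                }
            )
    return EmbryoTracks(
        cells=pd.DataFrame(cell_rows, columns=CELL_COLUMNS),
        interfaces=pd.DataFrame(iface_rows, columns=INTERFACE_COLUMNS),
        frame_interval_s=frame_interval_s,
        axes=axes,
    )


def generate_affine_flow_tracks(
    gradient: np.ndarray,
    n_frames: int = 61,
    rows: int = 10,
    cols: int = 10,
    side: float = 2.0,
    noise_um: float = 0.0,
    seed: int = 0,
    frame_interval_s: float = 30.0,
    drift_um_per_min: tuple[float, float] = (0.0, 0.0),
) -> EmbryoTracks:
    """Hexagonal-lattice tracks advected by a constant velocity gradient.

    Positions evolve as ``x(t + dt) = expm(G dt) x(t)`` with ``G`` the
    velocity-gradient tensor in /min, so an antisymmetric ``G`` produces
    an exact rigid rotation (all pairwise distances conserved) and a
    symmetric ``G`` a pure log-linear stretch; a uniform drift velocity
    can be superimposed.  Optional isotropic Gaussian jitter
    (``noise_um``) perturbs centroids only; outlines stay exact so
    recovery tests remain interpretable.
    """
    G = np.asarray(gradient, dtype=float)
    dt_min = frame_interval_s / 60.0
    step = expm(G * dt_min)
    pos0, cells = hex_lattice_patch(rows, cols, side)
    edges = _shared_edges(cells)

    frame_polys: list[dict[int, np.ndarray]] = []
    frame_edges: list[dict[frozenset, np.ndarray]] = []
    pos = pos0.copy()
    drift = np.asarray(drift_um_per_min, dtype=float) * dt_min
    for f in range(n_frames):
        polys = {cid: pos[loop] for cid, loop in cells.items()}
        for cid, poly in polys.items():
            if not Polygon(poly).is_simple:
                raise ValueError(
                    f"outline of cell {cid} self-intersects at frame {f}; "
                    "the imposed gradient is too large"
                )
        frame_polys.append(polys)
        frame_edges.append({pair: pos[list(vv)] for pair, vv in edges.items()})
        pos = pos @ step.T + drift

    noise = None
    if noise_um > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=noise_um, size=(n_frames, len(cells), 2))
    return _tables_from_frames(
        frame_polys, frame_edges, frame_interval_s, AxisFrame(), centroid_noise=noise
    )


# ----------------------------------------------------------------------
# scripted T1 generator
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ScriptedT1:
    """One scripted neighbour exchange on the lattice.

    ``losing`` names the two horizontally adjacent cells whose shared
    vertical junction shrinks; the cells above and below the junction
    gain contact.  The junction reaches zero length at ``swap_frame``,
    stays a four-way vertex for ``hold_frames`` further frames, and the
    new junction then grows by ``side / regrow_frames`` per frame.  If
    ``revert_frame`` is set, the exchange runs backwards from that frame
    and the original pair regains contact.
    """

    losing: tuple[int, int]
    shrink_start: int = 5
    swap_frame: int = 25
    hold_frames: int = 0
    regrow_frames: int = 20
    revert_frame: int | None = None

    @property
    def gain_frame(self) -> int:
        return self.swap_frame + self.hold_frames + 1


def _insert_pair(loop: list[int], old: int, pair: tuple[int, int],
                 positions: np.ndarray) -> list[int]:
    """Replace ``old`` by two vertices, choosing the order that keeps the
    polygon simple with positive area."""
    k = loop.index(old)
    for order in (list(pair), list(pair)[::-1]):
        cand = loop[:k] + order + loop[k + 1:]
        poly = Polygon(positions[cand])
        if poly.is_simple and poly.area > 0:
            return cand
    raise ValueError("could not insert resolved vertex pair consistently")


def generate_scripted_t1_lattice(
    script: list[ScriptedT1],
    n_frames: int = 61,
    rows: int = 5,
    cols: int = 5,
    side: float = 2.0,
    frame_interval_s: float = 30.0,
) -> EmbryoTracks:
    """Regular-hexagon tracks with scripted T1 swaps.

    Junction lengths follow the script exactly (linear shrink to zero,
    optional four-way hold, linear regrow between the orthogonal pair),
    and all outlines and interfaces stay consistent with the topology at
    every frame.  Scripts touching a common cell with overlapping active
    windows are rejected.
    """
    pos0, cells0 = hex_lattice_patch(rows, cols, side)
    base_edges = _shared_edges(cells0)
    pair_to_verts = dict(base_edges)

    # resolve each scripted quartet and check for conflicts
    events = []
    claimed: list[tuple[set[int], tuple[int, int]]] = []
    for sc in script:
        pair = frozenset(sc.losing)
        if pair not in pair_to_verts:
            raise ValueError(f"losing cells {sc.losing} share no junction")
        v1, v2 = pair_to_verts[pair]
        # order endpoints top/bottom; the junction must be DV-oriented
        if abs(pos0[v1][0] - pos0[v2][0]) > 1e-9:
            raise ValueError(f"junction of {sc.losing} is not vertical")
        v_top, v_bot = (v1, v2) if pos0[v1][1] > pos0[v2][1] else (v2, v1)
        third = lambda v: next(
            cid for cid, loop in cells0.items()
            if v in loop and cid not in sc.losing
        )
        cell_a, cell_b = third(v_top), third(v_bot)  # above, below
        quartet = set(sc.losing) | {cell_a, cell_b}
        t_hi = sc.revert_frame if sc.revert_frame is not None else n_frames
        window = (sc.shrink_start, t_hi)
        for other_cells, other_win in claimed:
            if quartet & other_cells and not (
                window[1] < other_win[0] or other_win[1] < window[0]
            ):
                raise ValueError("scripted swaps overlap on shared cells")
        claimed.append((quartet, window))
        events.append((sc, v_top, v_bot, cell_a, cell_b))

    # pre-build swapped topology and new vertices for every event
    n_v = len(pos0)
    pos_full = np.vstack([pos0, np.zeros((2 * len(events), 2))])
    swaps = []
    for ei, (sc, v_top, v_bot, cell_a, cell_b) in enumerate(events):
        w_left, w_right = n_v + 2 * ei, n_v + 2 * ei + 1
        mid = 0.5 * (pos0[v_top] + pos0[v_bot])
        pos_full[w_left] = mid
        pos_full[w_right] = mid
        swaps.append((sc, v_top, v_bot, cell_a, cell_b, w_left, w_right, mid))

    def junction_lengths(sc: ScriptedT1, f: int) -> tuple[float, float]:
        """(losing-junction length, gaining-junction length) at frame f."""
        s = side
        if f < sc.shrink_start:
            return s, 0.0
        if f < sc.swap_frame:
            return s * (sc.swap_frame - f) / (sc.swap_frame - sc.shrink_start), 0.0
        if f <= sc.swap_frame + sc.hold_frames:
            return 0.0, 0.0
        # growing phase (possibly reversed)
        grow = (f - sc.swap_frame - sc.hold_frames) * s / sc.regrow_frames
        if sc.revert_frame is None:
            return 0.0, min(s, grow)
        if f < sc.revert_frame:
            back = (sc.revert_frame - f) * s / sc.regrow_frames
            return 0.0, min(s, grow, back)
        if f == sc.revert_frame:
            return 0.0, 0.0
        return min(s, (f - sc.revert_frame) * s / sc.regrow_frames), 0.0

    frame_polys: list[dict[int, np.ndarray]] = []
    frame_edges: list[dict[frozenset, np.ndarray]] = []
    for f in range(n_frames):
        cells = {cid: list(loop) for cid, loop in cells0.items()}
        pos = pos_full.copy()
        for sc, v_top, v_bot, cell_a, cell_b, w_left, w_right, mid in swaps:
            lose_len, gain_len = junction_lengths(sc, f)
            ab_owns = gain_len > 0 or (
                sc.revert_frame is None
                and f > sc.swap_frame + sc.hold_frames
            ) or (
                sc.revert_frame is not None
                and sc.swap_frame + sc.hold_frames < f < sc.revert_frame
            )
            if not ab_owns:
                pos[v_top] = mid + np.array([0.0, lose_len / 2])
                pos[v_bot] = mid - np.array([0.0, lose_len / 2])
            else:
                # swapped topology: losing cells pinch to one vertex each,
                # gaining cells share the horizontal junction w_left-w_right
                pos[w_left] = mid - np.array([gain_len / 2, 0.0])
                pos[w_right] = mid + np.array([gain_len / 2, 0.0])
                c_left, c_right = sorted(
                    sc.losing, key=lambda cid: _polygon_centroid(pos0[cells0[cid]])[0]
                )
                for cid, keep in ((c_left, w_left), (c_right, w_right)):
                    loop = [keep if v in (v_top, v_bot) else v for v in cells[cid]]
                    dedup = [v for i, v in enumerate(loop) if loop[i - 1] != v]
                    cells[cid] = dedup
                for cid, old in ((cell_a, v_top), (cell_b, v_bot)):
                    cells[cid] = _insert_pair(cells[cid], old, (w_left, w_right), pos)
        polys = {}
        for cid, loop in cells.items():
            poly = pos[loop]
            keep = np.linalg.norm(poly - np.roll(poly, 1, axis=0), axis=1) > 1e-12
            polys[cid] = poly[keep]
        frame_polys.append(polys)
        edges = _shared_edges(cells)
        frame_edges.append(
            {
                pair: pos[list(vv)]
                for pair, vv in edges.items()
                if np.linalg.norm(pos[vv[0]] - pos[vv[1]]) > CONTACT_EPS
            }
        )
    return _tables_from_frames(frame_polys, frame_edges, frame_interval_s, AxisFrame())
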
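"""Periodic polygonal tilings for vertex-model simulations.

The tissue is a tiling of a flat torus (periodic box of size ``Lx × Ly``)
by polygonal cells.  Vertices carry positions, cells are ordered
(counter-clockwise) loops of vertex ids, and edges are derived from the
loops: every edge must be shared by exactly two cells, so the Euler
characteristic ``V - E + F`` is zero throughout.

Vertices of rank 3 are ordinary tricellular vertices; higher ranks
(four or more incident cells) represent protorosettes and rosettes
produced by edge collapses and awaiting probabilistic resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VertexMesh",
    "MeshTopologyError",
    "build_hex_tissue",
    "census_vertex_ranks",
    "STRIPE_LABELS",
]

STRIPE_LABELS = ("S1", "S2", "S3", "S4")


class MeshTopologyError(ValueError):
    """Raised when a mesh violates the torus-tiling invariants."""


@dataclass
class VertexMesh:
    """Vertex-model state on a periodic box.

    Parameters
    ----------
    pos
        ``(n_vertices, 2)`` float array of positions, kept inside
        ``[0, Lx) × [0, Ly)``.
    vids
        Vertex ids, one per row of ``pos``.  Ids are stable across
        topological events (a merged vertex gets a fresh id).
    cells
        Mapping ``cell_id -> list of vertex ids`` (CCW loop).
    stripe
        Mapping ``cell_id -> stripe index`` in ``{0, 1, 2, 3}``.
    box
        ``(Lx, Ly)``.
    time
        Simulation time in minutes.
    """

    pos: np.ndarray
    vids: np.ndarray
    cells: dict[int, list[int]]
    stripe: dict[int, int]
    box: tuple[float, float]
    time: float = 0.0
    # provenance of rank-4 vertices: vid -> (cell_a, cell_b) that shared the
    # collapsed junction; used to complete the T1 on resolution
    losing_pair: dict[int, tuple[int, int]] = field(default_factory=dict)
    _row_of: dict[int, int] = field(default_factory=dict, repr=False)
    _next_vid: int = 0
    _next_event_id: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.vids = np.asarray(self.vids, dtype=np.int64)
        self._row_of = {int(v): i for i, v in enumerate(self.vids)}
        if self._next_vid <= (self.vids.max(initial=-1)):
            self._next_vid = int(self.vids.max(initial=-1)) + 1

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vids)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def row(self, vid: int) -> int:
        return self._row_of[vid]

    def position(self, vid: int) -> np.ndarray:
        return self.pos[self._row_of[vid]]

    def copy(self) -> "VertexMesh":
        m = VertexMesh(
            pos=self.pos.copy(),
            vids=self.vids.copy(),
            cells={c: list(loop) for c, loop in self.cells.items()},
            stripe=dict(self.stripe),
            box=self.box,
            time=self.time,
            losing_pair=dict(self.losing_pair),
        )
        m._next_vid = self._next_vid
        m._next_event_id = self._next_event_id
        if hasattr(self, "_n_columns"):
            m._n_columns = self._n_columns  # type: ignore[attr-defined]
        return m

    # ------------------------------------------------------------------
    # periodic geometry helpers
    # ------------------------------------------------------------------
    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Wrap displacement vectors to the nearest periodic image."""
        d = np.asarray(d, dtype=float)
        Lx, Ly = self.box
        out = d.copy()
        out[..., 0] -= Lx * np.round(out[..., 0] / Lx)
        out[..., 1] -= Ly * np.round(out[..., 1] / Ly)
        return out

    def wrap(self) -> None:
        Lx, Ly = self.box
        self.pos[:, 0] %= Lx
        self.pos[:, 1] %= Ly

    def edge_vector(self, v1: int, v2: int) -> np.ndarray:
        return self.min_image(self.position(v2) - self.position(v1))

    def cell_polygon(self, cid: int) -> np.ndarray:
        """Unwrapped CCW polygon for one cell (first vertex as anchor)."""
        loop = self.cells[cid]
        rows = [self._row_of[v] for v in loop]
        p = self.pos[rows]
        d = self.min_image(np.diff(p, axis=0, append=p[:1]))
        out = np.empty_like(p)
        out[0] = p[0]
        out[1:] = p[0] + np.cumsum(d[:-1], axis=0)
        return out

    def cell_area(self, cid: int) -> float:
        q = self.cell_polygon(cid)
        return 0.5 * float(np.sum(q[:, 0] * np.roll(q[:, 1], -1) - np.roll(q[:, 0], -1) * q[:, 1]))

    def cell_perimeter(self, cid: int) -> float:
        q = self.cell_polygon(cid)
        return float(np.sum(np.linalg.norm(np.diff(q, axis=0, append=q[:1]), axis=1)))

    def cell_centroid(self, cid: int) -> np.ndarray:
        q = self.cell_polygon(cid)
        x, y = q[:, 0], q[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cr = x * yn - xn * y
        a = 0.5 * cr.sum()
        cx = np.sum((x + xn) * cr) / (6.0 * a)
        cy = np.sum((y + yn) * cr) / (6.0 * a)
        return np.array([cx, cy])

    # ------------------------------------------------------------------
    # derived topology
    # ------------------------------------------------------------------
    def edges(self) -> dict[frozenset[int], list[int]]:
        """Map edge (frozenset of two vertex ids) -> incident cell ids."""
        out: dict[frozenset, list[int]] = {}
        for cid, loop in self.cells.items():
            n = len(loop)
            for k in range(n):
                e = frozenset((loop[k], loop[(k + 1) % n]))
                out.setdefault(e, []).append(cid)
        return out

    def vertex_cells(self) -> dict[int, list[int]]:
        """Map vertex id -> incident cell ids (unordered)."""
        out: dict[int, list[int]] = {int(v): [] for v in self.vids}
        for cid, loop in self.cells.items():
            for v in loop:
                out[v].append(cid)
        return out

    def vertex_rank(self, vid: int) -> int:
        return sum(1 for loop in self.cells.values() if vid in loop)

    def ranks(self) -> dict[int, int]:
        vc = self.vertex_cells()
        return {v: len(cs) for v, cs in vc.items()}

    def cells_around_vertex(self, vid: int) -> list[int]:
        """Incident cells of ``vid`` in cyclic (CCW) order.

        Two incident cells are consecutive around the vertex iff they share
        an edge ending at the vertex.  For a cell whose CCW loop reads
        ``..., a, vid, b, ...`` the outgoing boundary edge ``(vid, b)`` is
        shared with the next cell clockwise of it, for which the same edge
        is incoming; chaining that relation walks once around the vertex.
        """
        wedges: dict[int, tuple[int, int]] = {}
        for cid, loop in self.cells.items():
            if vid in loop:
                k = loop.index(vid)
                a = loop[k - 1]
                b = loop[(k + 1) % len(loop)]
                wedges[cid] = (a, b)
        if not wedges:
            raise MeshTopologyError(f"vertex {vid} belongs to no cell")
        # successor(c) = cell whose incoming neighbour equals c's outgoing one
        by_in = {ab[0]: cid for cid, ab in wedges.items()}
        order = [next(iter(wedges))]
        for _ in range(len(wedges) - 1):
            out_v = wedges[order[-1]][1]
            nxt = by_in.get(out_v)
            if nxt is None or nxt in order:
                raise MeshTopologyError(f"broken cell fan around vertex {vid}")
            order.append(nxt)
        return order

    # ------------------------------------------------------------------
    # mutation helpers (used by the event machinery)
    # ------------------------------------------------------------------
    def add_vertex(self, p: np.ndarray) -> int:
        vid = self._next_vid
        self._next_vid += 1
        self.pos = np.vstack([self.pos, np.asarray(p, dtype=float)[None, :]])
        self.vids = np.append(self.vids, vid)
        self._row_of[vid] = len(self.vids) - 1
        return vid

    def remove_vertices(self, dead: set[int]) -> None:
        keep = np.array([v not in dead for v in self.vids])
        self.pos = self.pos[keep]
        self.vids = self.vids[keep]
        self._row_of = {int(v): i for i, v in enumerate(self.vids)}
        for v in dead:
            self.losing_pair.pop(v, None)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_cells

    def validate(self, check_geometry: bool = True) -> None:
        """Raise :class:`MeshTopologyError` on any broken invariant."""
        edges = self.edges()
        for e, cs in edges.items():
            if len(cs) != 2 or cs[0] == cs[1]:
                raise MeshTopologyError(f"edge {set(e)} borders cells {cs}")
        if self.euler_characteristic() != 0:
            raise MeshTopologyError(
                f"V-E+F = {self.euler_characteristic()} != 0 "
                f"(V={self.n_vertices}, E={len(edges)}, F={self.n_cells})"
            )
        for v, r in self.ranks().items():
            if r < 3:
                raise MeshTopologyError(f"vertex {v} has rank {r} < 3")
        for cid, loop in self.cells.items():
            if len(loop) < 3:
                raise MeshTopologyError(f"cell {cid} has {len(loop)} vertices")
            if len(set(loop)) != len(loop):
                raise MeshTopologyError(f"cell {cid} repeats a vertex")
        if check_geometry:
            for cid in self.cells:
                a = self.cell_area(cid)
                if a <= 0:
                    raise MeshTopologyError(f"cell {cid} has area {a} <= 0")


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------
def build_hex_tissue(
    nx: int,
    ny: int,
    stripes: str = "repeat4",
    area: float = 1.0,
) -> VertexMesh:
    """Build a periodic tiling of ``nx × ny`` regular hexagons.

    Hexagons are flat-topped and arranged in ``nx`` columns along the AP
    (x) axis and ``ny`` rows along DV (y); odd columns are offset by half
    a row, so ``nx`` must be even for the tiling to wrap periodically.
    Each cell receives one of four stripe identities repeating along AP
    (column index modulo 4), mimicking parasegmental identity stripes.

    Parameters
    ----------
    nx, ny
        Columns and rows of hexagons; ``nx`` must be even.
    stripes
        Stripe pattern; only ``"repeat4"`` (S1..S4 repeating by column)
        and ``"none"`` (all cells S1) are defined.
    area
        Hexagon area in model units (sets the length scale).

    Returns
    -------
    VertexMesh
        All cells have area ``area`` and all vertices rank 3.
    """
    if nx <= 0 or ny <= 0:
        raise ValueError("nx and ny must be positive")
    if nx % 2 != 0:
        raise ValueError("nx must be even for periodic hexagonal wrapping")
    if stripes not in ("repeat4", "none"):
        raise ValueError(f"unknown stripe pattern {stripes!r}")

    s = float(np.sqrt(2.0 * area / (3.0 * np.sqrt(3.0))))  # hexagon side
    Lx = 1.5 * s * nx
    Ly = np.sqrt(3.0) * s * ny

    # flat-top hexagon: vertices at angles 0, 60, ..., 300 degrees
    ang = np.deg2rad(np.arange(0, 360, 60))
    hexv = s * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    key_of: dict[tuple[int, int], int] = {}
    positions: list[np.ndarray] = []
    cells: dict[int, list[int]] = {}
    stripe: dict[int, int] = {}

    def vertex_at(p: np.ndarray) -> int:
        q = np.array([p[0] % Lx, p[1] % Ly])
        key = (int(round(q[0] / s * 4.0)) % int(round(Lx / s * 4.0)),
               int(round(q[1] / (s * np.sqrt(3.0) / 2.0) * 2.0))
               % int(round(Ly / (s * np.sqrt(3.0) / 2.0) * 2.0)))
        if key not in key_of:
            key_of[key] = len(positions)
            positions.append(q)
        return key_of[key]

    cid = 0
    for i in range(nx):
        for j in range(ny):
            cx = 1.5 * s * i + 0.75 * s
            cy = np.sqrt(3.0) * s * (j + 0.5 * (i % 2)) + np.sqrt(3.0) * s / 2.0
            loop = [vertex_at(np.array([cx, cy]) + hv) for hv in hexv]
            cells[cid] = loop
            stripe[cid] = (i % 4) if stripes == "repeat4" else 0
            cid += 1

    pos = np.array(positions)
    mesh = VertexMesh(
        pos=pos,
        vids=np.arange(len(positions)),
        cells=cells,
        stripe=stripe,
        box=(Lx, Ly),
    )
    mesh.validate()
    return mesh


def census_vertex_ranks(mesh: VertexMesh) -> tuple[dict[int, int], dict[str, int]]:
    """Per-cell vertex-rank class and tissue-wide counts.

    A cell's class is the maximum number of cells sharing any of its
    vertices: 3 for ordinary cells, 4 for protorosette members, 5+ for
    rosette members.

    Returns
    -------
    cell_class
        ``cell_id -> max rank`` (integer).
    counts
        ``{"3": n3, "4": n4, "5+": n5}``; values sum to the cell count.
    """
    ranks = mesh.ranks()
    cell_class = {
        cid: max(ranks[v] for v in loop) for cid, loop in mesh.cells.items()
    }
    counts = {"3": 0, "4": 0, "5+": 0}
    for r in cell_class.values():
        counts["3" if r == 3 else "4" if r == 4 else "5+"] += 1
    return cell_class, counts
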
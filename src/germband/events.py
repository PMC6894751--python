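"""Topological events: edge collapses and higher-order vertex resolution.

Instead of the classical instantaneous T1 swap, a junction that shortens
below a threshold merges its two endpoints into a single higher-order
vertex: four cells around the vertex form a protorosette (rank 4), five
or more a rosette (rank 5+).  A rank-4 vertex resolves with probability
``1 - exp(-p4 * dt)`` per step, a rank-5+ vertex with
``1 - exp(-p5plus * dt)``; resolution splits the vertex in two, creating
a short new junction between a previously non-adjacent cell pair and so
completing the neighbour exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import VertexMesh
from .mechanics import ModelParams, compute_energy, invalidate_cache, _incidence

__all__ = [
    "MergeRecord",
    "ResolutionRecord",
    "attempt_edge_merges",
    "resolve_vertices",
    "split_vertex",
]


@dataclass(frozen=True)
class MergeRecord:
    time: float
    old_vertices: tuple[int, int]
    new_vertex: int
    rank: int                      #: rank of the merged vertex
    losing_cells: tuple[int, int]  #: cells that shared the collapsed junction


@dataclass(frozen=True)
class ResolutionRecord:
    time: float
    vertex: int                    #: vertex that resolved (id survives as the rank r-1 part)
    rank: int                      #: rank before resolution
    pinched_cell: int              #: cell split off with the new rank-3 vertex
    gaining_pair: tuple[int, int]  #: cells that acquire the new junction
    new_vertex: int


# ----------------------------------------------------------------------
# merges
# ----------------------------------------------------------------------
def _merge_edge(mesh: VertexMesh, v1: int, v2: int, cells_e: tuple[int, int]) -> MergeRecord | None:
    """Collapse edge (v1, v2) to its midpoint; return record or None if skipped."""
    # cells that would drop below 3 vertices forbid the merge
    for cid in cells_e:
        if len(mesh.cells[cid]) <= 3:
            return None
    holders = [cid for cid, loop in mesh.cells.items() if v1 in loop or v2 in loop]
    both = [cid for cid in holders if v1 in mesh.cells[cid] and v2 in mesh.cells[cid]]
    if sorted(both) != sorted(cells_e):
        return None  # pathological sharing; skip and leave geometry to relax

    mid = mesh.position(v1) + 0.5 * mesh.edge_vector(v1, v2)
    w = mesh.add_vertex(np.array([mid[0] % mesh.box[0], mid[1] % mesh.box[1]]))
    for cid in holders:
        loop = mesh.cells[cid]
        new_loop = [w if v in (v1, v2) else v for v in loop]
        dedup: list[int] = []
        for v in new_loop:
            if not dedup or dedup[-1] != v:
                dedup.append(v)
        if len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        mesh.cells[cid] = dedup
    mesh.losing_pair.pop(v1, None)
    mesh.losing_pair.pop(v2, None)
    mesh.remove_vertices({v1, v2})
    rank = len(holders)
    if rank == 4:
        mesh.losing_pair[w] = (cells_e[0], cells_e[1])
    invalidate_cache(mesh)
    return MergeRecord(
        time=mesh.time,
        old_vertices=(v1, v2),
        new_vertex=w,
        rank=rank,
        losing_cells=(cells_e[0], cells_e[1]),
    )


def attempt_edge_merges(mesh: VertexMesh, params: ModelParams) -> list[MergeRecord]:
    """Collapse every edge shorter than ``l_merge``, shortest first, in place.

    Edge lengths are re-evaluated after each collapse because a merge
    changes the local topology (this is how rosettes grow: junctions
    attached to an existing high-order vertex merge into it).
    Merges that would create a two-sided cell are skipped.
    """
    records: list[MergeRecord] = []
    skipped: set[frozenset] = set()
    while True:
        # vectorised candidate scan on the incidence cache
        inc = _incidence(mesh)
        ev = mesh.min_image(mesh.pos[inc.e2] - mesh.pos[inc.e1])
        lengths = np.linalg.norm(ev, axis=1)
        order = np.argsort(lengths)
        candidates = [
            inc.edge_keys[i]
            for i in order
            if lengths[i] < params.l_merge and inc.edge_keys[i] not in skipped
        ]
        if not candidates:
            return records
        # collapse shortest first; endpoints touched this sweep force a
        # re-scan because the local geometry has changed
        touched: set[int] = set()
        progressed = False
        for e in candidates:
            v1, v2 = tuple(e)
            if v1 in touched or v2 in touched:
                continue
            cs = mesh.edges().get(e)
            if cs is None or len(cs) != 2:
                continue
            rec = _merge_edge(mesh, v1, v2, (cs[0], cs[1]))
            if rec is None:
                skipped.add(e)
            else:
                records.append(rec)
                touched.update((v1, v2, rec.new_vertex))
                progressed = True
        if not progressed:
            return records


# ----------------------------------------------------------------------
# resolutions
# ----------------------------------------------------------------------
def split_vertex(mesh: VertexMesh, vid: int, pinch_cell: int) -> ResolutionRecord:
    """Split high-order vertex ``vid`` by pinching off ``pinch_cell``, in place.

    The two cells flanking ``pinch_cell`` in the cyclic order around the
    vertex become adjacent through a new junction of length ``l_new``
    (set by the caller via vertex placement); the pinched cell and its
    flankers meet at a fresh rank-3 vertex, while ``vid`` survives with
    rank reduced by one.
    """
    order = mesh.cells_around_vertex(vid)
    r = len(order)
    if r < 4:
        raise ValueError(f"vertex {vid} has rank {r} < 4")
    i = order.index(pinch_cell)
    p_cell = order[i - 1]
    q_cell = order[(i + 1) % r]

    # placement along the direction from the vertex to the pinched cell
    w_pos = mesh.position(vid).copy()
    u = mesh.min_image(mesh.cell_centroid(pinch_cell) - w_pos)
    u = u / np.linalg.norm(u)
    l_new = getattr(mesh, "_l_new", 0.15)
    if r == 4:
        w1_pos = w_pos + 0.5 * l_new * u
        w2_pos = w_pos - 0.5 * l_new * u
    else:
        w1_pos = w_pos + l_new * u
        w2_pos = w_pos
    w1 = mesh.add_vertex(w1_pos % np.array(mesh.box))
    mesh.pos[mesh.row(vid)] = w2_pos % np.array(mesh.box)

    # pinched cell: its copy of the vertex becomes the new rank-3 vertex
    loop = mesh.cells[pinch_cell]
    mesh.cells[pinch_cell] = [w1 if v == vid else v for v in loop]

    # flanking cells: traversal passes through both vertices; the new one
    # is inserted on the side of the edge shared with the pinched cell
    pinch_loop = set(mesh.cells[pinch_cell])
    for cid in (p_cell, q_cell):
        loop = mesh.cells[cid]
        k = loop.index(vid)
        a = loop[k - 1]
        b = loop[(k + 1) % len(loop)]
        if a in pinch_loop:
            new_loop = loop[:k] + [w1, vid] + loop[k + 1:]
        elif b in pinch_loop:
            new_loop = loop[:k] + [vid, w1] + loop[k + 1:]
        else:  # pragma: no cover - guarded by cells_around_vertex
            raise RuntimeError("flanking cell shares no edge with pinched cell")
        mesh.cells[cid] = new_loop

    mesh.losing_pair.pop(vid, None)
    invalidate_cache(mesh)
    return ResolutionRecord(
        time=mesh.time,
        vertex=vid,
        rank=r,
        pinched_cell=pinch_cell,
        gaining_pair=(p_cell, q_cell),
        new_vertex=w1,
    )


def _choose_pinch(
    mesh: VertexMesh, vid: int, params: ModelParams, rng: np.random.Generator
) -> int:
    """Pick the cell to pinch off at a resolving vertex.

    A rank-4 vertex created by a junction collapse completes the T1: the
    recorded losing pair stays separated, i.e. one of the two losing
    cells is pinched off so that the previously non-adjacent pair gains
    the new junction.  Otherwise (rosettes, or rank-4 without
    provenance) the energetically most favourable split is taken, ties
    broken uniformly at random.
    """
    order = mesh.cells_around_vertex(vid)
    pair = mesh.losing_pair.get(vid)
    if pair is not None and len(order) == 4 and all(c in order for c in pair):
        # pinching either losing cell makes the other diagonal adjacent;
        # take the lower id for determinism
        return min(pair)
    energies = []
    for cand in order:
        trial = mesh.copy()
        trial._l_new = getattr(mesh, "_l_new", params.l_new)  # type: ignore[attr-defined]
        split_vertex(trial, vid, cand)
        energies.append(compute_energy(trial, params))
    energies = np.asarray(energies)
    best = np.flatnonzero(energies <= energies.min() + 1e-12)
    return order[int(rng.choice(best))]


def resolve_vertices(
    mesh: VertexMesh,
    params: ModelParams,
    rng: np.random.Generator,
) -> list[ResolutionRecord]:
    """Resolve higher-order vertices stochastically, in place.

    Every rank-4 vertex resolves this step with probability
    ``1 - exp(-p4_rate * dt)`` and every rank-5+ vertex with
    ``1 - exp(-p5plus_rate * dt)``.  Vertices are visited in increasing
    id order and each consumes one uniform draw from ``rng`` (plus one
    more on an energy tie), so runs are reproducible given the seed.
    """
    mesh._l_new = params.l_new  # type: ignore[attr-defined]
    inc = _incidence(mesh)
    rank_arr = inc.vertex_rank_array(mesh)
    if int(rank_arr.max(initial=0)) < 4:
        return []
    ranks = {int(mesh.vids[i]): int(r) for i, r in enumerate(rank_arr) if r >= 4}
    records: list[ResolutionRecord] = []
    for vid in sorted(ranks):
        rate = params.p4_rate if ranks[vid] == 4 else params.p5plus_rate
        prob = params.step_probability(rate)
        if rng.random() >= prob:
            continue
        pinch = _choose_pinch(mesh, vid, params, rng)
        records.append(split_vertex(mesh, vid, pinch))
    return records
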
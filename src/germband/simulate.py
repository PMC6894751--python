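"""Germband-extension simulations: main loop, presets and tracks export.

One step of the simulation is: passive relaxation (overdamped gradient
descent), edge merges (junctions below the collapse threshold form
higher-order vertices), probabilistic vertex resolution, and the
posterior pull.  Snapshots are stored every 30 simulated seconds to
mimic a time-lapse movie, and can be exported as tracked-cell tables so
the analysis modules run identically on simulated and real-style data.

Named presets reproduce the published parameterisations: ``WT``
(p4 = 1/min, p5+ = 0.1/min), ``sdk`` (p4 = 0.1/min, p5+ = 0/min, so
rosettes never resolve and rearrangements get stuck) and ``sdk_soft``
(as ``sdk`` with the perimeter contractility lowered to 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import VertexMesh, build_hex_tissue, census_vertex_ranks
from .mechanics import (
    PRESETS,
    ModelParams,
    compute_energy,
    equilibrate_scale,
    relax_box_dv,
    relax_step,
    _incidence,
)
from .events import attempt_edge_merges, resolve_vertices
from .pull import apply_posterior_pull
from .tracks import (
    CELL_COLUMNS,
    INTERFACE_COLUMNS,
    AxisFrame,
    EmbryoTracks,
    _format_outline,
)

__all__ = ["SimulationResult", "simulate_gbe", "mesh_to_frame", "PRESETS", "UM_PER_MODEL"]

#: one hexagon side of the reference packing corresponds to ~3.4 μm
_HEX_SIDE = float(np.sqrt(2.0 / (3.0 * np.sqrt(3.0))))
UM_PER_MODEL = 3.4 / _HEX_SIDE

#: snapshot cadence in minutes (30-s movie frames)
SNAPSHOT_INTERVAL_MIN = 0.5

#: initial positional jitter (fraction of a hexagon side) breaking the
#: perfect lattice symmetry, as segmentation noise would
INIT_JITTER_FRACTION = 0.03


@dataclass
class SimulationResult:
    params: ModelParams
    snapshots: list[VertexMesh]           #: deep copies, every 0.5 min
    snapshot_times: list[float]
    events: pd.DataFrame                  #: time, kind, vertex, rank, cells
    diagnostics: dict = field(default_factory=dict)

    def census_series(self) -> pd.DataFrame:
        rows = []
        for t, m in zip(self.snapshot_times, self.snapshots):
            _, counts = census_vertex_ranks(m)
            ranks = m.ranks()
            rows.append(
                {
                    "time_min": t,
                    "cells_rank3": counts["3"],
                    "cells_rank4": counts["4"],
                    "cells_rank5plus": counts["5+"],
                    "vertices_rank4plus": sum(1 for r in ranks.values() if r >= 4),
                    "vertices_rank5plus": sum(1 for r in ranks.values() if r >= 5),
                }
            )
        return pd.DataFrame(rows)

    def to_tracks(self) -> EmbryoTracks:
        """Export snapshots as tracked-cell tables in μm."""
        cell_rows: list[dict] = []
        iface_rows: list[dict] = []
        n_frames = len(self.snapshots)
        pair_frames: dict[frozenset, set[int]] = {}
        per_frame_edges = []
        for f, mesh in enumerate(self.snapshots):
            edges = mesh.edges()
            per_frame_edges.append(edges)
            for cs in edges.values():
                pair_frames.setdefault(frozenset(cs), set()).add(f)
        for f, mesh in enumerate(self.snapshots):
            for cid in sorted(mesh.cells):
                poly = mesh.cell_polygon(cid) * UM_PER_MODEL
                c = mesh.cell_centroid(cid) * UM_PER_MODEL
                cell_rows.append(
                    {
                        "frame": f,
                        "cell_id": cid,
                        "x": c[0],
                        "y": c[1],
                        "outline": _format_outline(poly),
                        "cell_type": f"S{mesh.stripe[cid] + 1}",
                        "prev_id": cid if f > 0 else -1,
                        "next_id": cid if f < n_frames - 1 else -1,
                    }
                )
            for e, cs in sorted(
                per_frame_edges[f].items(), key=lambda kv: sorted(kv[1])
            ):
                v1, v2 = tuple(e)
                p1 = mesh.position(v1) * UM_PER_MODEL
                p2 = (mesh.position(v1) + mesh.edge_vector(v1, v2)) * UM_PER_MODEL
                a, b = sorted(cs)
                iid = f"{a}-{b}"
                pair = frozenset(cs)
                iface_rows.append(
                    {
                        "frame": f,
                        "interface_id": iid,
                        "cell_a": a,
                        "cell_b": b,
                        "x1": p1[0],
                        "y1": p1[1],
                        "x2": p2[0],
                        "y2": p2[1],
                        "prev_id": iid if (f - 1) in pair_frames[pair] else "",
                        "next_id": iid if (f + 1) in pair_frames[pair] else "",
                    }
                )
        return EmbryoTracks(
            cells=pd.DataFrame(cell_rows, columns=CELL_COLUMNS),
            interfaces=pd.DataFrame(iface_rows, columns=INTERFACE_COLUMNS),
            frame_interval_s=SNAPSHOT_INTERVAL_MIN * 60.0,
            axes=AxisFrame(),
        )


def mesh_to_frame(mesh: VertexMesh) -> dict:
    """JSON-serialisable snapshot of a mesh."""
    return {
        "time_min": mesh.time,
        "box": list(mesh.box),
        "vertices": {int(v): mesh.position(v).tolist() for v in mesh.vids},
        "cells": {int(c): [int(v) for v in loop] for c, loop in mesh.cells.items()},
        "stripe": {int(c): int(s) for c, s in mesh.stripe.items()},
        "unit_map": {"um_per_model_length": UM_PER_MODEL, "min_per_model_time": 1.0},
    }


def simulate_gbe(
    params: ModelParams | str,
    nx: int = 14,
    ny: int = 20,
    check_invariants: bool = True,
    validate_every: int = 100,
    **overrides,
) -> SimulationResult:
    """Run a germband-extension simulation.

    Parameters
    ----------
    params
        A :class:`ModelParams` or a preset name (``"WT"``, ``"sdk"``,
        ``"sdk_soft"``); keyword overrides update individual fields.
    nx, ny
        Tissue size in hexagon columns x rows (default 14 x 20 = 280
        cells).
    check_invariants
        Monitor per-step energy monotonicity of the passive relaxation
        and the topological invariants; violations abort the run.
    validate_every
        Steps between full topology validations (Euler characteristic
        and cell count are checked every step regardless).

    Returns a :class:`SimulationResult` with 30-s snapshots, the event
    log and run diagnostics.  Runs are deterministic given the seed.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    if overrides:
        params = params.replace(**overrides)

    rng = np.random.default_rng(params.seed)
    mesh = build_hex_tissue(nx, ny, area=params.A0)
    mesh._n_columns = nx  # type: ignore[attr-defined]
    scale = equilibrate_scale(mesh, params)
    jitter = INIT_JITTER_FRACTION * _HEX_SIDE * np.sqrt(params.A0)
    mesh.pos += rng.normal(scale=jitter, size=mesh.pos.shape)
    mesh.wrap()

    n_steps = int(round(params.t_end / params.dt))
    snap_every = max(1, int(round(SNAPSHOT_INTERVAL_MIN / params.dt)))
    n_cells0 = mesh.n_cells

    snapshots = [mesh.copy()]
    snapshot_times = [0.0]
    event_rows: list[dict] = []
    max_energy_increase = 0.0
    e_prev = compute_energy(mesh, params)

    for step in range(1, n_steps + 1):
        mesh.time = step * params.dt

        # 1) passive relaxation
        if check_invariants:
            e_before = compute_energy(mesh, params)
            e_after = relax_step(mesh, params, check_energy=True)
            max_energy_increase = max(max_energy_increase, e_after - e_before)
        else:
            relax_step(mesh, params)

        # 2) junction collapses
        for rec in attempt_edge_merges(mesh, params):
            event_rows.append(
                {
                    "time_min": rec.time,
                    "kind": "merge",
                    "vertex": rec.new_vertex,
                    "rank": rec.rank,
                    "cells": "|".join(map(str, rec.losing_cells)),
                }
            )

        # 3) probabilistic resolutions
        for rec in resolve_vertices(mesh, params, rng):
            event_rows.append(
                {
                    "time_min": rec.time,
                    "kind": "resolve",
                    "vertex": rec.vertex,
                    "rank": rec.rank,
                    "cells": "|".join(map(str, rec.gaining_pair)),
                }
            )

        # 4) posterior pull, then the DV box convergence channel
        apply_posterior_pull(mesh, params)
        relax_box_dv(mesh, params)

        if check_invariants:
            if mesh.n_cells != n_cells0:
                raise RuntimeError(f"cell count changed at step {step}")
            if mesh.n_vertices - _incidence(mesh).n_edges() + mesh.n_cells != 0:
                raise RuntimeError(f"Euler characteristic broken at step {step}")
            if step % validate_every == 0:
                mesh.validate(check_geometry=False)

        if step % snap_every == 0:
            snapshots.append(mesh.copy())
            snapshot_times.append(mesh.time)

    e_final = compute_energy(mesh, params)
    events = pd.DataFrame(
        event_rows, columns=["time_min", "kind", "vertex", "rank", "cells"]
    )
    return SimulationResult(
        params=params,
        snapshots=snapshots,
        snapshot_times=snapshot_times,
        events=events,
        diagnostics={
            "max_relax_energy_increase": max_energy_increase,
            "initial_energy": e_prev,
            "final_energy": e_final,
            "final_box": mesh.box,
            "equilibration_scale": scale,
        },
    )
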
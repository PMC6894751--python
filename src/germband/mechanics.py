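"""Passive mechanics: energy, forces, relaxation and tissue stress.

The tissue energy is the standard vertex-model functional

    E = sum_cells K/2 (A - A0)^2  +  sum_edges Lambda_e * l_e
        + sum_cells Gamma/2 * L^2

with area elasticity ``K``, preferred area ``A0``, line tension
``Lambda_e`` per junction and perimeter contractility ``Gamma``.
Junctions between cells of *different* stripe identity carry a
supplementary cable tension ``Lambda_cable`` on top of ``Lambda``,
representing the planar-polarised actomyosin cables of parasegment
boundaries that drive junction shortening during germband extension.

Dynamics are overdamped gradient descent with unit friction:
``x <- x - dt * dE/dx``.  The global (Batchelor/virial) stress tensor is
the exact derivative of the energy with respect to an affine box strain,
normalised by box area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import VertexMesh, MeshTopologyError

__all__ = [
    "ModelParams",
    "StepSizeError",
    "compute_energy",
    "compute_forces",
    "relax_step",
    "measure_tissue_stress",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the vertex model, all in dimensionless model units.

    Lengths are in units where a regular hexagon of the preferred area
    ``A0 = 1`` has side ~0.62; time is in minutes.
    """

    Lambda: float = 0.05          #: junctional line tension
    Gamma: float = 0.04           #: perimeter contractility
    K: float = 1.0                #: area elastic modulus
    A0: float = 1.0               #: preferred cell area
    Lambda_cable: float = 0.10    #: extra tension on stripe-mismatch junctions
    p4_rate: float = 1.0          #: resolution rate of rank-4 vertices (/min)
    p5plus_rate: float = 0.1      #: resolution rate of rank-5+ vertices (/min)
    sigma_posterior: float = 3e-4  #: peak posterior stress (model units)
    sigma_plateau_min: float = 15.0  #: pull held constant until this time
    sigma_end_min: float = 30.0   #: pull ramps linearly to zero at this time
    l_merge: float = 0.25         #: edge-collapse threshold length
    l_new: float = 0.375          #: new-edge length on resolution
    dt: float = 0.01              #: time step (minutes)
    t_end: float = 30.0           #: simulated duration (minutes)
    seed: int = 0                 #: RNG seed
    probe_strain: float = 1e-3    #: probe strain for stiffness measurement
    posterior_columns: int = 2    #: width of the pulled region, in columns
    box_dv_mobility: float = 0.25  #: DV box-strain rate per unit DV stress (/min)
    cable_spread: float = 0.5     #: quenched +/- spread of per-junction cable tension

    def __post_init__(self) -> None:
        for name in ("Lambda", "Gamma", "K", "A0", "l_merge", "l_new", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p4_rate", "p5plus_rate", "Lambda_cable", "sigma_posterior"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sigma_at(self, t: float) -> float:
        """Posterior stress schedule: plateau, then linear ramp to zero."""
        if t < self.sigma_plateau_min:
            return self.sigma_posterior
        if t >= self.sigma_end_min:
            return 0.0
        frac = (self.sigma_end_min - t) / (self.sigma_end_min - self.sigma_plateau_min)
        return self.sigma_posterior * frac

    def step_probability(self, rate: float) -> float:
        """Per-step resolution probability, ``1 - exp(-rate * dt)``."""
        return float(-np.expm1(-rate * self.dt))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


PRESETS: dict[str, ModelParams] = {
    "WT": ModelParams(p4_rate=1.0, p5plus_rate=0.1),
    "sdk": ModelParams(p4_rate=0.1, p5plus_rate=0.0),
    "sdk_soft": ModelParams(p4_rate=0.1, p5plus_rate=0.0, Gamma=0.01),
}


class StepSizeError(RuntimeError):
    """Gradient step increased the energy beyond tolerance."""


# ----------------------------------------------------------------------
# cached incidence arrays
# ----------------------------------------------------------------------
class _Incidence:
    """Flat index arrays for vectorised energy/force evaluation.

    Valid until the mesh topology changes; geometry (positions, box) may
    move freely underneath.
    """

    def __init__(self, mesh: VertexMesh):
        cids = list(mesh.cells)
        self.cids = cids
        loop_rows: list[int] = []
        cell_of_entry: list[int] = []
        starts: list[int] = []
        for ci, cid in enumerate(cids):
            starts.append(len(loop_rows))
            for v in mesh.cells[cid]:
                loop_rows.append(mesh.row(v))
                cell_of_entry.append(ci)
        self.loop_rows = np.array(loop_rows, dtype=np.intp)
        self.cell_of_entry = np.array(cell_of_entry, dtype=np.intp)
        self.starts = np.array(starts, dtype=np.intp)
        n = len(loop_rows)
        ends = np.append(self.starts[1:], n)
        # index of next/prev entry within each loop
        nxt = np.arange(1, n + 1)
        prv = np.arange(-1, n - 1)
        nxt[ends - 1] = self.starts
        prv[self.starts] = ends - 1
        self.next_entry = nxt
        self.prev_entry = prv

        # distinct edges with their total line tension
        lam: dict[frozenset, float] = {}
        everts: dict[frozenset, tuple[int, int]] = {}
        ecells: dict[frozenset, list[int]] = {}
        for cid in cids:
            loop = mesh.cells[cid]
            for k in range(len(loop)):
                e = frozenset((loop[k], loop[(k + 1) % len(loop)]))
                ecells.setdefault(e, []).append(cid)
                everts[e] = (loop[k], loop[(k + 1) % len(loop)])
        self.edge_keys = list(everts)
        self.edge_cells = {e: tuple(ecells[e]) for e in self.edge_keys}
        self.e1 = np.array([mesh.row(everts[e][0]) for e in self.edge_keys], dtype=np.intp)
        self.e2 = np.array([mesh.row(everts[e][1]) for e in self.edge_keys], dtype=np.intp)
        self._mismatch = np.array(
            [
                mesh.stripe[ecells[e][0]] != mesh.stripe[ecells[e][1]]
                if len(ecells[e]) == 2
                else False
                for e in self.edge_keys
            ]
        )

    def edge_tensions(self, params: ModelParams) -> np.ndarray:
        """Per-edge line tension, including quenched cable variability.

        Junctions between unlike stripes carry ``Lambda_cable`` scaled by
        a factor drawn uniformly from ``1 +/- cable_spread``.  The factor
        is a pure function of the run seed and the (unordered) cell pair,
        so it is quenched: stable over time, across topology rebuilds,
        and restored if the same junction re-forms.
        """
        key = (params.seed, params.cable_spread, params.Lambda, params.Lambda_cable)
        if getattr(self, "_tension_key", None) == key:
            return self._tension_cache
        factors = np.zeros(len(self.edge_keys))
        for i, e in enumerate(self.edge_keys):
            if self._mismatch[i]:
                a, b = sorted(self.edge_cells[e])
                u = np.random.default_rng((params.seed, a, b)).random()
                factors[i] = 1.0 - params.cable_spread + 2.0 * params.cable_spread * u
        self._tension_cache = params.Lambda + params.Lambda_cable * factors
        self._tension_key = key
        return self._tension_cache

    def n_edges(self) -> int:
        return len(self.edge_keys)

    def vertex_rank_array(self, mesh: VertexMesh) -> np.ndarray:
        """Rank (number of incident cells) per vertex row."""
        return np.bincount(self.loop_rows, minlength=len(mesh.vids))

    # -- geometry -------------------------------------------------------
    def geometry(self, mesh: VertexMesh):
        """Per-entry unwrapped coordinates, edge vectors, areas, perimeters."""
        p = mesh.pos[self.loop_rows]
        d = mesh.min_image(p[self.next_entry] - p)
        # unwrapped coordinates q relative to each loop's first vertex
        c = np.cumsum(d, axis=0)
        qs = np.zeros_like(d)
        qs[1:] = c[:-1]
        q = qs - qs[self.starts][self.cell_of_entry]
        cr = q[:, 0] * (q[:, 1] + d[:, 1]) - (q[:, 0] + d[:, 0]) * q[:, 1]
        areas = 0.5 * np.add.reduceat(cr, self.starts)
        elen = np.linalg.norm(d, axis=1)
        perims = np.add.reduceat(elen, self.starts)
        return q, d, elen, areas, perims


def _incidence(mesh: VertexMesh) -> _Incidence:
    inc = getattr(mesh, "_incidence_cache", None)
    if inc is None:
        inc = _Incidence(mesh)
        mesh._incidence_cache = inc  # type: ignore[attr-defined]
    return inc


def invalidate_cache(mesh: VertexMesh) -> None:
    if hasattr(mesh, "_incidence_cache"):
        del mesh._incidence_cache


# ----------------------------------------------------------------------
# energy / forces / stress
# ----------------------------------------------------------------------
def compute_energy(mesh: VertexMesh, params: ModelParams) -> float:
    """Total vertex-model energy of the tissue (model units)."""
    inc = _incidence(mesh)
    _, _, elen, areas, perims = inc.geometry(mesh)
    if np.any(areas <= 0):
        raise MeshTopologyError("degenerate cell with non-positive area")
    e_area = 0.5 * params.K * np.sum((areas - params.A0) ** 2)
    e_per = 0.5 * params.Gamma * np.sum(perims**2)
    lam = inc.edge_tensions(params)
    ev = mesh.min_image(mesh.pos[inc.e2] - mesh.pos[inc.e1])
    e_line = float(np.sum(lam * np.linalg.norm(ev, axis=1)))
    return float(e_area + e_per + e_line)


def compute_forces(mesh: VertexMesh, params: ModelParams) -> np.ndarray:
    """Negative energy gradient, ``(n_vertices, 2)``."""
    inc = _incidence(mesh)
    q, d, elen, areas, perims = inc.geometry(mesh)
    if np.any(areas <= 0):
        raise MeshTopologyError("degenerate cell with non-positive area")
    grad = np.zeros_like(mesh.pos)

    # area term: dA/dq_k = 0.5 * (y_{k+1} - y_{k-1}, x_{k-1} - x_{k+1})
    qn = q + d                      # position of next vertex
    qp = q - d[inc.prev_entry]      # position of previous vertex
    dA = 0.5 * np.stack([qn[:, 1] - qp[:, 1], qp[:, 0] - qn[:, 0]], axis=1)
    coef = (params.K * (areas - params.A0))[inc.cell_of_entry]
    np.add.at(grad, inc.loop_rows, coef[:, None] * dA)

    # perimeter term: dL/dq_k = u_{k-1} - u_k with u = d/|d|
    with np.errstate(invalid="ignore", divide="ignore"):
        u = d / elen[:, None]
    u = np.nan_to_num(u)
    dL = u[inc.prev_entry] - u
    coefL = (params.Gamma * perims)[inc.cell_of_entry]
    np.add.at(grad, inc.loop_rows, coefL[:, None] * dL)

    # line tension on distinct edges
    lam = inc.edge_tensions(params)
    ev = mesh.min_image(mesh.pos[inc.e2] - mesh.pos[inc.e1])
    el = np.linalg.norm(ev, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ue = ev / el[:, None]
    ue = np.nan_to_num(ue)
    np.add.at(grad, inc.e1, -lam[:, None] * ue)
    np.add.at(grad, inc.e2, lam[:, None] * ue)

    return -grad


def relax_step(
    mesh: VertexMesh,
    params: ModelParams,
    check_energy: bool = False,
    tol: float = 1e-10,
    max_backtracks: int = 8,
) -> float:
    """One overdamped gradient-descent step, in place.

    Vertices move by ``dt * F`` with unit friction.  When
    ``check_energy`` is set, the energy after the step is compared with
    the energy before; if it increased by more than ``tol`` the step is
    retried with a halved increment (gradient descent is guaranteed to
    descend for a small enough step), and a :class:`StepSizeError` is
    raised only if ``max_backtracks`` halvings do not suffice.

    Returns the post-step energy if ``check_energy`` else ``nan``.
    """
    F = compute_forces(mesh, params)
    if not check_energy:
        mesh.pos += params.dt * F
        mesh.wrap()
        return float("nan")
    e0 = compute_energy(mesh, params)
    base = mesh.pos.copy()
    dt = params.dt
    for _ in range(max_backtracks + 1):
        mesh.pos = base + dt * F
        e1 = compute_energy(mesh, params)
        if e1 <= e0 + tol:
            mesh.wrap()
            return float(e1)
        dt *= 0.5
    mesh.pos = base
    raise StepSizeError(
        f"energy increased from {e0:.12g} to {e1:.12g} despite backtracking"
    )


def rescale_box(mesh: VertexMesh, cx: float, cy: float) -> None:
    """Affinely rescale positions and box by (cx, cy), in place."""
    mesh.pos[:, 0] *= cx
    mesh.pos[:, 1] *= cy
    mesh.box = (mesh.box[0] * cx, mesh.box[1] * cy)


def equilibrate_scale(mesh: VertexMesh, params: ModelParams) -> float:
    """Rescale the tissue isotropically to its energy minimum, in place.

    A freshly built lattice at the preferred area is under net tension
    (line tension and contractility both favour shrinking), so the
    mechanical ground state has cells slightly smaller than ``A0``.
    Starting from the minimum removes the spurious isotropic pre-stress
    that would otherwise masquerade as a deformation drive.

    Returns the applied scale factor.
    """
    from scipy.optimize import minimize_scalar

    base_pos = mesh.pos.copy()
    base_box = mesh.box

    def energy_at(logc: float) -> float:
        c = float(np.exp(logc))
        mesh.pos = base_pos * c
        mesh.box = (base_box[0] * c, base_box[1] * c)
        return compute_energy(mesh, params)

    res = minimize_scalar(energy_at, bounds=(-0.5, 0.5), method="bounded",
                          options={"xatol": 1e-10})
    c = float(np.exp(res.x))
    mesh.pos = base_pos * c
    mesh.box = (base_box[0] * c, base_box[1] * c)
    return c


def relax_box_dv(mesh: VertexMesh, params: ModelParams) -> float:
    """One overdamped step of the DV box degree of freedom, in place.

    The box height creeps towards zero DV stress at strain rate
    ``-box_dv_mobility * sigma_yy``; this is the convergence channel of
    convergent extension (a periodic box cannot converge otherwise).
    Returns the applied DV strain increment.
    """
    if params.box_dv_mobility == 0.0:
        return 0.0
    sigma_yy = measure_tissue_stress(mesh, params)[1, 1]
    eps = float(np.clip(-params.box_dv_mobility * sigma_yy * params.dt, -1e-3, 1e-3))
    rescale_box(mesh, 1.0, 1.0 + eps)
    return eps


def measure_tissue_stress(mesh: VertexMesh, params: ModelParams) -> np.ndarray:
    """Global 2x2 symmetric stress tensor (virial form).

    ``sigma = (1/A_box) * [ sum_c K (A_c - A0) A_c I
    + sum_e T_e (d x d) / l ]`` where the effective tension ``T_e`` of an
    edge collects its line tension plus ``Gamma * L`` from both incident
    cells.  This is the exact derivative of the energy with respect to
    affine box strain, divided by the box area.
    """
    inc = _incidence(mesh)
    _, d, elen, areas, perims = inc.geometry(mesh)
    if np.any(areas <= 0) or np.any(elen <= 0):
        raise MeshTopologyError("degenerate mesh in stress evaluation")
    Lx, Ly = mesh.box
    sigma = np.zeros((2, 2))
    pressure_term = params.K * np.sum((areas - params.A0) * areas)
    sigma[0, 0] += pressure_term
    sigma[1, 1] += pressure_term
    # perimeter contribution, per loop entry
    coefL = (params.Gamma * perims)[inc.cell_of_entry] / elen
    sigma += np.einsum("k,ki,kj->ij", coefL, d, d)
    # line tension on distinct edges
    lam = inc.edge_tensions(params)
    ev = mesh.min_image(mesh.pos[inc.e2] - mesh.pos[inc.e1])
    el = np.linalg.norm(ev, axis=1)
    sigma += np.einsum("k,ki,kj->ij", lam / el, ev, ev)
    sigma /= Lx * Ly
    return 0.5 * (sigma + sigma.T)
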
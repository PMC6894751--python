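"""Posterior pulling stress, converted to strain via a stiffness probe.

The invaginating posterior midgut pulls on the germband along AP.  The
model represents this as an applied stress ``sigma_posterior`` acting on
the posterior-most region of the tissue.  Because the simulation moves
vertices, not stresses, the applied stress is converted to a strain each
step: a small probe strain ``E_x`` is applied to the posterior region,
the AP stiffness ``C_xx`` is measured as the change in tissue-level
AP stress over ``E_x``, the probe is reverted exactly, and the true
posterior strain ``E_posterior = sigma_posterior / C_xx`` is then
applied as ``x -> x + E_posterior * x`` on the region (with the box
length updated so the tiling stays periodic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import VertexMesh
from .mechanics import ModelParams, measure_tissue_stress

__all__ = ["PosteriorPullProbe", "StiffnessError", "apply_posterior_pull", "probe_stiffness"]


class StiffnessError(RuntimeError):
    """Probed AP stiffness was non-positive; the pull step is aborted."""


@dataclass(frozen=True)
class PosteriorPullProbe:
    E_x: float               #: probe strain applied to the posterior region
    sigma_xx_before: float   #: AP tissue stress before the probe
    sigma_xx_after: float    #: AP tissue stress with the probe applied
    C_xx: float              #: AP stiffness, (after - before) / E_x
    E_posterior: float       #: applied strain, sigma_posterior / C_xx


def _posterior_mask(mesh: VertexMesh, params: ModelParams) -> tuple[np.ndarray, float]:
    """Vertices in the posterior region and the region's anterior edge x0.

    The region is the posterior-most strip of the box, two hexagon
    columns wide at the initial packing; it is defined geometrically (as
    a fraction of the box) so it tracks the tissue as cells rearrange.
    """
    Lx, _ = mesh.box
    n_cols = getattr(mesh, "_n_columns", 14)
    frac = params.posterior_columns / n_cols
    x0 = Lx * (1.0 - frac)
    return mesh.pos[:, 0] >= x0, x0


def _stretch(mesh: VertexMesh, mask: np.ndarray, x0: float, strain: float) -> None:
    """x -> x0 + (1 + strain) (x - x0) on masked vertices; box follows."""
    Lx, Ly = mesh.box
    mesh.pos[mask, 0] = x0 + (1.0 + strain) * (mesh.pos[mask, 0] - x0)
    mesh.box = (Lx + strain * (Lx - x0), Ly)


def probe_stiffness(
    mesh: VertexMesh, params: ModelParams
) -> tuple[float, float, float]:
    """Measure the AP stiffness of the posterior region by probe strain.

    Applies the probe strain ``E_x`` to the posterior region, records
    the AP tissue-stress change, and reverts the mesh exactly (the
    positions after revert are bitwise identical to the input).

    Returns ``(C_xx, sigma_xx_before, sigma_xx_after)``.
    """
    mask, x0 = _posterior_mask(mesh, params)
    E_x = params.probe_strain
    sigma_before = measure_tissue_stress(mesh, params)[0, 0]
    saved_pos = mesh.pos.copy()
    saved_box = mesh.box
    _stretch(mesh, mask, x0, E_x)
    sigma_after = measure_tissue_stress(mesh, params)[0, 0]
    mesh.pos = saved_pos  # exact revert, bitwise
    mesh.box = saved_box
    return (sigma_after - sigma_before) / E_x, float(sigma_before), float(sigma_after)


def apply_posterior_pull(
    mesh: VertexMesh,
    params: ModelParams,
    sigma_posterior: float | None = None,
) -> PosteriorPullProbe:
    """Apply the posterior pull for one step, in place.

    With ``sigma_posterior == 0`` the mesh is untouched and
    ``E_posterior`` is zero.  Otherwise the stiffness is probed (and the
    probe reverted bitwise) before the calibrated strain
    ``E_posterior = sigma_posterior / C_xx`` is applied.

    Raises
    ------
    StiffnessError
        If the probed ``C_xx`` is not positive.
    """
    if sigma_posterior is None:
        sigma_posterior = params.sigma_at(mesh.time)
    if sigma_posterior == 0.0:
        sigma = measure_tissue_stress(mesh, params)[0, 0]
        return PosteriorPullProbe(params.probe_strain, sigma, sigma, float("nan"), 0.0)

    C_xx, sigma_before, sigma_after = probe_stiffness(mesh, params)
    if C_xx <= 0:
        raise StiffnessError(f"probed C_xx = {C_xx:.6g} <= 0 at t = {mesh.time} min")
    E_post = sigma_posterior / C_xx
    mask, x0 = _posterior_mask(mesh, params)
    _stretch(mesh, mask, x0, E_post)
    mesh.wrap()
    return PosteriorPullProbe(params.probe_strain, sigma_before, sigma_after, C_xx, E_post)
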
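# Methods

This note documents the model and measurement procedures the package
implements, the parameter choices that matter, and what the synthetic
data do and do not establish about real embryo movies.

## Vertex model

**Energy.** Cells tile a flat torus (periodic box Lx × Ly). The energy
is the standard form E = Σ K/2 (A − A₀)² + Σ Λₑ ℓₑ + Σ Γ/2 L² with
K = A₀ = 1 defining the units; (Λ, Γ) = (0.05, 0.04) for wild type and
Γ = 0.01 for the "soft" variant. One model length unit corresponds to
≈ 5.48 μm so that a reference hexagon side is ≈ 3.4 μm; one time unit
is one minute.

**Cables.** Each cell carries one of four stripe identities repeating
along AP (column index mod 4). Junctions between cells of different
stripes receive supplementary tension Λ_cable = 0.2 (4Λ), standing in
for parasegmental actomyosin cables. Each such junction's cable
tension is additionally scaled by a quenched factor drawn uniformly
from 1 ± 0.5, a pure function of the run seed and the unordered cell
pair. The disorder mimics junction-to-junction variability in myosin
recruitment; mechanically it is what staggers junction collapses in
time — a perfectly uniform tissue reaches the collapse threshold
everywhere in the same step, which is neither realistic nor useful.
Both the cable magnitude and the spread are model choices: with the
weaker 2Λ cables no junction ever collapses within 30 min under this
quasi-static dynamics.

**Dynamics.** Overdamped gradient descent, unit friction, dt = 0.01 min,
30 simulated minutes. A relaxation step moves vertices by −dt ∇E; when
invariant checking is on, a step that would raise the energy by more
than 1e−10 is retried with a halved increment (gradient descent
descends for a small enough step), and errors out only if backtracking
fails. In practice the nominal step never needs backtracking.

**Initial state.** A regular 14 × 20 hexagon tiling (280 cells) is
first rescaled isotropically to its energy minimum — a fresh lattice at
the preferred area is under net tension, and starting away from the
minimum would masquerade as a deformation drive — and then perturbed
with Gaussian vertex jitter of 3% of a hexagon side (segmentation-scale
noise; also a symmetry breaker).

**Convergence channel.** The box height relaxes towards zero DV stress
at strain rate −k σ_yy with mobility k = 0.25 per unit stress per
minute. A periodic box has no other way to converge along DV, and
without convergence the DV-spanning cable chains — whose total vertical
extent is pinned to Ly — can never shorten their junctions to the
collapse threshold. The mobility was chosen so the initial DV
convergence rate (≈ −0.02/min) matches the magnitude observed in
germband movies. The box width is driven only by the posterior pull.

**Topological events.** A junction shorter than ℓ_merge = 0.25
collapses to its midpoint, producing a rank-4 vertex (protorosette), or
rank 5+ (rosette) when an endpoint was already high-rank; collapses
that would create a two-sided cell are skipped. ℓ_merge sits at about
half the converged junction length so that collapse is reached on the
convergence path over the 30-min run; ℓ_new = 1.5 ℓ_merge prevents
immediate re-collapse of resolved junctions. Per step, each rank-4
vertex resolves with probability 1 − exp(−p₄ dt) and each rank-5+
vertex with 1 − exp(−p₅₊ dt) (the exponential convention makes
behaviour invariant to dt refinement). A rank-4 vertex created by a
collapse remembers the cell pair that lost the junction, and its
resolution completes the T1 (the previously non-adjacent pair gains a
junction). A rank-r (r ≥ 5) resolution pinches off one cell — creating
a fresh rank-3 vertex and leaving rank r−1 — choosing among the r
admissible pinches the one that most lowers the energy, ties broken
uniformly with the run RNG. All stochastic draws consume a single
seeded generator in a documented order (vertices visited by increasing
id), so runs are bit-reproducible.

**Posterior pull.** The applied stress follows a plateau of
σ_posterior = 3e−4 (model units) for 15 min, then ramps linearly to
zero at 30 min. Each step the posterior region — the posterior-most
strip of the box, two hexagon columns wide at the initial packing,
defined geometrically so it tracks the tissue — is probed with a small
strain E_x = 1e−3 (x → x₀ + (1+E_x)(x−x₀), box length updated so the
tiling stays periodic); the AP stiffness is C_xx = Δσ_xx/E_x on the
tissue-level virial stress; the probe is reverted bitwise; and the true
strain E_post = σ_posterior/C_xx is applied the same way. σ_posterior
was calibrated so the initial AP tissue strain rate is ≈ 0.026/min,
inside the 0.02–0.03/min target for early GBE. Stress is the exact
derivative of the energy under affine box strain (cell-pressure
identity term plus tension dyads), validated against finite differences.

**Phenomenology at the defaults.** Junction collapses begin ≈ 4 min in
and continue throughout. With wild-type rates protorosettes resolve in
≈ 1 min and rosettes in ≈ 10 min, so the census of stuck vertices
stays low and net productive T1s accumulate (≈ 0.3 per DV interface by
30 min, seed 1). With the impaired rates (p₄ = 0.1/min, p₅₊ = 0)
rosettes grow monotonically and productive intercalation nearly
vanishes — the simulated mutant phenotype.

## Tracked-cell data model

One CSV per entity plus a JSON header. `cells.csv`: frame, cell_id,
centroid x/y (μm), outline (full-precision coordinate string),
cell_type, prev/next temporal links. `interfaces.csv`: frame,
interface id, incident cell pair, endpoint coordinates, temporal
links. `header.json`: frame interval (30 s default), AP/DV unit
vectors, midline position, unit. Validation enforces referential
integrity, simple outlines, centroid consistency (1e−6 μm) and link
integrity. Zero-length interfaces (four-way configurations) are not
written; adjacency treats lengths ≤ 1e−9 μm as no contact.

Simulator exports unwrap each cell across the periodic seam
individually, so a small fraction of cell pairs near the seam have
centroids on opposite sides of the field. Topological analyses are
unaffected; distance-based analyses can drop such domains with the
`max_neighbour_distance_um` guard.

## Synthetic generators

**Affine flows.** A hexagon patch (side 2 μm, cell area ≈ 10.4 μm², in
the germband apical range; 61 frames at 30 s by default) advected by
x(t+dt) = expm(G dt) x(t) plus optional uniform drift. The matrix
exponential makes antisymmetric G an exact isometry, so rotation tests
are exact rather than O(dt²). Optional Gaussian jitter applies to
centroids only, keeping outline-based recovery interpretable.

**Scripted T1s.** A junction shrinks linearly to zero, holds a
four-way vertex for a scripted number of frames, then the orthogonal
junction grows linearly between the gaining pair; reversions are
supported. All outlines and interfaces stay consistent with the
topology frame by frame. Scripts that touch a common cell in
overlapping windows are rejected. The idealised symmetric swap
(vertical junction, gaining cells directly above/below) realises the
textbook angles exactly: corrected lost–gained angle 90°,
shortening-to-centroid angle 0°.

What the generators do not emulate: segmentation errors, cell
divisions or deaths, curved tissue geometry, drift in the axis frame,
and pixelated (rather than polygonal) outlines. Passing the recovery
tests therefore certifies the estimators' correctness on clean
geometry, not their robustness to every artefact of real movies.

## Measurements

**Ellipse fits.** The best-fit ellipse is constrained to the polygon's
exact area and centroid; the aspect ratio and orientation minimise the
symmetric-difference area against a 128-gon ellipse approximation,
refined by Nelder–Mead (fixed settings, deterministic) from the
second-moment ellipse. The fit never ends worse than its moment-based
start. Tracking pipelines typically fit pixel masks rather than
polygons; the objective is the same, only the discretisation differs.

**Strain rates.** Domains are a focal cell plus its interface corona
over a 2-min, 5-frame window. The tissue tensor comes from a centred
least-squares affine map of member centroids from the window's first
to last frame, converted to a symmetric log-strain rate via the polar
decomposition (rigid rotations drop out exactly; using the full window
suppresses centroid-noise bias, which stays below 10% at 0.1 μm
jitter). The cell-shape tensor fits per-cell boundary-point maps per
frame pair (vertex correspondence when counts match, arc-length
resampling to 64 points otherwise), averages over the window and then
area-weights over member cells. Intercalation is defined as tissue
minus shape, so the decomposition identity is exact by construction.
Movie synchronisation takes the first frame whose domain-median AP
tissue strain rate strictly exceeds 0.01/min. The within-embryo
confidence ribbon is 1.96·sqrt(mean within-embryo variance / N) with N
the per-frame sample count; the pooled variance and N are exported so
alternative normalisations can be formed.

**T1 detection.** Quartets are registered wherever an interface
appears or disappears between frames (the two common neighbours
complete the cycle). Per-frame ownership (which diagonal holds the
interface) is canonicalised: four-way frames inherit the most recent
owner (leading unknowns take the first known owner), and ownership
bouts shorter than 5 frames flanked by a common owner are reversed,
shortest first, earliest first among ties, iterating to a fixed point
(the operation is idempotent). Surviving ownership changes are T1
gains, timed at the first physical contact of the gaining pair.
Orientations use the ±5-min offsets (10 frames at 30 s; nearest frame
otherwise); the lost–gained angle subtracts the rotation of the
gaining pair's centroid line; productive counts subtract AP-oriented
gains from DV-oriented gains (classified by the gaining centroid line
versus 45°, ties DV) and normalise by the per-frame count of
DV-oriented interfaces. Resolution phases smooth the immortal length
series with a 5-frame Hanning window (length not dictated by the
source method; exposed as a parameter) and measure the contiguous
sub-threshold (0.75 μm) run straddling the swap, discarding runs that
touch either end of the series.

## Problem sizes and determinism

The test suite runs ten full 280-cell, 30-min simulations (five seeds
per preset) plus the oracle suites; everything is seeded, and
hypothesis cases are derandomised. The acceptance script's quantities
are deterministic; its seed selects among equivalent interior
junctions of the lattice.

## Known limitations

* The convergence channel is a single global degree of freedom; real
  germbands converge nonuniformly along DV.
* The pull prescribes strain through the probed stiffness each step;
  no inertia or external viscosity, so the AP extension rate tracks
  the stress schedule closely.
* Junction-tension disorder is quenched; there is no temporal myosin
  dynamics, so junction-length fluctuations are underestimated.
* Cell count is fixed: no divisions, extrusions, or 3D mechanics.
* Analyses assume planar tracks; curvature correction of embryo
  surfaces is out of scope.
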
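"""Quasi-static activation-field model for electrode geometry comparison.

Solves the conduction equation div(sigma grad V) = 0 in a 3 mm cube of
brain tissue (sigma = 0.2 S/m) with electrodes modelled as constant
current sources on the cube's bottom face, the far faces grounded, and
the rest of the bottom face insulating.  Rigid geometries carry a 40-um
conformal glial-scar layer (sigma = 0.166 S/m); neurons inside the scar
are not counted.  The solver is a cell-centered finite-volume scheme on a
graded tensor-product grid (fine near the electrodes, coarse toward the
boundary) with harmonic-mean face conductivities, solved by Jacobi
preconditioned conjugate gradients.

Activation follows a current-density criterion: tissue where |J| exceeds
1000 A/m^2 counts as activated, and the activatable-neuron count is that
volume times the neuron density.  ``current_uA`` is the output of one
electrode site; an 8-site array injects eight times that in total.
Because the solution is linear in the injected current, activation curves
and matched currents are computed from a single solve per geometry by
rescaling |J|.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueModel", "ElectrodeGeometry", "ActivationModel", "GridSpec",
    "FieldSolution", "ConvergenceError", "MatchingOutOfRange",
    "build_geometry", "solve_field", "activated_volume", "activated_count",
    "sweep_current", "matching_current", "export_vtk",
]

UM = 1e-6
MM = 1e-3


class ConvergenceError(RuntimeError):
    """Raised when the iterative solve does not reach tolerance."""


class MatchingOutOfRange(RuntimeError):
    """Raised when no current within the search range matches the target."""


@dataclass
class TissueModel:
    """Tissue electrical model (SI units).

    ``rel_permittivity`` is recorded for completeness but unused: the
    solve is quasi-static and the activation criterion is on conduction
    current density.
    """

    sigma_brain: float = 0.2  # S/m
    sigma_glia: float = 0.166  # S/m
    rel_permittivity: float = 88.9
    domain_size: float = 3 * MM  # cube side
    glial_thickness: float = 40 * UM

    def validate(self) -> None:
        if self.sigma_brain <= 0 or self.sigma_glia <= 0:
            raise ValueError("conductivities must be positive")
        if self.glial_thickness < 0:
            raise ValueError("glial thickness must be non-negative")


# array site layout: 8 rectangles of 12 um (x) x 16 um (y) in a single
# column at 30 um center-to-center pitch along y (the 16-site shank covers
# 450 um at the same pitch)
SITE_W = 12 * UM
SITE_H = 16 * UM
SITE_PITCH = 30 * UM
N_SITES = 8
MICROWIRE_RADIUS = 50 * UM

_KINDS = ("flexible_array", "rigid_array", "microwire")


@dataclass
class ElectrodeGeometry:
    """One of the three compared electrode geometries.

    ``rects`` holds (x0, x1, y0, y1) site rectangles on the bottom face;
    ``disc_radius`` is set for the microwire instead.  ``glial_thickness``
    is the conformal scar thickness (0 for the flexible array).
    """

    kind: str
    rects: list[tuple[float, float, float, float]] = dfield(
        default_factory=list)
    disc_radius: float | None = None
    glial_thickness: float = 0.0

    @property
    def n_sites(self) -> int:
        return len(self.rects) if self.rects else 1

    @property
    def site_area(self) -> float:
        if self.disc_radius is not None:
            return np.pi * self.disc_radius ** 2
        x0, x1, y0, y1 = self.rects[0]
        return (x1 - x0) * (y1 - y0)


def build_geometry(kind: str,
                   tissue: TissueModel | None = None) -> ElectrodeGeometry:
    """Construct the flexible-array, rigid-array or microwire geometry.

    Flexible and rigid arrays share sizes and layout; the rigid variants
    additionally carry the conformal glial layer.
    """
    tissue = tissue or TissueModel()
    tissue.validate()
    if kind not in _KINDS:
        raise ValueError(f"unknown electrode kind {kind!r}; "
                         f"expected one of {_KINDS}")
    if kind == "microwire":
        return ElectrodeGeometry(kind, disc_radius=MICROWIRE_RADIUS,
                                 glial_thickness=tissue.glial_thickness)
    yc = (np.arange(N_SITES) - (N_SITES - 1) / 2) * SITE_PITCH
    rects = [(-SITE_W / 2, SITE_W / 2, y - SITE_H / 2, y + SITE_H / 2)
             for y in yc]
    glia = tissue.glial_thickness if kind == "rigid_array" else 0.0
    return ElectrodeGeometry(kind, rects=rects, glial_thickness=glia)


@dataclass
class GridSpec:
    """Graded tensor-product grid: uniform ``h_fine`` spacing inside the
    fine region around the electrodes, geometric growth (``ratio``) out to
    the domain boundary, capped at ``h_max``."""

    h_fine: float
    fine_x: float  # fine half-extent in x
    fine_y: float
    fine_z: float  # fine extent above the bottom face
    ratio: float = 1.35
    h_max: float = 250 * UM

    def scaled(self, factor: float) -> "GridSpec":
        """Refined (factor < 1) or coarsened copy; extents unchanged."""
        return GridSpec(self.h_fine * factor, self.fine_x, self.fine_y,
                        self.fine_z, self.ratio, self.h_max)


#: Default grids resolve the activation volume of each geometry: ~3-4 um
#: cells near the sites, covering the region where |J| can exceed
#: threshold at the currents of interest (<= 100 uA).
DEFAULT_GRIDS = {
    "flexible_array": GridSpec(3 * UM, 60 * UM, 165 * UM, 60 * UM),
    "rigid_array": GridSpec(4 * UM, 130 * UM, 235 * UM, 130 * UM),
    "microwire": GridSpec(4 * UM, 180 * UM, 180 * UM, 180 * UM),
}

#: Coarse grids for fast solver checks (linearity, conservation).
COARSE_GRIDS = {k: GridSpec(v.h_fine * 2.5, v.fine_x, v.fine_y, v.fine_z)
                for k, v in DEFAULT_GRIDS.items()}


def _graded_axis(fine_lo, fine_hi, h, dom_lo, dom_hi, ratio, h_max):
    n_fine = max(1, int(round((fine_hi - fine_lo) / h)))
    edges = list(np.linspace(fine_lo, fine_hi, n_fine + 1))
    step, x = h, fine_hi
    while x < dom_hi - 1e-12:
        step = min(step * ratio, h_max, dom_hi - x)
        x += step
        edges.append(x)
    step, x, left = h, fine_lo, []
    while x > dom_lo + 1e-12:
        step = min(step * ratio, h_max, x - dom_lo)
        x -= step
        left.append(x)
    return np.asarray(left[::-1] + edges)


class _Grid:
    """Cell-centered tensor grid from 1-D edge arrays."""

    def __init__(self, xe, ye, ze):
        self.xe, self.ye, self.ze = xe, ye, ze
        self.xc = 0.5 * (xe[:-1] + xe[1:])
        self.yc = 0.5 * (ye[:-1] + ye[1:])
        self.zc = 0.5 * (ze[:-1] + ze[1:])
        self.dx, self.dy, self.dz = np.diff(xe), np.diff(ye), np.diff(ze)
        self.shape = (len(self.xc), len(self.yc), len(self.zc))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_volumes(self):
        return (self.dx[:, None, None] * self.dy[None, :, None]
                * self.dz[None, None, :])


def _make_grid(geom: ElectrodeGeometry, tissue: TissueModel,
               spec: GridSpec) -> _Grid:
    half = tissue.domain_size / 2
    xe = _graded_axis(-spec.fine_x, spec.fine_x, spec.h_fine, -half, half,
                      spec.ratio, spec.h_max)
    ye = _graded_axis(-spec.fine_y, spec.fine_y, spec.h_fine, -half, half,
                      spec.ratio, spec.h_max)
    ze = _graded_axis(0.0, spec.fine_z, spec.h_fine, 0.0,
                      tissue.domain_size, spec.ratio, spec.h_max)
    return _Grid(xe, ye, ze)


def _glial_mask(grid: _Grid, geom: ElectrodeGeometry) -> np.ndarray:
    """Cells within ``glial_thickness`` of the electrode-bearing surface."""
    t = geom.glial_thickness
    if t <= 0:
        return np.zeros(grid.shape, dtype=bool)
    X = grid.xc[:, None, None]
    Y = grid.yc[None, :, None]
    Z = grid.zc[None, None, :]
    if geom.disc_radius is not None:
        rho = np.sqrt(X ** 2 + Y ** 2)
        d_in_plane = np.maximum(rho - geom.disc_radius, 0.0)
    else:
        x0 = min(r[0] for r in geom.rects)
        x1 = max(r[1] for r in geom.rects)
        y0 = min(r[2] for r in geom.rects)
        y1 = max(r[3] for r in geom.rects)
        dx = np.maximum(np.maximum(x0 - X, X - x1), 0.0)
        dy = np.maximum(np.maximum(y0 - Y, Y - y1), 0.0)
        d_in_plane = np.sqrt(dx ** 2 + dy ** 2)
    return d_in_plane ** 2 + Z ** 2 <= t ** 2


def _rect_overlap(xe, ye, rect):
    x0, x1, y0, y1 = rect
    ox = np.clip(np.minimum(xe[1:], x1) - np.maximum(xe[:-1], x0), 0, None)
    oy = np.clip(np.minimum(ye[1:], y1) - np.maximum(ye[:-1], y0), 0, None)
    return ox[:, None] * oy[None, :]


def _disc_overlap(xe, ye, r, nsub=8):
    nx, ny = len(xe) - 1, len(ye) - 1
    out = np.zeros((nx, ny))
    for i in range(nx):
        if xe[i] > r or xe[i + 1] < -r:
            continue
        xs = np.linspace(xe[i], xe[i + 1], 2 * nsub + 1)[1::2]
        for j in range(ny):
            if ye[j] > r or ye[j + 1] < -r:
                continue
            ys = np.linspace(ye[j], ye[j + 1], 2 * nsub + 1)[1::2]
            frac = np.mean((xs[:, None] ** 2 + ys[None, :] ** 2) <= r * r)
            out[i, j] = frac * (xe[i + 1] - xe[i]) * (ye[j + 1] - ye[j])
    return out


def _assemble(grid: _Grid, sigma: np.ndarray):
    """7-point FV matrix with harmonic-mean face conductivities.

    Bottom face: natural Neumann (sources enter via the RHS).  All other
    faces: Dirichlet V=0 through ghost half-cells.
    """
    N = grid.n_cells
    idx = np.arange(N).reshape(grid.shape)
    diag = np.zeros(N)
    rows, cols, vals = [], [], []

    def couple(tr, ia, ib):
        f, a, b = tr.ravel(), ia.ravel(), ib.ravel()
        rows.append(a); cols.append(b); vals.append(-f)
        rows.append(b); cols.append(a); vals.append(-f)
        np.add.at(diag, a, f)
        np.add.at(diag, b, f)

    d = 0.5 * (grid.dx[:-1] + grid.dx[1:])
    hm = 2 * sigma[:-1] * sigma[1:] / (sigma[:-1] + sigma[1:])
    couple(hm * (grid.dy[None, :, None] * grid.dz[None, None, :])
           / d[:, None, None], idx[:-1], idx[1:])
    d = 0.5 * (grid.dy[:-1] + grid.dy[1:])
    hm = 2 * sigma[:, :-1] * sigma[:, 1:] / (sigma[:, :-1] + sigma[:, 1:])
    couple(hm * (grid.dx[:, None, None] * grid.dz[None, None, :])
           / d[None, :, None], idx[:, :-1], idx[:, 1:])
    d = 0.5 * (grid.dz[:-1] + grid.dz[1:])
    hm = 2 * sigma[:, :, :-1] * sigma[:, :, 1:] / (sigma[:, :, :-1]
                                                   + sigma[:, :, 1:])
    couple(hm * (grid.dx[:, None, None] * grid.dy[None, :, None])
           / d[None, None, :], idx[:, :, :-1], idx[:, :, 1:])

    dirichlet = []  # (cell index, transmissibility) for outflux accounting

    def ground(sig_face, area, dist, ii):
        tr = (sig_face * area / dist).ravel()
        np.add.at(diag, ii.ravel(), tr)
        dirichlet.append((ii.ravel(), tr))

    area_x = grid.dy[:, None] * grid.dz[None, :]
    ground(sigma[0], area_x, 0.5 * grid.dx[0], idx[0])
    ground(sigma[-1], area_x, 0.5 * grid.dx[-1], idx[-1])
    area_y = grid.dx[:, None] * grid.dz[None, :]
    ground(sigma[:, 0], area_y, 0.5 * grid.dy[0], idx[:, 0])
    ground(sigma[:, -1], area_y, 0.5 * grid.dy[-1], idx[:, -1])
    area_z = grid.dx[:, None] * grid.dy[None, :]
    ground(sigma[:, :, -1], area_z, 0.5 * grid.dz[-1], idx[:, :, -1])

    rows.append(np.arange(N)); cols.append(np.arange(N)); vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N))
    return A, dirichlet


def _face_current_density(grid: _Grid, V: np.ndarray, sigma: np.ndarray):
    """|J| at cell centers from averaged face flux densities."""
    J2 = np.zeros(grid.shape)
    for axis, dd in enumerate((grid.dx, grid.dy, grid.dz)):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s_lo, s_hi = sigma[tuple(sl_lo)], sigma[tuple(sl_hi)]
        hm = 2 * s_lo * s_hi / (s_lo + s_hi)
        d = 0.5 * (dd[:-1] + dd[1:])
        shape = [1, 1, 1]
        shape[axis] = len(d)
        jf = hm * (V[tuple(sl_lo)] - V[tuple(sl_hi)]) / d.reshape(shape)
        Jax = np.zeros(grid.shape)
        mid_lo = [slice(None)] * 3
        mid_lo[axis] = slice(1, -1)
        first = [slice(None)] * 3
        first[axis] = 0
        last = [slice(None)] * 3
        last[axis] = -1
        jf_lo = [slice(None)] * 3
        jf_lo[axis] = slice(None, -1)
        jf_hi = [slice(None)] * 3
        jf_hi[axis] = slice(1, None)
        Jax[tuple(mid_lo)] = 0.5 * (jf[tuple(jf_lo)] + jf[tuple(jf_hi)])
        Jax[tuple(first)] = np.take(jf, 0, axis=axis)
        Jax[tuple(last)] = np.take(jf, -1, axis=axis)
        J2 += Jax ** 2
    return np.sqrt(J2)


@dataclass
class FieldSolution:
    """Solved potential and current-density field for one geometry."""

    geometry: ElectrodeGeometry
    tissue: TissueModel
    current_uA: float  # per electrode site
    grid: _Grid
    potential: np.ndarray  # V, (nx, ny, nz)
    j_magnitude: np.ndarray  # A/m^2
    glial: np.ndarray  # bool mask
    injected_A: float  # total injected current
    boundary_outflux_A: float

    @property
    def conservation_error(self) -> float:
        """Relative mismatch between injected and boundary-exiting current."""
        return abs(self.boundary_outflux_A - self.injected_A) \
            / self.injected_A


def solve_field(geom: ElectrodeGeometry, tissue: TissueModel | None = None,
                current_uA: float = 5.0, grid: GridSpec | str | None = None,
                rtol: float = 1e-8, maxiter: int = 30000) -> FieldSolution:
    """Solve the conduction problem at ``current_uA`` per electrode site.

    ``grid`` may be a :class:`GridSpec`, ``"default"``, or ``"coarse"``.
    The injected current is distributed uniformly over each site surface
    (equal current per site).  Raises :class:`ConvergenceError` if CG does
    not reach ``rtol``.
    """
    tissue = tissue or TissueModel()
    tissue.validate()
    if current_uA <= 0:
        raise ValueError("current must be positive")
    if grid is None or grid == "default":
        spec = DEFAULT_GRIDS[geom.kind]
    elif grid == "coarse":
        spec = COARSE_GRIDS[geom.kind]
    elif isinstance(grid, GridSpec):
        spec = grid
    else:
        raise ValueError(f"unknown grid spec {grid!r}")

    g = _make_grid(geom, tissue, spec)
    sigma = np.full(g.shape, tissue.sigma_brain)
    glial = _glial_mask(g, geom)
    sigma[glial] = tissue.sigma_glia

    A, dirichlet = _assemble(g, sigma)
    b = np.zeros(g.shape)
    I_site = current_uA * 1e-6
    if geom.disc_radius is not None:
        ov = _disc_overlap(g.xe, g.ye, geom.disc_radius)
    else:
        ov = sum(_rect_overlap(g.xe, g.ye, r) for r in geom.rects)
    if ov.sum() <= 0:
        raise ValueError("electrode surfaces not resolved by the grid")
    total = I_site * geom.n_sites
    b[:, :, 0] = ov * (total / ov.sum())

    M = sp.diags(1.0 / A.diagonal())
    V, info = spla.cg(A, b.ravel(), rtol=rtol, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ V - b.ravel()) / np.linalg.norm(b)
        raise ConvergenceError(
            f"CG did not converge (info={info}, residual={res:.2e})")
    V = V.reshape(g.shape)
    J = _face_current_density(g, V, sigma)
    outflux = sum(float((tr * V.ravel()[ii]).sum()) for ii, tr in dirichlet)
    return FieldSolution(geom, tissue, current_uA, g, V, J, glial,
                         injected_A=total, boundary_outflux_A=outflux)


@dataclass
class ActivationModel:
    """Threshold-on-|J| activation criterion.

    ``neuron_density`` defaults to the printed M2 constant 135,801 per
    cubic meter; matched-current comparisons are independent of its value
    (it cancels when counts are equated), so it is held as a configurable
    constant.
    """

    j_threshold: float = 1000.0  # A/m^2
    neuron_density: float = 135_801.0  # per m^3, as printed

    def validate(self) -> None:
        if self.j_threshold <= 0 or self.neuron_density <= 0:
            raise ValueError("threshold and density must be positive")


def activated_volume(sol: FieldSolution, j_threshold: float = 1000.0,
                     scale: float = 1.0) -> float:
    """Brain-tissue volume (m^3) with |J| strictly above threshold.

    ``scale`` rescales the solved field linearly (current multiplier);
    glial-scar cells are excluded from the tissue volume.
    """
    act = (sol.j_magnitude * scale > j_threshold) & ~sol.glial
    return float(sol.grid.cell_volumes()[act].sum())


def activated_count(sol: FieldSolution,
                    model: ActivationModel | None = None,
                    scale: float = 1.0) -> float:
    """Activatable neurons: density times suprathreshold tissue volume."""
    model = model or ActivationModel()
    model.validate()
    return model.neuron_density * activated_volume(
        sol, model.j_threshold, scale)


def sweep_current(geom: ElectrodeGeometry,
                  tissue: TissueModel | None = None,
                  model: ActivationModel | None = None,
                  currents_uA=None, grid=None,
                  solution: FieldSolution | None = None) -> pd.DataFrame:
    """Activated count vs. injected current (1-100 uA by default).

    Exploits linearity: one solve at 1 uA per site, rescaled to every
    grid point.  Pass ``solution`` to reuse an existing solve.
    """
    model = model or ActivationModel()
    currents = np.asarray(
        [1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0]
        if currents_uA is None else currents_uA, dtype=float)
    if len(currents) == 0:
        raise ValueError("empty current grid")
    if np.any(np.diff(currents) <= 0):
        raise ValueError("current grid must be ascending")
    sol = solution or solve_field(geom, tissue, 1.0, grid=grid)
    rows = [{"current_uA": c,
             "count": activated_count(sol, model, scale=c / sol.current_uA),
             "volume_m3": activated_volume(sol, model.j_threshold,
                                           scale=c / sol.current_uA)}
            for c in currents]
    return pd.DataFrame(rows)


def matching_current(geom: ElectrodeGeometry,
                     tissue: TissueModel | None = None,
                     model: ActivationModel | None = None,
                     reference_count: float = 0.0,
                     grid=None, solution: FieldSolution | None = None,
                     tol_uA: float = 0.1, max_uA: float = 100.0) -> float:
    """Smallest per-site current whose activated count reaches a reference.

    Bisection on the (monotone) rescaled activation curve to ``tol_uA``.
    Raises :class:`MatchingOutOfRange` if even ``max_uA`` is insufficient.
    """
    model = model or ActivationModel()
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    sol = solution or solve_field(geom, tissue, 1.0, grid=grid)

    def count(c):
        return activated_count(sol, model, scale=c / sol.current_uA)

    if count(max_uA) < reference_count:
        raise MatchingOutOfRange(
            f"{geom.kind} cannot reach the reference count within "
            f"{max_uA} uA")
    lo, hi = 0.0, max_uA
    while hi - lo > tol_uA:
        mid = 0.5 * (lo + hi)
        if count(mid) >= reference_count:
            hi = mid
        else:
            lo = mid
    return hi


def export_vtk(sol: FieldSolution, path) -> None:
    """Write the solution as a legacy ASCII VTK rectilinear grid.

    Point data: potential (V), |J| (A/m^2) and the glial mask, at cell
    centers of the solver grid; loadable in ParaView/VisIt.
    """
    g = sol.grid
    nx, ny, nz = g.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{sol.geometry.kind} at {sol.current_uA} uA per site\n")
        f.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        for name, coords in (("X", g.xc), ("Y", g.yc), ("Z", g.zc)):
            f.write(f"{name}_COORDINATES {len(coords)} double\n")
            f.write(" ".join(f"{c:.9e}" for c in coords) + "\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in (("potential_V", sol.potential),
                          ("J_A_per_m2", sol.j_magnitude),
                          ("glial", sol.glial.astype(float))):
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; our arrays are (x, y, z)
            flat = arr.transpose(2, 1, 0).ravel()
            f.write("\n".join(f"{v:.6e}" for v in flat) + "\n")
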
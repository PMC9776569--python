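"""Finite-difference linear Poisson-Boltzmann electrostatics with focusing.

The solver discretizes  div(eps grad phi) - eps_out kappa^2 phi = -4 pi rho / kT
on a cubic grid (potential in kT/e, lengths in nm, charges in e) with the
standard 7-point stencil.  Dielectric values are sampled at grid-edge
midpoints (eps_in inside the union of atomic spheres, eps_out elsewhere),
charges are spread by trilinear assignment (conserving total charge exactly),
and the linear system is relaxed by checkerboard successive over-relaxation.

A two-step focusing procedure solves a coarse grid over the whole solute with
Debye-screened Coulombic boundary values, then a fine grid centered on a
titratable group with boundary values interpolated from the coarse solution.

On top of the solver sit the charging-energy terms of the multisite titration
model: the intrinsic pKa of each site state,

    pKint(i,s) = pKmod(i,s) - ddG(i,s) / (kT ln 10),

where ddG compares the charging free energy of the state (relative to the
site's reference state) in the protein with the same quantity in the isolated
model compound, and the symmetric site-site coupling matrix W computed from
charge differences with respect to the reference states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from constph.constants import COULOMB_KJ_NM, LN10, debye_kappa, kt_kj
from constph.sites import SiteState, Structure, TitratableSite


class PBConvergenceError(RuntimeError):
    """SOR failed to reach the convergence threshold."""

    def __init__(self, residual: float, iterations: int):
        super().__init__(f"LPBE solver did not converge: residual "
                         f"{residual:.3g} kT/e after {iterations} iterations")
        self.residual = residual
        self.iterations = iterations


# --------------------------------------------------------------------------
# grids and configuration
# --------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Cubic grid: odd number of nodes per side, spacing (nm), center (nm)."""

    nodes_per_side: int
    spacing: float
    center: np.ndarray

    def __post_init__(self):
        if self.nodes_per_side < 9 or self.nodes_per_side % 2 == 0:
            raise ValueError("nodes_per_side must be odd and >= 9")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def half_edge(self) -> float:
        return 0.5 * (self.nodes_per_side - 1) * self.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.center - self.half_edge

    def axis(self) -> np.ndarray:
        return np.arange(self.nodes_per_side) * self.spacing

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        rel = np.atleast_2d(points) - self.origin
        lim = (self.nodes_per_side - 1) * self.spacing - margin
        return np.all((rel >= margin) & (rel <= lim), axis=1)


@dataclass
class PBConfig:
    """Physical and numerical settings of the PB calculation."""

    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.1          # mol/L, 1:1 salt
    temperature: float = 310.0           # K
    convergence_tol: float = 0.01        # kT/e, max node update
    coarse_spacing: float = 0.1          # nm
    fine_spacing: float = 0.025          # nm
    nodes_per_side: int = 81
    boundary: str = "coulombic_debye"    # or "zero"
    dielectric_smoothing: str = "midpoint"  # or "harmonic" (edge-fraction)
    probe_radius: float = 0.0            # nm, dielectric-boundary inflation
    ion_exclusion: float = 0.0           # nm, Stern layer width
    coarse_margin: float = 1.0           # nm added on each side of the solute
    max_iterations: int = 20000

    def __post_init__(self):
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValueError("need eps_out >= eps_in >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")

    @property
    def kt(self) -> float:
        return kt_kj(self.temperature)

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_out, self.temperature)


@dataclass
class PotentialGrid:
    """Solved potential (kT/e) on a grid, with the final SOR residual."""

    spec: GridSpec
    values: np.ndarray
    residual: float
    iterations: int = 0

    def at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at arbitrary points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - self.spec.origin) / self.spec.spacing
        n = self.spec.nodes_per_side
        if np.any(rel < -1e-9) or np.any(rel > n - 1 + 1e-9):
            raise ValueError("point outside grid")
        rel = np.clip(rel, 0.0, n - 1 - 1e-12)
        i0 = np.floor(rel).astype(int)
        f = rel - i0
        v = self.values
        out = np.zeros(len(pts))
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    out += wx * wy * wz * v[i0[:, 0] + dx, i0[:, 1] + dy,
                                            i0[:, 2] + dz]
        return out


@dataclass
class PBMaps:
    """Discretized problem: edge dielectrics, ion accessibility, node charges."""

    eps_x: np.ndarray          # (n-1, n, n)
    eps_y: np.ndarray          # (n, n-1, n)
    eps_z: np.ndarray          # (n, n, n-1)
    ion_accessible: np.ndarray  # (n, n, n) bool
    charge: np.ndarray          # (n, n, n), e
    skipped_atoms: list = field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(self.charge.sum())


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

def _mark_inside(mask: np.ndarray, coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                 center: np.ndarray, radius: float) -> None:
    """Set mask True where the (x, y, z) outer-product points fall in a sphere."""
    cx, cy, cz = coords
    ix = np.nonzero(np.abs(cx - center[0]) <= radius)[0]
    iy = np.nonzero(np.abs(cy - center[1]) <= radius)[0]
    iz = np.nonzero(np.abs(cz - center[2]) <= radius)[0]
    if not (len(ix) and len(iy) and len(iz)):
        return
    dx2 = (cx[ix] - center[0]) ** 2
    dy2 = (cy[iy] - center[1]) ** 2
    dz2 = (cz[iz] - center[2]) ** 2
    sub = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
           <= radius * radius)
    view = mask[np.ix_(ix, iy, iz)]
    mask[np.ix_(ix, iy, iz)] = view | sub


def _edge_fraction(frac: np.ndarray, starts: np.ndarray, h: float,
                   perp_a: np.ndarray, perp_b: np.ndarray,
                   center_along: float, center_a: float, center_b: float,
                   radius: float, axis: int) -> None:
    """Accumulate (as a max) the fraction of each grid edge inside a sphere.

    ``starts`` are the lower endpoints along the edge axis; ``perp_a/b`` the
    coordinates in the two perpendicular directions.
    """
    da2 = (perp_a - center_a) ** 2
    db2 = (perp_b - center_b) ** 2
    rho2 = radius * radius - (da2[:, None] + db2[None, :])
    ia, ib = np.nonzero(rho2 > 0)
    if len(ia) == 0:
        return
    rho = np.sqrt(rho2[ia, ib])
    lo = center_along - rho
    hi = center_along + rho
    overlap = (np.minimum(starts[:, None] + h, hi[None, :])
               - np.maximum(starts[:, None], lo[None, :]))
    f = np.clip(overlap / h, 0.0, 1.0)
    ni = len(starts)
    gi = np.repeat(np.arange(ni), len(ia))
    ga = np.tile(ia, ni)
    gb = np.tile(ib, ni)
    vals = f.ravel()
    if axis == 0:
        np.maximum.at(frac, (gi, ga, gb), vals)
    elif axis == 1:
        np.maximum.at(frac, (ga, gi, gb), vals)
    else:
        np.maximum.at(frac, (ga, gb, gi), vals)


def build_maps(structure: Structure, spec: GridSpec, config: PBConfig,
               charges: np.ndarray | None = None,
               allow_outside: bool = False) -> PBMaps:
    """Discretize dielectric, ion accessibility, and charges onto the grid.

    ``charges`` overrides the structure's atomic charges (same length); this
    is how the charging calculations place only a single site's charges while
    the full structure still defines the dielectric boundary.

    Edge dielectrics are midpoint-sampled by default; the "harmonic"
    smoothing option instead harmonically averages eps over the exact
    fraction of each edge inside the solute, which removes the staircase
    dependence of solvation energies on the grid alignment.

    A charged atom outside the grid raises an error unless ``allow_outside``
    (the fine focusing step, where outside charges enter via the boundary
    values interpolated from the coarse solution).
    """
    n = spec.nodes_per_side
    h = spec.spacing
    ax = spec.origin[0] + spec.axis()
    ay = spec.origin[1] + spec.axis()
    az = spec.origin[2] + spec.axis()
    mid = 0.5 * h

    ion_blocked = np.zeros((n, n, n), dtype=bool)

    positions = structure.positions if len(structure) else np.zeros((0, 3))
    radii = structure.radii if len(structure) else np.zeros(0)
    q = structure.charges if charges is None else np.asarray(charges, float)
    if len(q) != len(structure):
        raise ValueError("charge override length mismatch")

    harmonic = config.dielectric_smoothing == "harmonic"
    if harmonic:
        frac_x = np.zeros((n - 1, n, n))
        frac_y = np.zeros((n, n - 1, n))
        frac_z = np.zeros((n, n, n - 1))
    else:
        inside_x = np.zeros((n - 1, n, n), dtype=bool)
        inside_y = np.zeros((n, n - 1, n), dtype=bool)
        inside_z = np.zeros((n, n, n - 1), dtype=bool)

    for pos, rad in zip(positions, radii):
        if rad <= 0:
            continue
        r = rad + config.probe_radius
        if harmonic:
            _edge_fraction(frac_x, ax[:-1], h, ay, az, pos[0], pos[1],
                           pos[2], r, axis=0)
            _edge_fraction(frac_y, ay[:-1], h, ax, az, pos[1], pos[0],
                           pos[2], r, axis=1)
            _edge_fraction(frac_z, az[:-1], h, ax, ay, pos[2], pos[0],
                           pos[1], r, axis=2)
        else:
            _mark_inside(inside_x, (ax[:-1] + mid, ay, az), pos, r)
            _mark_inside(inside_y, (ax, ay[:-1] + mid, az), pos, r)
            _mark_inside(inside_z, (ax, ay, az[:-1] + mid), pos, r)
        _mark_inside(ion_blocked, (ax, ay, az), pos, r + config.ion_exclusion)

    if harmonic:
        def mix(f):
            return 1.0 / (f / config.eps_in + (1.0 - f) / config.eps_out)
        eps_x, eps_y, eps_z = mix(frac_x), mix(frac_y), mix(frac_z)
    else:
        eps_x = np.where(inside_x, config.eps_in, config.eps_out)
        eps_y = np.where(inside_y, config.eps_in, config.eps_out)
        eps_z = np.where(inside_z, config.eps_in, config.eps_out)

    charge = np.zeros((n, n, n))
    skipped = []
    rel_all = (positions - spec.origin) / h
    for a, (rel, qa) in enumerate(zip(rel_all, q)):
        if qa == 0.0:
            continue
        if np.any(rel < 0) or np.any(rel > n - 1):
            if allow_outside:
                skipped.append(a)
                continue
            raise ValueError(f"charged atom {a} outside grid")
        i0 = np.minimum(np.floor(rel).astype(int), n - 2)
        f = rel - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((f[0] if dx else 1 - f[0])
                         * (f[1] if dy else 1 - f[1])
                         * (f[2] if dz else 1 - f[2]))
                    charge[i0[0] + dx, i0[1] + dy, i0[2] + dz] += w * qa

    return PBMaps(eps_x, eps_y, eps_z, ~ion_blocked, charge, skipped)


def debye_boundary(spec: GridSpec, positions: np.ndarray, charges: np.ndarray,
                   config: PBConfig) -> np.ndarray:
    """Grid array with faces set to the screened-Coulomb potential (kT/e)."""
    n = spec.nodes_per_side
    phi = np.zeros((n, n, n))
    if config.boundary == "zero" or len(positions) == 0:
        return phi
    sel = charges != 0.0
    pos = np.atleast_2d(positions)[sel]
    q = np.asarray(charges)[sel]
    if len(q) == 0:
        return phi
    ax = spec.origin[0] + spec.axis()
    ay = spec.origin[1] + spec.axis()
    az = spec.origin[2] + spec.axis()
    pref = COULOMB_KJ_NM / (config.eps_out * config.kt)
    kappa = config.kappa

    def face(points):
        d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        return pref * np.sum(q[None, :] * np.exp(-kappa * d) / d, axis=1)

    grids = np.meshgrid(ax, ay, az, indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).reshape(n, n, n, 3)
    for axis in range(3):
        for idx in (0, n - 1):
            sl = [slice(None)] * 3
            sl[axis] = idx
            pts = coords[tuple(sl)].reshape(-1, 3)
            phi[tuple(sl)] = face(pts).reshape(n, n)
    return phi


# --------------------------------------------------------------------------
# SOR relaxation
# --------------------------------------------------------------------------

def solve_lpbe(maps: PBMaps, spec: GridSpec, config: PBConfig,
               boundary_values: np.ndarray | None = None) -> PotentialGrid:
    """Relax the 7-point LPBE stencil by checkerboard SOR.

    Iterates until the largest node update falls below
    ``config.convergence_tol`` (kT/e) and raises
    :class:`PBConvergenceError` after ``config.max_iterations`` sweeps.
    """
    n = spec.nodes_per_side
    h = spec.spacing

    phi = (np.zeros((n, n, n)) if boundary_values is None
           else np.array(boundary_values, dtype=float, copy=True))

    src = 4.0 * math.pi * COULOMB_KJ_NM * maps.charge / (config.kt * h)
    salt = (maps.ion_accessible.astype(float)
            * config.eps_out * config.kappa ** 2 * h * h)

    ex, ey, ez = maps.eps_x, maps.eps_y, maps.eps_z
    den = (ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
           + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
           + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]
           + salt[1:-1, 1:-1, 1:-1])
    src_int = src[1:-1, 1:-1, 1:-1]

    ii, jj, kk = np.meshgrid(np.arange(n - 2), np.arange(n - 2),
                             np.arange(n - 2), indexing="ij")
    parity = (ii + jj + kk) % 2 == 0
    colors = (parity, ~parity)

    omega = 2.0 / (1.0 + math.sin(math.pi / (n - 1)))
    interior = phi[1:-1, 1:-1, 1:-1]

    # Stopping: the max node update must fall below the threshold, and so
    # must the *projected remaining error* residual * rho / (1 - rho) with
    # rho the observed per-sweep contraction -- the raw update criterion
    # alone can stop an over-relaxed sweep an order of magnitude early.
    residual = math.inf
    prev = math.inf
    rho = omega - 1.0
    for it in range(1, config.max_iterations + 1):
        residual = 0.0
        for mask in colors:
            num = (ex[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
                   + ex[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
                   + ey[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
                   + ey[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
                   + ez[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
                   + ez[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
                   + src_int)
            delta = omega * (num / den - interior)
            interior[mask] += delta[mask]
            dmax = float(np.max(np.abs(delta[mask]))) if mask.any() else 0.0
            residual = max(residual, dmax)
        if math.isfinite(prev) and prev > 0:
            ratio = min(residual / prev, 0.9999)
            rho = 0.5 * (rho + max(ratio, 0.0))
        prev = residual
        err_est = residual * rho / max(1.0 - rho, 1e-6)
        if residual < config.convergence_tol and err_est < config.convergence_tol:
            if not np.all(np.isfinite(phi)):
                raise PBConvergenceError(math.nan, it)
            return PotentialGrid(spec, phi, residual, it)
    raise PBConvergenceError(residual, config.max_iterations)


# --------------------------------------------------------------------------
# two-step focusing
# --------------------------------------------------------------------------

@dataclass
class FocusResult:
    """Coarse and fine potentials from the two-step focusing procedure."""

    coarse: PotentialGrid
    fine: PotentialGrid

    def potential_at(self, points: np.ndarray) -> np.ndarray:
        """Potential (kT/e), from the fine grid where available, else coarse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(pts))
        margin = self.fine.spec.spacing
        in_fine = self.fine.spec.contains(pts, margin=margin)
        if in_fine.any():
            out[in_fine] = self.fine.at(pts[in_fine])
        if (~in_fine).any():
            out[~in_fine] = self.coarse.at(pts[~in_fine])
        return out


def coarse_grid_spec(structure: Structure, config: PBConfig) -> GridSpec:
    """Coarse grid over the whole solute: fixed nodes, spacing inflated with a
    warning when the default box would not cover the solute plus margin."""
    n = config.nodes_per_side
    if len(structure):
        pos = structure.positions
        center = pos.mean(axis=0)
        extent = np.abs(pos - center).max() + structure.radii.max(initial=0.0)
    else:
        center = np.zeros(3)
        extent = 0.0
    needed = extent + config.coarse_margin
    spacing = config.coarse_spacing
    if needed > 0.5 * (n - 1) * spacing:
        spacing = 2.0 * needed / (n - 1)
        warnings.warn(f"coarse grid spacing inflated to {spacing:.3f} nm to "
                      f"cover the solute", stacklevel=2)
    return GridSpec(n, spacing, center)


def focus_solve(structure: Structure, center: np.ndarray, config: PBConfig,
                charges: np.ndarray | None = None,
                coarse_spec: GridSpec | None = None) -> FocusResult:
    """Two-step focused solve around ``center`` (a titratable group).

    Both grids have ``config.nodes_per_side`` nodes.  The coarse grid covers
    the solute and uses analytic (Debye-screened Coulombic) boundary values;
    the fine grid is centered on the group with boundary values interpolated
    trilinearly from the coarse solution.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if coarse_spec is None:
        coarse_spec = coarse_grid_spec(structure, config)
    if not coarse_spec.contains(center[None, :]).all():
        raise ValueError("focus center outside coarse grid")

    q = structure.charges if charges is None else np.asarray(charges, float)

    cmaps = build_maps(structure, coarse_spec, config, charges=q)
    cbound = debye_boundary(coarse_spec, structure.positions, q, config)
    coarse = solve_lpbe(cmaps, coarse_spec, config, cbound)

    fine_spec = GridSpec(config.nodes_per_side, config.fine_spacing, center)
    lo = fine_spec.origin
    hi = fine_spec.origin + (fine_spec.nodes_per_side - 1) * fine_spec.spacing
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    if not coarse_spec.contains(corners).all():
        raise ValueError("fine grid extends beyond coarse grid")

    nf = fine_spec.nodes_per_side
    axf = fine_spec.axis()
    gx, gy, gz = np.meshgrid(axf + lo[0], axf + lo[1], axf + lo[2],
                             indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    init = coarse.at(pts).reshape(nf, nf, nf)

    fmaps = build_maps(structure, fine_spec, config, charges=q,
                       allow_outside=True)
    fine = solve_lpbe(fmaps, fine_spec, config, init)
    return FocusResult(coarse, fine)


# --------------------------------------------------------------------------
# charging energies, intrinsic pKa, and the W matrix
# --------------------------------------------------------------------------

def _context_structure(structure: Structure, site: TitratableSite,
                       context: str,
                       model_extra_atoms: tuple[str, ...] = ()):
    """Return (context structure, index of each full-structure atom in it)."""
    if context == "protein":
        return structure, {i: i for i in range(len(structure))}
    if context != "model_compound":
        raise ValueError(f"unknown context {context!r}")
    wanted = set(site.model_compound_atoms) | set(model_extra_atoms)
    keep = sorted(i for name, i in site.atom_index.items() if name in wanted)
    # extra (cap) atoms are looked up in the site's residue
    res_atoms = {structure.atoms[i].name: i
                 for i in range(len(structure))
                 if structure.atoms[i].residue_index
                 == structure.atoms[next(iter(site.atom_index.values()))].residue_index}
    for name in model_extra_atoms:
        if name in res_atoms and res_atoms[name] not in keep:
            keep.append(res_atoms[name])
    keep = sorted(set(keep))
    sub = structure.subset(keep)
    return sub, {full: j for j, full in enumerate(keep)}


def _charging_solve(structure: Structure, site: TitratableSite,
                    state: SiteState, context: str, config: PBConfig,
                    model_extra_atoms: tuple[str, ...] = ()):
    """Solve with only the site state's charges placed in the given context.

    Returns (self_energy kT, background_energy kT, potential at every
    full-structure atom position, in kT/e).
    """
    if state not in site.states:
        raise ValueError(f"state {state.label!r} not in site {site.site_id}")
    ctx, idx_map = _context_structure(structure, site, context,
                                      model_extra_atoms)
    q = np.zeros(len(ctx))
    member_ctx = set()
    for name in site.member_atoms:
        member_ctx.add(idx_map[site.atom_index[name]])
    for name, qa in state.atom_charges.items():
        q[idx_map[site.atom_index[name]]] = qa

    center = np.mean([structure.atoms[site.atom_index[n]].position
                      for n in site.model_compound_atoms], axis=0)
    focus = focus_solve(ctx, center, config, charges=q)

    phi_ctx = focus.potential_at(ctx.positions)
    self_e = 0.5 * float(np.dot(q, phi_ctx))
    bg_mask = np.array([j not in member_ctx for j in range(len(ctx))])
    back_e = float(np.dot(ctx.charges[bg_mask], phi_ctx[bg_mask])) \
        if bg_mask.any() else 0.0

    phi_full = focus.potential_at(structure.positions) \
        if context == "protein" else None
    return self_e, back_e, phi_full


def charging_terms(structure: Structure, site: TitratableSite,
                   state: SiteState, context: str, config: PBConfig,
                   model_extra_atoms: tuple[str, ...] = ()):
    """(self_energy, background_energy) in kT for one site state and context.

    Only the state's charges are placed; the context ("protein" or
    "model_compound") decides which atoms shape the dielectric and contribute
    background charges.  The identical fine grid (centered on the model
    compound) is used for both contexts of a site, so grid self-energy
    artifacts cancel in the protein-minus-model difference.
    """
    self_e, back_e, _ = _charging_solve(structure, site, state, context,
                                        config, model_extra_atoms)
    return self_e, back_e


@dataclass
class SiteEnergyTable:
    """Intrinsic pKa per site state plus the symmetric coupling matrix (pK)."""

    site_ids: list[int]
    state_labels: dict[int, list[str]]
    protonation: dict[tuple[int, str], int]
    pkmod: dict[tuple[int, str], float]
    pkint: dict[tuple[int, str], float]
    reference: dict[int, str]
    w: dict[tuple[tuple[int, str], tuple[int, str]], float]
    temperature: float = 310.0

    def get_w(self, site_i: int, state_a: str, site_j: int, state_b: str) -> float:
        if site_i == site_j:
            return 0.0
        key = ((site_i, state_a), (site_j, state_b))
        if key[0] > key[1]:
            key = (key[1], key[0])
        return self.w.get(key, 0.0)

    def set_w(self, site_i: int, state_a: str, site_j: int, state_b: str,
              value: float) -> None:
        key = ((site_i, state_a), (site_j, state_b))
        if key[0] > key[1]:
            key = (key[1], key[0])
        self.w[key] = value

    def validate(self) -> None:
        for sid in self.site_ids:
            ref = self.reference[sid]
            if abs(self.pkint[(sid, ref)] - self.pkmod[(sid, ref)]) > 1e-9:
                raise ValueError(f"site {sid}: reference pKint != pKmod")
        for ((si, sa), (sj, sb)), val in self.w.items():
            if si == sj and val != 0.0:
                raise ValueError("nonzero W between states of one site")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "temperature": self.temperature,
            "sites": [
                {
                    "site_id": sid,
                    "reference": self.reference[sid],
                    "states": [
                        {"label": lab,
                         "x": self.protonation[(sid, lab)],
                         "pkmod": self.pkmod[(sid, lab)],
                         "pkint": self.pkint[(sid, lab)]}
                        for lab in self.state_labels[sid]
                    ],
                }
                for sid in self.site_ids
            ],
            "interactions": [
                {"site_i": si, "state_a": sa, "site_j": sj, "state_b": sb,
                 "w": val}
                for ((si, sa), (sj, sb)), val in sorted(self.w.items())
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "SiteEnergyTable":
        site_ids, labels, x, pkmod, pkint, ref = [], {}, {}, {}, {}, {}
        for s in data["sites"]:
            sid = s["site_id"]
            site_ids.append(sid)
            labels[sid] = [st["label"] for st in s["states"]]
            ref[sid] = s["reference"]
            for st in s["states"]:
                key = (sid, st["label"])
                x[key] = st["x"]
                pkmod[key] = st["pkmod"]
                pkint[key] = st["pkint"]
        w = {}
        table = cls(site_ids, labels, x, pkmod, pkint, ref, w,
                    data.get("temperature", 310.0))
        for row in data.get("interactions", []):
            table.set_w(row["site_i"], row["state_a"], row["site_j"],
                        row["state_b"], row["w"])
        return table

    def to_tsv(self, pkint_path, interactions_path) -> None:
        import pandas as pd
        rows = [{"site": sid, "state": lab,
                 "x": self.protonation[(sid, lab)],
                 "pkmod": self.pkmod[(sid, lab)],
                 "pkint": self.pkint[(sid, lab)],
                 "reference": int(lab == self.reference[sid])}
                for sid in self.site_ids for lab in self.state_labels[sid]]
        pd.DataFrame(rows).to_csv(pkint_path, sep="\t", index=False)
        wrows = [{"site_i": si, "state_a": sa, "site_j": sj, "state_b": sb,
                  "w_pk": val}
                 for ((si, sa), (sj, sb)), val in sorted(self.w.items())]
        pd.DataFrame(wrows, columns=["site_i", "state_a", "site_j",
                                     "state_b", "w_pk"]) \
            .to_csv(interactions_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, pkint_path, interactions_path,
                 temperature: float = 310.0) -> "SiteEnergyTable":
        import pandas as pd
        pk = pd.read_csv(pkint_path, sep="\t")
        site_ids, labels, x, pkmod, pkint, ref = [], {}, {}, {}, {}, {}
        for _, row in pk.iterrows():
            sid = int(row["site"])
            lab = str(row["state"])
            if sid not in labels:
                site_ids.append(sid)
                labels[sid] = []
            labels[sid].append(lab)
            x[(sid, lab)] = int(row["x"])
            pkmod[(sid, lab)] = float(row["pkmod"])
            pkint[(sid, lab)] = float(row["pkint"])
            if int(row.get("reference", 0)):
                ref[sid] = lab
        table = cls(site_ids, labels, x, pkmod, pkint, ref, {}, temperature)
        wdf = pd.read_csv(interactions_path, sep="\t")
        for _, row in wdf.iterrows():
            table.set_w(int(row["site_i"]), str(row["state_a"]),
                        int(row["site_j"]), str(row["state_b"]),
                        float(row["w_pk"]))
        return table


def compute_energy_table(structure: Structure, sites: list[TitratableSite],
                         config: PBConfig,
                         model_extra_atoms: tuple[str, ...] = ()) -> SiteEnergyTable:
    """Full PB pass: intrinsic pKa of every site state and the W matrix.

    All sites are first set to their reference-state charges (the background
    against which pKint is defined).  For every site state, the LPBE is solved
    twice with only that state's charges placed -- once in the protein, once
    in the isolated model compound, on the identical fine grid -- and

        pKint = pKmod - [dG_protein(s->ref) - dG_model(s->ref)] / ln 10

    (energies in kT).  W between states of two sites uses the potentials and
    charges *relative to the reference states*, so any pair involving a
    reference state couples with W = 0 and there is no double counting with
    the background term of pKint; the matrix is symmetrized by averaging.
    """
    from constph.sites import apply_state

    work = structure.copy()
    resolved = []
    for site in sites:
        s = site
        apply_state(work, s, s.reference_state)
        resolved.append(s)

    g_prot: dict[tuple[int, str], float] = {}
    g_model: dict[tuple[int, str], float] = {}
    phi_full: dict[tuple[int, str], np.ndarray] = {}

    for site in resolved:
        for state in site.states:
            key = (site.site_id, state.label)
            se, be, phi = _charging_solve(work, site, state, "protein",
                                          config, model_extra_atoms)
            g_prot[key] = se + be
            phi_full[key] = phi
            se, be, _ = _charging_solve(work, site, state, "model_compound",
                                        config, model_extra_atoms)
            g_model[key] = se + be

    site_ids = [s.site_id for s in resolved]
    labels = {s.site_id: [st.label for st in s.states] for s in resolved}
    x = {(s.site_id, st.label): st.protonation_count
         for s in resolved for st in s.states}
    pkmod = {(s.site_id, st.label): st.pkmod
             for s in resolved for st in s.states}
    ref = {s.site_id: s.reference_state.label for s in resolved}

    pkint = {}
    for s in resolved:
        rkey = (s.site_id, ref[s.site_id])
        for st in s.states:
            key = (s.site_id, st.label)
            ddg = (g_prot[key] - g_prot[rkey]) - (g_model[key] - g_model[rkey])
            pkint[key] = st.pkmod - ddg / LN10

    # delta-potentials and delta-charges vs the reference state
    dphi = {}
    for s in resolved:
        rkey = (s.site_id, ref[s.site_id])
        for st in s.states:
            key = (s.site_id, st.label)
            dphi[key] = phi_full[key] - phi_full[rkey]

    dq = {}
    for s in resolved:
        ref_q = s.reference_state.atom_charges
        for st in s.states:
            idx, dqv = [], []
            for name in s.member_atoms:
                d = st.atom_charges.get(name, 0.0) - ref_q.get(name, 0.0)
                if d != 0.0:
                    idx.append(s.atom_index[name])
                    dqv.append(d)
            dq[(s.site_id, st.label)] = (np.array(idx, dtype=int),
                                         np.array(dqv))

    table = SiteEnergyTable(site_ids, labels, x, pkmod, pkint, ref, {},
                            config.temperature)
    for a, sa in enumerate(resolved):
        for sb in resolved[a + 1:]:
            for st_a in sa.states:
                ka = (sa.site_id, st_a.label)
                for st_b in sb.states:
                    kb = (sb.site_id, st_b.label)
                    ib, qb = dq[kb]
                    w_ab = float(np.dot(dphi[ka][ib], qb)) / LN10
                    ia, qa = dq[ka]
                    w_ba = float(np.dot(dphi[kb][ia], qa)) / LN10
                    table.set_w(*ka, *kb, 0.5 * (w_ab + w_ba))
    return table
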
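"""Desk-scale photon transport through voxel phantoms.

Two engines share the same geometry and material data:

* a deterministic primary-beam engine (:func:`primary_transmission`,
  :func:`project_radiograph`, :func:`deposit_kerma`) that casts one
  parallel ray per voxel column or mesh cell and applies Beer-Lambert
  attenuation with collision-kerma energy deposition, and
* an analog Monte Carlo engine (:func:`mc_transport`) with exact
  heterogeneous free-path sampling for the axis-aligned primaries and
  Woodcock delta-tracking for Compton-scattered photons.

Both work in the kerma approximation: energy transferred to electrons is
deposited at the interaction site (no electron transport), which is
adequate at diagnostic photon energies and drifts for small organs above
roughly 1 MeV.  Voxels labelled with the outside ID are treated as
vacuum; over desk-scale path lengths the attenuation of air is below
0.5% and ignoring it keeps the closed-form fixtures exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import (
    MEC2_MEV,
    CoefficientTable,
    mixture_components,
    mixture_mu,
    mixture_muen,
)
from .phantom import VoxelPhantom

EV_PER_MEV = 1.0e6


# ----------------------------------------------------------------------
# Source / tally types

@dataclass(frozen=True)
class PlanarSource:
    """Monodirectional planar photon source travelling along +x.

    The plane sits at ``x0`` and spans ``y_extent`` x ``z_extent`` (cm).
    ``energy_mev`` is the single emission line of a run.
    """

    x0: float
    y_extent: tuple[float, float]
    z_extent: tuple[float, float]
    energy_mev: float
    particles_per_batch: int = 80_000_000
    batches: int = 10

    def __post_init__(self):
        if self.y_extent[1] <= self.y_extent[0] or self.z_extent[1] <= self.z_extent[0]:
            raise ValueError("source extents must be ordered (min, max)")
        if self.energy_mev <= 0:
            raise ValueError("source energy must be positive")

    @property
    def area(self) -> float:
        """Emission area in cm^2."""
        return (self.y_extent[1] - self.y_extent[0]) * (
            self.z_extent[1] - self.z_extent[0]
        )


def ap_source(phantom: VoxelPhantom, energy_mev: float,
              margin: float = 1.0, x0: float | None = None) -> PlanarSource:
    """AP (anterior-posterior) broad beam fully covering the phantom."""
    ll, ur = phantom.lower_left, phantom.upper_right
    return PlanarSource(
        x0=float(ll[0] - 1.0) if x0 is None else x0,
        y_extent=(float(ll[1] - margin), float(ur[1] + margin)),
        z_extent=(float(ll[2] - margin), float(ur[2] + margin)),
        energy_mev=energy_mev,
    )


@dataclass(frozen=True)
class MeshTallySpec:
    """Regular flux mesh: grid dims (nx, ny, nz) and corner coordinates."""

    dims: tuple[int, int, int]
    lower_left: tuple[float, float, float]
    upper_right: tuple[float, float, float]

    def __post_init__(self):
        if any(n <= 0 for n in self.dims):
            raise ValueError("mesh dims must be positive")
        if any(u <= l for l, u in zip(self.lower_left, self.upper_right)):
            raise ValueError("mesh corners must be ordered lower_left < upper_right")


@dataclass
class HeatingTally:
    """Per-organ deposited energy, eV per source particle."""

    heating_ev: dict[int, float]
    sem_ev: dict[int, float]
    n_particles: int

    def total(self) -> float:
        return float(sum(self.heating_ev.values()))

    def relative_error(self, organ_id: int) -> float:
        h = self.heating_ev.get(organ_id, 0.0)
        return float("inf") if h == 0 else self.sem_ev.get(organ_id, 0.0) / h


@dataclass
class FluenceTally:
    """Fluence on the normalisation plane, cm^-2 per source particle."""

    per_particle: float
    sem: float = 0.0

    def __post_init__(self):
        if self.per_particle <= 0:
            raise ValueError("fluence must be positive for a non-degenerate source")


# ----------------------------------------------------------------------
# Material maps

def _material_arrays(phantom: VoxelPhantom, energy_mev: float,
                     table: CoefficientTable | None):
    """Per-material linear coefficients at one energy.

    Returns ``(index_grid, mu_lin, muen_ratio, id_of_index)`` where
    ``index_grid`` maps each voxel to a compact material index; the last
    index is the outside (vacuum) with zero coefficients.
    """
    table = table or CoefficientTable.default()
    organs = list(phantom.registry)
    lut = np.full(256, len(organs), dtype=np.int32)
    mu = np.zeros(len(organs) + 1)
    ratio = np.zeros(len(organs) + 1)
    for i, o in enumerate(organs):
        lut[o.id] = i
        m = o.density * mixture_mu(o.composition, energy_mev, table)
        me = o.density * mixture_muen(o.composition, energy_mev, table)
        mu[i] = m
        ratio[i] = me / m
    index_grid = lut[phantom.ids]
    ids = np.array([o.id for o in organs] + [phantom.outside_id])
    return index_grid, mu, ratio, ids


# ----------------------------------------------------------------------
# Ray traversal

def siddon_traverse(phantom: VoxelPhantom, origin, direction):
    """Walk a ray through the lattice (Amanatides-Woo stepping).

    Returns a list of ``((iz, iy, ix), chord_cm)`` in visit order; the
    chords sum to the length of the ray-box intersection.  An empty list
    means the ray misses the lattice.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("ray direction must be non-zero")
    d = direction / norm
    lo, hi = phantom.lower_left, phantom.upper_right
    nx, ny, nz = phantom.dims
    dims = np.array([nx, ny, nz])
    pitch = phantom.pitch

    # slab clipping for entry/exit parameters
    t0, t1 = 0.0, np.inf
    for ax in range(3):
        if d[ax] == 0.0:
            if not (lo[ax] <= origin[ax] <= hi[ax]):
                return []
        else:
            ta = (lo[ax] - origin[ax]) / d[ax]
            tb = (hi[ax] - origin[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return []

    eps = 1e-12 * max(1.0, t1)
    p = origin + (t0 + eps) * d
    idx = np.floor((p - lo) / pitch).astype(int)
    idx = np.clip(idx, 0, dims - 1)
    step = np.where(d > 0, 1, -1)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] != 0.0:
            next_bound = lo[ax] + (idx[ax] + (1 if d[ax] > 0 else 0)) * pitch
            t_max[ax] = (next_bound - origin[ax]) / d[ax]
            t_delta[ax] = pitch / abs(d[ax])

    out = []
    t = t0
    while t < t1 - eps:
        ax = int(np.argmin(t_max))
        t_next = min(t_max[ax], t1)
        chord = t_next - t
        if chord > 0:
            out.append(((int(idx[2]), int(idx[1]), int(idx[0])), float(chord)))
        t = t_next
        idx[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        if idx[ax] < 0 or idx[ax] >= dims[ax]:
            break
    return out


def primary_transmission(phantom: VoxelPhantom, origin, direction,
                         energy_mev: float,
                         table: CoefficientTable | None = None) -> float:
    """Uncollided Beer-Lambert transmission of one ray, exp(-sum mu*chord)."""
    index_grid, mu, _, _ = _material_arrays(phantom, energy_mev, table)
    tau = 0.0
    for (iz, iy, ix), chord in siddon_traverse(phantom, origin, direction):
        tau += mu[index_grid[iz, iy, ix]] * chord
    return float(np.exp(-tau))


# ----------------------------------------------------------------------
# Radiography

def _column_transmission(phantom: VoxelPhantom, energy_mev: float,
                         table: CoefficientTable | None) -> np.ndarray:
    """Transmission of +x parallel rays through every (z, y) voxel column."""
    index_grid, mu, _, _ = _material_arrays(phantom, energy_mev, table)
    tau = (mu[index_grid] * phantom.pitch).sum(axis=2)
    return np.exp(-tau)


def project_radiograph(phantom: VoxelPhantom, source: PlanarSource,
                       mesh: MeshTallySpec, energy_mev: float | None = None,
                       table: CoefficientTable | None = None) -> np.ndarray:
    """Primary-fluence image on a y-z mesh behind the phantom.

    One parallel +x ray per mesh cell centre; the returned array has
    shape ``(nz_mesh, ny_mesh)`` and holds the transmitted fraction of a
    unit incident fluence (1.0 in unobstructed cells).
    """
    if mesh.lower_left[0] < source.x0:
        raise ValueError(
            f"mesh at x={mesh.lower_left[0]} lies in front of the source plane "
            f"x={source.x0}"
        )
    energy_mev = source.energy_mev if energy_mev is None else energy_mev
    trans = _column_transmission(phantom, energy_mev, table)  # (nz, ny)
    lo = phantom.lower_left
    nx, ny, nz = phantom.dims

    _, my, mz = mesh.dims
    yc = np.linspace(mesh.lower_left[1], mesh.upper_right[1], my, endpoint=False)
    yc += (mesh.upper_right[1] - mesh.lower_left[1]) / (2 * my)
    zc = np.linspace(mesh.lower_left[2], mesh.upper_right[2], mz, endpoint=False)
    zc += (mesh.upper_right[2] - mesh.lower_left[2]) / (2 * mz)
    iy = np.floor((yc - lo[1]) / phantom.pitch).astype(int)
    iz = np.floor((zc - lo[2]) / phantom.pitch).astype(int)
    in_y = (iy >= 0) & (iy < ny)
    in_z = (iz >= 0) & (iz < nz)
    img = np.ones((mz, my))
    zz, yy = np.meshgrid(np.clip(iz, 0, nz - 1), np.clip(iy, 0, ny - 1),
                         indexing="ij")
    vals = trans[zz, yy]
    mask = np.outer(in_z, in_y)
    img[mask] = vals[mask]
    # outside the source footprint no photons arrive at all
    ys = (yc >= source.y_extent[0]) & (yc <= source.y_extent[1])
    zs = (zc >= source.z_extent[0]) & (zc <= source.z_extent[1])
    img *= np.outer(zs, ys)
    return img


def michelson_contrast(bright: float, dark: float) -> float:
    """Michelson contrast (I1 - I2) / (I1 + I2)."""
    return (bright - dark) / (bright + dark)


def radiograph_to_png(image: np.ndarray, path, log_norm: bool = True) -> None:
    """8-bit grayscale export; logarithmic normalisation by default, as
    is usual for radiographic flux spanning several decades."""
    from PIL import Image

    img = np.asarray(image, dtype=float)
    if log_norm:
        floor = img[img > 0].min() if np.any(img > 0) else 1e-12
        img = np.log(np.maximum(img, floor))
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    # image rows run top-down; z runs bottom-up
    arr = (255 * scaled[::-1]).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def radiograph_to_pgm(image: np.ndarray, path, log_norm: bool = True) -> None:
    img = np.asarray(image, dtype=float)
    if log_norm:
        floor = img[img > 0].min() if np.any(img > 0) else 1e-12
        img = np.log(np.maximum(img, floor))
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    arr = (255 * scaled[::-1]).astype(np.uint8)
    with open(path, "w") as fh:
        fh.write(f"P2\n{arr.shape[1]} {arr.shape[0]}\n255\n")
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


# ----------------------------------------------------------------------
# Deterministic collision kerma

def deposit_kerma(phantom: VoxelPhantom, source: PlanarSource,
                  energy_mev: float | None = None,
                  table: CoefficientTable | None = None,
                  return_balance: bool = False):
    """Collision-kerma deposition of the uncollided beam, one ray per
    voxel column.

    Per voxel the deposited energy is ``E * phi_in * (1 - exp(-mu*d)) *
    muen/mu``; the remaining collided share leaves as scatter and is
    booked separately.  Returns ``(HeatingTally, FluenceTally)`` with
    zero statistical uncertainty, heating in eV per source particle.
    With ``return_balance=True`` a third dict reports the energy
    bookkeeping per unit incident fluence.
    """
    energy_mev = source.energy_mev if energy_mev is None else energy_mev
    index_grid, mu, ratio, ids = _material_arrays(phantom, energy_mev, table)
    pitch = phantom.pitch
    mu_grid = mu[index_grid]                       # (nz, ny, nx)
    tau = np.cumsum(mu_grid * pitch, axis=2)
    phi_in = np.exp(-(tau - mu_grid * pitch))      # fluence entering each voxel
    collided = phi_in * -np.expm1(-mu_grid * pitch)

    # columns actually inside the beam footprint
    yc = phantom.voxel_centers(1)
    zc = phantom.voxel_centers(2)
    in_beam = np.outer(
        (zc >= source.z_extent[0]) & (zc <= source.z_extent[1]),
        (yc >= source.y_extent[0]) & (yc <= source.y_extent[1]),
    ).astype(float)                                # (nz, ny)
    collided *= in_beam[:, :, None]

    e_ev = energy_mev * EV_PER_MEV
    dep = e_ev * collided * ratio[index_grid]      # per unit fluence, per voxel
    per_mat = np.bincount(index_grid.ravel(), weights=dep.ravel(),
                          minlength=len(mu))
    # eV per source particle: a column of cross-section pitch^2 intercepts
    # pitch^2/A of the particles emitted per unit source area
    scale = pitch**2 / source.area
    heating = {int(i): float(per_mat[k] * scale)
               for k, i in enumerate(ids[:-1])}
    tally = HeatingTally(heating, {int(i): 0.0 for i in ids[:-1]},
                         n_particles=0)
    fluence = FluenceTally(per_particle=1.0 / source.area)
    if not return_balance:
        return tally, fluence
    n_cols = float(in_beam.sum())
    transmitted = float((np.exp(-tau[:, :, -1]) * in_beam).sum()) * e_ev
    deposited = float(dep.sum()) * 1.0
    scattered = float((e_ev * collided * (1 - ratio[index_grid])).sum())
    balance = {
        "incident": n_cols * e_ev,
        "deposited": deposited,
        "scattered_escape": scattered,
        "transmitted": transmitted,
    }
    return tally, fluence, balance


# ----------------------------------------------------------------------
# Analog Monte Carlo

class _DenseMaterialTables:
    """Log-log interpolation tables per material on a dense energy grid,
    used by the MC engine for post-scatter energies."""

    def __init__(self, phantom: VoxelPhantom, table: CoefficientTable | None,
                 n: int = 128):
        table = table or CoefficientTable.default()
        organs = list(phantom.registry)
        self.egrid = np.geomspace(table.emin, table.emax, n)
        self.log_e = np.log(self.egrid)
        nm = len(organs) + 1
        self.mu = np.zeros((nm, n))
        self.pe = np.zeros((nm, n))
        self.inc = np.zeros((nm, n))
        self.ratio = np.zeros((nm, n))
        self.lut = np.full(256, nm - 1, dtype=np.int32)
        for i, o in enumerate(organs):
            self.lut[o.id] = i
            mu = o.density * mixture_mu(o.composition, self.egrid, table)
            muen = o.density * mixture_muen(o.composition, self.egrid, table)
            pe, inc, coh = mixture_components(o.composition, self.egrid, table)
            self.mu[i] = mu
            self.pe[i] = o.density * pe
            self.inc[i] = o.density * inc
            self.ratio[i] = muen / mu
        self.mu_max = self.mu.max(axis=0)
        self.emin = float(self.egrid[0])

    def _gather(self, arr, mat_idx, energy):
        k = np.clip(np.searchsorted(self.log_e, np.log(energy)) - 1,
                    0, len(self.egrid) - 2)
        f = (np.log(energy) - self.log_e[k]) / (self.log_e[k + 1] - self.log_e[k])
        a0 = arr[mat_idx, k]
        a1 = arr[mat_idx, k + 1]
        with np.errstate(divide="ignore"):
            out = np.where(
                (a0 > 0) & (a1 > 0),
                np.exp(np.log(np.maximum(a0, 1e-300)) * (1 - f)
                       + np.log(np.maximum(a1, 1e-300)) * f),
                a0 * (1 - f) + a1 * f,
            )
        return out

    def mu_of(self, mat_idx, energy):
        return self._gather(self.mu, mat_idx, energy)

    def pe_of(self, mat_idx, energy):
        return self._gather(self.pe, mat_idx, energy)

    def inc_of(self, mat_idx, energy):
        return self._gather(self.inc, mat_idx, energy)

    def ratio_of(self, mat_idx, energy):
        return self._gather(self.ratio, mat_idx, energy)

    def mu_max_of(self, energy):
        k = np.clip(np.searchsorted(self.log_e, np.log(energy)) - 1,
                    0, len(self.egrid) - 2)
        return np.maximum(self.mu_max[k], self.mu_max[k + 1])


def sample_klein_nishina(energy_mev, rng):
    """Sample scattered photon energies from the Klein-Nishina law by
    Kahn's rejection method.  Returns (E_scattered, cos_theta)."""
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    a = e / MEC2_MEV
    xi = np.empty_like(e)
    todo = np.ones(e.shape, dtype=bool)
    p1 = (2 * a + 1) / (2 * a + 9)
    while todo.any():
        idx = np.flatnonzero(todo)
        r1, r2, r3 = rng.random((3, idx.size))
        aa = a[idx]
        branch_a = r1 < p1[idx]
        x = np.where(branch_a, 1 + 2 * aa * r2, (1 + 2 * aa) / (1 + 2 * aa * r2))
        cos_t = 1 - (x - 1) / aa
        acc_a = r3 <= 4 * (x - 1) / (x * x)
        acc_b = r3 <= 0.5 * (cos_t**2 + 1.0 / x)
        accept = np.where(branch_a, acc_a, acc_b)
        sel = idx[accept]
        xi[sel] = x[accept]
        todo[sel] = False
    cos_t = 1 - (xi - 1) / a
    return e / xi, np.clip(cos_t, -1.0, 1.0)


def _rotate_directions(dirs, cos_t, rng):
    """New unit vectors at polar angle acos(cos_t) about each old
    direction, uniform azimuth."""
    n = dirs.shape[0]
    sin_t = np.sqrt(np.maximum(0.0, 1 - cos_t**2))
    phi = rng.random(n) * 2 * np.pi
    # orthonormal frame around each direction
    helper = np.where(np.abs(dirs[:, 2:3]) < 0.9,
                      np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]]))
    v = np.cross(dirs, helper)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = np.cross(dirs, v)
    new = (cos_t[:, None] * dirs
           + sin_t[:, None] * (np.cos(phi)[:, None] * v + np.sin(phi)[:, None] * w))
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def mc_transport(phantom: VoxelPhantom, source: PlanarSource,
                 energy_mev: float | None = None, n: int = 100_000,
                 seed: int = 0, scatter: bool = True, rayleigh: bool = False,
                 batches: int = 10,
                 table: CoefficientTable | None = None):
    """Analog Monte Carlo photon transport with per-organ heating tally.

    Histories are tracked in the kerma approximation: photoelectric
    events deposit the full photon energy locally; Compton events deposit
    the transferred energy locally and continue the scattered photon
    (Klein-Nishina sampling); coherent events change nothing (a
    small-angle approximation; with ``rayleigh=False``, the default, this
    is statistically identical to excluding the coherent cross section).
    With ``scatter=False`` every real collision scores the expected local
    kerma ``E * muen/mu`` and terminates, the unbiased analog of
    :func:`deposit_kerma`.  Photons falling below the coefficient-table
    cutoff deposit their remaining energy on the spot.

    Returns ``(HeatingTally, FluenceTally)``; uncertainties are standard
    deviations of the mean over ``batches`` batches.
    """
    if n < 1:
        raise ValueError("particle count n must be >= 1")
    if batches < 1 or batches > n:
        batches = max(1, min(batches, n))
    energy_mev = source.energy_mev if energy_mev is None else energy_mev
    dense = _DenseMaterialTables(phantom, table)
    mat_grid = dense.lut[phantom.ids]
    nz, ny, nx = phantom.ids.shape
    n_mat = dense.mu.shape[0]
    lo = phantom.lower_left
    hi = phantom.upper_right
    pitch = phantom.pitch
    # column optical depth tables at the source energy
    mu_at_e0 = np.array([
        np.interp(np.log(energy_mev), dense.log_e, np.log(np.maximum(row, 1e-300)))
        for row in dense.mu
    ])
    mu_at_e0 = np.where(dense.mu[:, 0] > 0, np.exp(mu_at_e0), 0.0)
    mu_grid_e0 = mu_at_e0[mat_grid]
    cum = np.cumsum(mu_grid_e0 * pitch, axis=2)  # (nz, ny, nx)

    seqs = np.random.SeedSequence(seed).spawn(batches)
    per_batch = np.zeros((batches, n_mat))
    counts = [n // batches + (1 if b < n % batches else 0) for b in range(batches)]

    for b, (seq, nb) in enumerate(zip(seqs, counts)):
        rng = np.random.default_rng(seq)
        dep = np.zeros(n_mat)
        if nb == 0:
            continue
        # ---- primaries: exact free-path sampling along +x columns
        y = rng.uniform(*source.y_extent, nb)
        z = rng.uniform(*source.z_extent, nb)
        iy = np.floor((y - lo[1]) / pitch).astype(int)
        iz = np.floor((z - lo[2]) / pitch).astype(int)
        inside = (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        iy, iz = iy[inside], iz[inside]
        yq, zq = y[inside], z[inside]
        s0 = np.zeros(iy.size)  # optical depth already consumed
        scat_pos, scat_dir, scat_e = [], [], []
        for _ in range(200):
            if iy.size == 0:
                break
            rows = cum[iz, iy, :]                     # (m, nx)
            s_target = s0 - np.log(rng.random(iy.size))
            ix = (rows < s_target[:, None]).sum(axis=1)
            alive = ix < nx
            if not alive.any():
                break
            iy, iz, yq, zq = iy[alive], iz[alive], yq[alive], zq[alive]
            s_target, rows, ix = s_target[alive], rows[alive], ix[alive]
            m = mat_grid[iz, iy, ix]
            mu_v = mu_at_e0[m]
            pe = dense.pe_of(m, np.full(m.size, energy_mev))
            inc = dense.inc_of(m, np.full(m.size, energy_mev))
            u = rng.random(m.size) * mu_v
            if not scatter:
                ratio = dense.ratio_of(m, np.full(m.size, energy_mev))
                np.add.at(dep, m, energy_mev * ratio)
                iy = iy[:0]
                break
            is_pe = u < pe
            is_inc = (~is_pe) & (u < pe + inc)
            # photoelectric: full local absorption
            np.add.at(dep, m[is_pe], energy_mev)
            # Compton: deposit transfer, hand photon to the scattered pool
            if is_inc.any():
                mi = m[is_inc]
                e_sc, cos_t = sample_klein_nishina(
                    np.full(mi.size, energy_mev), rng)
                np.add.at(dep, mi, energy_mev - e_sc)
                cumbefore = np.where(ix[is_inc] > 0,
                                     rows[is_inc, np.maximum(ix[is_inc] - 1, 0)],
                                     0.0)
                frac = (s_target[is_inc] - cumbefore) / np.maximum(
                    mu_at_e0[mi], 1e-300)
                xq = lo[0] + ix[is_inc] * pitch + np.clip(frac, 0, pitch)
                d0 = np.tile(np.array([[1.0, 0.0, 0.0]]), (mi.size, 1))
                scat_pos.append(np.column_stack([xq, yq[is_inc], zq[is_inc]]))
                scat_dir.append(_rotate_directions(d0, cos_t, rng))
                scat_e.append(e_sc)
            # coherent: photon continues along +x from the collision point
            keep = ~(is_pe | is_inc)
            iy, iz, yq, zq = iy[keep], iz[keep], yq[keep], zq[keep]
            s0 = s_target[keep]

        # ---- scattered pool: Woodcock delta-tracking
        if scat_e:
            pos = np.concatenate(scat_pos)
            dirs = np.concatenate(scat_dir)
            en = np.concatenate(scat_e)
            # below-cutoff photons deposit locally
            low = en < dense.emin
            if low.any():
                vox = np.floor((pos[low] - lo) / pitch).astype(int)
                ok = np.all((vox >= 0) & (vox < [nx, ny, nz]), axis=1)
                mm = mat_grid[vox[ok, 2], vox[ok, 1], vox[ok, 0]]
                np.add.at(dep, mm, en[low][ok])
                pos, dirs, en = pos[~low], dirs[~low], en[~low]
            for _ in range(100_000):
                if en.size == 0:
                    break
                mu_maj = dense.mu_max_of(en)
                step = -np.log(rng.random(en.size)) / np.maximum(mu_maj, 1e-300)
                pos = pos + dirs * step[:, None]
                vox = np.floor((pos - lo) / pitch).astype(int)
                inside = np.all((vox >= 0) & (vox < [nx, ny, nz]), axis=1)
                pos, dirs, en, vox = pos[inside], dirs[inside], en[inside], vox[inside]
                mu_maj = mu_maj[inside]
                if en.size == 0:
                    break
                m = mat_grid[vox[:, 2], vox[:, 1], vox[:, 0]]
                mu_real = dense.mu_of(m, en)
                hit = rng.random(en.size) * mu_maj < mu_real
                if hit.any():
                    mh = m[hit]
                    eh = en[hit]
                    pe = dense.pe_of(mh, eh)
                    inc = dense.inc_of(mh, eh)
                    u = rng.random(mh.size) * np.maximum(mu_real[hit], 1e-300)
                    is_pe = u < pe
                    is_inc = (~is_pe) & (u < pe + inc)
                    np.add.at(dep, mh[is_pe], eh[is_pe])
                    kill = hit.copy()
                    kill[np.flatnonzero(hit)[~(is_pe | is_inc)]] = False  # coherent
                    if is_inc.any():
                        sel = np.flatnonzero(hit)[is_inc]
                        e_sc, cos_t = sample_klein_nishina(en[sel], rng)
                        np.add.at(dep, m[sel], en[sel] - e_sc)
                        dirs[sel] = _rotate_directions(dirs[sel], cos_t, rng)
                        en[sel] = e_sc
                        cutoff = np.zeros(en.size, dtype=bool)
                        cutoff[sel] = e_sc < dense.emin
                        if cutoff.any():
                            np.add.at(dep, m[cutoff & hit], en[cutoff & hit])
                            kill[cutoff] = True
                        kill[sel[e_sc >= dense.emin]] = False
                    keep = ~kill
                    pos, dirs, en = pos[keep], dirs[keep], en[keep]
        per_batch[b] = dep * EV_PER_MEV / nb

    mean = per_batch.mean(axis=0)
    sem = (per_batch.std(axis=0, ddof=1) / np.sqrt(batches)
           if batches > 1 else np.zeros(n_mat))
    ids = [o.id for o in phantom.registry]
    tally = HeatingTally(
        {oid: float(mean[k]) for k, oid in enumerate(ids)},
        {oid: float(sem[k]) for k, oid in enumerate(ids)},
        n_particles=n,
    )
    fluence = FluenceTally(per_particle=1.0 / source.area)
    return tally, fluence
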
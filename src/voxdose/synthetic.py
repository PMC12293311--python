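"""Deterministic stylized voxel phantoms for testing the full pipeline.

A real segmented whole-body phantom is not redistributable, so this
module builds a stand-in body from geometric primitives (ellipsoids,
cylinders, shells, boxes) painted onto the voxel lattice in priority
order.  The default recipe places all 30 organs/tissues of the bundled
synthetic registry - 14 ICRP-103 weighted organs (colon as two IDs), the
13 male remainder tissues, the eye lenses and the cortical skeleton -
inside a trunk+head body whose outermost voxel layer becomes the skin
shell.  Anatomical realism is explicitly not the goal; exercising every
downstream code path (including remainder handling in the effective
dose) is.

Axes: x is the anterior-posterior depth (the AP beam travels along +x,
entering the front of the body at negative x), y is lateral, z is the
body axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .phantom import OUTSIDE_ID, OrganRegistry, OrganSpec, VoxelPhantom

_DATA_PACKAGE = "voxdose.data"
_REGISTRY_RESOURCE = "organ_registry_synthetic.csv"

SHAPES = ("ellipsoid", "cylinder", "shell", "box")


def default_registry() -> OrganRegistry:
    """The bundled synthetic 30-organ registry (stand-in data, not a
    survey-derived phantom's)."""
    with resources.files(_DATA_PACKAGE).joinpath(_REGISTRY_RESOURCE).open() as fh:
        return OrganRegistry.from_csv(fh)


@dataclass(frozen=True)
class Primitive:
    """One geometric organ primitive.

    ``size`` is interpreted per shape: ellipsoid/shell semi-axes (cm),
    cylinder (radius, radius, half-height), box half-sizes.  ``shell``
    keeps only the region between the outer ellipsoid and the same
    ellipsoid shrunk by ``thickness``.  ``axis`` orients cylinders.
    """

    organ_id: int
    shape: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    priority: int
    axis: str = "z"
    thickness: float = 0.0
    jitter: bool = True

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "shell" and self.thickness <= 0:
            raise ValueError("shell primitive needs a positive thickness")


@dataclass(frozen=True)
class PhantomRecipe:
    """Recipe for :func:`generate_phantom`.

    ``jitter_cm`` is the standard deviation of the seeded Gaussian jitter
    applied to the centres of primitives with ``jitter=True``; geometry
    is otherwise deterministic.  ``skin_id`` (when set) converts the
    outermost voxel layer of the painted body into a closed skin shell.
    """

    dims: tuple[int, int, int]
    pitch: float
    seed: int = 0
    primitives: tuple[Primitive, ...] = ()
    jitter_cm: float = 0.15
    skin_id: int | None = None


def _mask(prim: Primitive, X, Y, Z, center) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = prim.size
    dx, dy, dz = X - cx, Y - cy, Z - cz
    if prim.shape == "ellipsoid":
        return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    if prim.shape == "shell":
        outer = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
        t = prim.thickness
        ai, bi, ci = max(a - t, 1e-6), max(b - t, 1e-6), max(c - t, 1e-6)
        inner = (dx / ai) ** 2 + (dy / bi) ** 2 + (dz / ci) ** 2 <= 1.0
        return outer & ~inner
    if prim.shape == "box":
        return (np.abs(dx) <= a) & (np.abs(dy) <= b) & (np.abs(dz) <= c)
    # cylinder
    if prim.axis == "z":
        return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0, np.abs(dz) <= c
    if prim.axis == "y":
        return (dx / a) ** 2 + (dz / b) ** 2 <= 1.0, np.abs(dy) <= c
    return (dy / a) ** 2 + (dz / b) ** 2 <= 1.0, np.abs(dx) <= c


def generate_phantom(recipe: PhantomRecipe,
                     registry: OrganRegistry | None = None) -> VoxelPhantom:
    """Paint a recipe onto the lattice; deterministic for a fixed seed.

    Later-priority primitives overwrite earlier ones.  Organs that end up
    with zero voxels at the requested resolution trigger a warning
    listing their IDs.
    """
    registry = registry or default_registry()
    nx, ny, nz = recipe.dims
    pitch = recipe.pitch
    x = (np.arange(nx) - nx / 2 + 0.5) * pitch
    y = (np.arange(ny) - ny / 2 + 0.5) * pitch
    z = (np.arange(nz) - nz / 2 + 0.5) * pitch
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")

    rng = np.random.default_rng(recipe.seed)
    grid = np.full((nz, ny, nx), OUTSIDE_ID, dtype=np.int16)
    requested: set[int] = set()
    for prim in sorted(recipe.primitives, key=lambda p: p.priority):
        if prim.organ_id not in registry:
            raise KeyError(f"primitive organ ID {prim.organ_id} not in registry")
        requested.add(prim.organ_id)
        # jitter draw happens for every jitterable primitive, in a fixed
        # order, so geometry is reproducible regardless of voxel grid
        offset = (
            rng.normal(0.0, recipe.jitter_cm, size=3)
            if prim.jitter and recipe.jitter_cm > 0
            else np.zeros(3)
        )
        center = tuple(np.asarray(prim.center) + offset)
        m = _mask(prim, X, Y, Z, center)
        if isinstance(m, tuple):  # cylinder returns (radial, axial)
            m = m[0] & m[1]
        grid[m] = prim.organ_id

    if recipe.skin_id is not None:
        requested.add(recipe.skin_id)
        body = grid != OUTSIDE_ID
        interior = ndimage.binary_erosion(body)
        grid[body & ~interior] = recipe.skin_id

    present = set(np.unique(grid).tolist()) - {OUTSIDE_ID}
    missing = sorted(requested - present)
    if missing:
        warnings.warn(
            f"organs with zero voxels at this resolution: IDs {missing}",
            stacklevel=2,
        )
    return VoxelPhantom(grid, pitch, registry)


# ----------------------------------------------------------------------
# Default 30-organ body

def default_body_recipe(dims=(64, 64, 160), pitch=0.4, seed=0) -> PhantomRecipe:
    """Stylized adult trunk+head body with all 30 registry organs.

    At the default resolution the lattice spans 25.6 x 25.6 x 64 cm; the
    trunk is an elliptical cylinder ~18 cm deep (AP) by ~22 cm wide, so
    beam attenuation is of the order of a real abdomen.  The outermost
    voxel layer becomes the skin (ID 1).
    """
    E, C, SH = "ellipsoid", "cylinder", "shell"
    p: list[Primitive] = []
    pr = 0

    def add(organ_id, shape, center, size, axis="z", thickness=0.0, jitter=True):
        nonlocal pr
        pr += 1
        p.append(Primitive(organ_id, shape, center, size, pr, axis, thickness, jitter))

    # body envelope (muscle, ID 24); never jittered
    add(24, C, (0, 0, -8), (9, 11, 22), jitter=False)          # trunk
    add(24, E, (0, 0, 22), (7, 7.5, 9), jitter=False)          # head
    add(24, C, (0, 0, 13.5), (4, 4, 2.5), jitter=False)        # neck
    # skeleton: skull shell, spine column with marrow and surface annulus
    add(23, SH, (0, 0, 23), (5.3, 5.8, 6.3), thickness=0.8, jitter=False)
    add(2, E, (0, 0, 23), (4.5, 5.0, 5.5), jitter=False)       # brain
    add(3, E, (-5.8, 2.5, 24), (0.5, 0.5, 0.5), jitter=False)  # eye lenses
    add(3, E, (-5.8, -2.5, 24), (0.5, 0.5, 0.5), jitter=False)
    add(28, E, (-4.5, 0, 19), (1.5, 2.0, 1.0))                 # oral mucosa
    add(4, E, (-3, 4, 16.5), (1.0, 1.5, 1.0))                  # salivary glands
    add(4, E, (-3, -4, 16.5), (1.0, 1.5, 1.0))
    add(30, C, (-1, 0, 13.5), (1.2, 1.2, 2.0))                 # extrathoracic
    add(5, E, (-2.5, 0, 12.0), (1.0, 1.8, 1.2))                # thyroid
    add(25, E, (-5, 0, 9), (1.0, 1.5, 1.5))                    # thymus
    add(6, C, (1, 0.5, 4), (0.8, 0.8, 9))                      # oesophagus
    add(7, E, (0.5, 5.5, 5), (6, 4, 8))                        # lungs
    add(7, E, (0.5, -5.5, 5), (6, 4, 8))
    add(9, E, (-2, 1.5, 3), (4, 4.5, 4))                       # heart
    add(10, E, (-1, -4.5, -4), (6, 6, 4))                      # liver
    add(11, E, (-3, 4, -3), (3, 3.5, 3.5))                     # stomach
    add(12, E, (2, 8, -3), (2, 1.5, 3))                        # spleen
    add(13, E, (0, 1, -6), (1.2, 5, 1.0))                      # pancreas
    add(14, E, (4.5, 4.5, -8), (2, 1.8, 3))                    # kidneys
    add(14, E, (4.5, -4.5, -8), (2, 1.8, 3))
    add(15, E, (4.5, 4.5, -4.2), (0.8, 0.8, 1.0))              # adrenals
    add(15, E, (4.5, -4.5, -4.2), (0.8, 0.8, 1.0))
    add(16, E, (-2, 0, -13), (5, 6, 4))                        # small intestine
    add(17, C, (-3, 0, -9.5), (1.5, 1.5, 7), axis="y")         # colon (upper)
    add(18, C, (-3, -7, -14), (1.5, 1.5, 4))                   # colon (lower)
    add(26, E, (-5, -4, -7), (1.0, 1.0, 1.8))                  # gall bladder
    add(19, E, (-4, 0, -20), (2.5, 2.5, 2.0))                  # bladder
    add(27, E, (-1, 0, -22), (1.2, 1.2, 1.0))                  # prostate
    add(20, E, (-5, 1.5, -26), (1.0, 1.0, 1.5))                # gonads
    add(20, E, (-5, -1.5, -26), (1.0, 1.0, 1.5))
    add(29, E, (0, 9.5, 8), (1.0, 1.0, 1.5))                   # lymph nodes
    add(29, E, (0, -9.5, 8), (1.0, 1.0, 1.5))
    add(8, E, (-8.5, 4.5, 6), (1.6, 2.5, 2.5))                 # breast
    add(8, E, (-8.5, -4.5, 6), (1.6, 2.5, 2.5))
    # spine painted last so abdominal organs cannot overwrite it
    add(22, C, (6, 0, -8), (1.7, 1.7, 22), jitter=False)       # bone surface
    add(23, C, (6, 0, -8), (1.4, 1.4, 22), jitter=False)       # cortical bone
    add(21, C, (6, 0, -8), (0.8, 0.8, 22), jitter=False)       # red marrow

    return PhantomRecipe(
        dims=dims, pitch=pitch, seed=seed, primitives=tuple(p), skin_id=1
    )


def generate_body(dims=(64, 64, 160), pitch=0.4, seed=0,
                  registry: OrganRegistry | None = None) -> VoxelPhantom:
    """Convenience wrapper: default body recipe -> phantom."""
    return generate_phantom(default_body_recipe(dims, pitch, seed), registry)


# ----------------------------------------------------------------------
# Slab phantoms (closed-form transport fixtures)

def generate_slab_phantom(layers, registry: OrganRegistry | None = None,
                          pitch: float = 0.5, lateral=(1, 1)) -> VoxelPhantom:
    """1D-layered lattice along x.

    ``layers`` is a list of ``(organ_id, thickness_cm)``; each thickness
    must be a whole multiple of ``pitch``.  ``lateral`` gives (ny, nz).
    """
    registry = registry or default_registry()
    ny, nz = lateral
    cols: list[np.ndarray] = []
    for organ_id, thickness in layers:
        n = thickness / pitch
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"layer thickness {thickness} cm is not a multiple of pitch {pitch}"
            )
        registry.by_id(organ_id)  # raises for unknown IDs
        cols.append(np.full(int(round(n)), organ_id, dtype=np.int16))
    if not cols:
        raise ValueError("slab phantom needs at least one layer")
    profile = np.concatenate(cols)
    grid = np.broadcast_to(profile, (nz, ny, profile.size)).copy()
    return VoxelPhantom(grid, pitch, registry)
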
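"""Voxel anthropomorphic phantom data model and fill-card I/O.

A phantom is a 3D lattice of small cubes ("voxels"), each labelled with
the integer ID of the organ or tissue it belongs to.  IDs index an organ
registry carrying name, density and elemental composition; ID 255 is
reserved for the air outside the body.  The lattice is stored as a numpy
array indexed ``(z, y, x)`` with x varying fastest in the linear fill
order ("filled from the bottom"), and its physical frame is centred on
the origin.

Fill cards are the plain-text exchange format for the ID lattice: a
header line ``# dims nx ny nz pitch`` followed by whitespace-separated
integers, optionally run-length encoded as ``<value>r<count>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import ELEMENTS

OUTSIDE_ID = 255
#: ID 0 is a legal fill-card token meaning void; it carries no material
VOID_ID = 0

#: air surrounding (and possibly inside) the body; argon folded into N2
AIR_COMPOSITION = {"N": 0.768, "O": 0.232}
AIR_DENSITY = 0.001205  # g/cm^3

#: registry CSV element columns, fixed order
ELEMENT_COLUMNS = list(ELEMENTS)

WEIGHT_CLASSES = ("weighted", "remainder", "unscored")


@dataclass(frozen=True)
class OrganSpec:
    """One segmented organ/tissue: ID, density and elemental make-up.

    ``weight_class`` records how the organ enters the effective dose:
    ``weighted`` (carries a named ICRP tissue weighting factor),
    ``remainder`` (shares the remainder weight), or ``unscored``.
    """

    id: int
    name: str
    density: float
    composition: dict[str, float]
    weight_class: str = "remainder"

    def __post_init__(self):
        if not (1 <= self.id <= 254):
            raise ValueError(f"organ ID {self.id} outside 1-254 (255 is air)")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ValueError(f"{self.name}: unknown weight class {self.weight_class!r}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total}, expected 1"
            )
        unknown = set(self.composition) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"{self.name}: unknown elements {sorted(unknown)}")


class OrganRegistry:
    """Ordered collection of :class:`OrganSpec` with unique IDs."""

    def __init__(self, organs):
        organs = list(organs)
        ids = [o.id for o in organs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate organ IDs in registry")
        self.organs = organs
        self._by_id = {o.id: o for o in organs}
        self._by_name = {o.name: o for o in organs}

    def __iter__(self):
        return iter(self.organs)

    def __len__(self):
        return len(self.organs)

    def __contains__(self, organ_id: int) -> bool:
        return organ_id in self._by_id

    @property
    def ids(self):
        return [o.id for o in self.organs]

    def by_id(self, organ_id: int) -> OrganSpec:
        try:
            return self._by_id[organ_id]
        except KeyError:
            raise KeyError(f"organ ID {organ_id} not in registry") from None

    def by_name(self, name: str) -> OrganSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"organ {name!r} not in registry") from None

    # -- CSV interface --------------------------------------------------
    @classmethod
    def from_csv(cls, path_or_buf) -> "OrganRegistry":
        df = pd.read_csv(path_or_buf)
        organs = []
        for _, row in df.iterrows():
            comp = {
                el: float(row[el])
                for el in ELEMENT_COLUMNS
                if el in df.columns and float(row[el]) > 0
            }
            organs.append(
                OrganSpec(int(row["id"]), str(row["name"]), float(row["density"]),
                          comp, str(row["weight_class"]))
            )
        return cls(organs)

    def to_csv(self, path_or_buf) -> None:
        rows = []
        for o in self.organs:
            row = {"id": o.id, "name": o.name, "density": o.density,
                   "weight_class": o.weight_class}
            for el in ELEMENT_COLUMNS:
                row[el] = o.composition.get(el, 0.0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path_or_buf, index=False)


@dataclass
class VoxelPhantom:
    """Organ-ID lattice with physical pitch, centred on the origin.

    ``ids`` is indexed ``(z, y, x)``; ``dims`` is reported as
    ``(nx, ny, nz)``.  Voxel index ``(i, j, k)`` along (x, y, z) has its
    centre at ``(i - n/2 + 0.5) * pitch`` per axis.
    """

    ids: np.ndarray
    pitch: float
    registry: OrganRegistry
    outside_id: int = OUTSIDE_ID

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 3:
            raise ValueError("ids grid must be 3-dimensional (z, y, x)")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        present = set(np.unique(self.ids).tolist())
        allowed = set(self.registry.ids) | {self.outside_id, VOID_ID}
        stray = present - allowed
        if stray:
            raise ValueError(f"grid contains IDs not in registry: {sorted(stray)}")

    # -- geometry -------------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.ids.shape
        return (nx, ny, nz)

    @property
    def voxel_count(self) -> int:
        return int(self.ids.size)

    @property
    def lower_left(self) -> np.ndarray:
        """Physical (x, y, z) of the lattice corner, cm."""
        return -np.array(self.dims, dtype=float) * self.pitch / 2.0

    @property
    def upper_right(self) -> np.ndarray:
        return -self.lower_left

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Centre coordinates of voxels along ``axis`` (0=x, 1=y, 2=z), cm."""
        n = self.dims[axis]
        return (np.arange(n) - n / 2 + 0.5) * self.pitch

    # -- bookkeeping ----------------------------------------------------
    def organ_voxel_counts(self) -> dict[int, int]:
        """Voxel count per ID actually present in the grid."""
        vals, counts = np.unique(self.ids, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def organ_mass(self, organ_id: int) -> float:
        """Mass of one organ in grams: voxel count * pitch^3 * density."""
        spec = self.registry.by_id(organ_id)  # raises for unknown ID
        n = int(np.count_nonzero(self.ids == organ_id))
        return n * self.pitch**3 * spec.density

    def organ_masses(self) -> dict[str, float]:
        """Masses in grams for every registry organ (zero if absent)."""
        counts = self.organ_voxel_counts()
        return {
            o.name: counts.get(o.id, 0) * self.pitch**3 * o.density
            for o in self.registry
        }

    def total_mass(self) -> float:
        """Body mass in grams (air excluded)."""
        return sum(self.organ_masses().values())


def voxel_count(phantom: VoxelPhantom) -> int:
    """Total number of voxels, the product of the lattice dimensions."""
    return phantom.voxel_count


# ----------------------------------------------------------------------
# Fill-card I/O

_RUN_TOKEN = re.compile(r"^(-?\d+)r(\d+)$")


def read_fill_card(stream):
    """Parse a fill card into ``(linear_ids, header)``.

    ``header`` is ``None`` or a dict with keys ``dims`` and ``pitch`` when
    the canonical ``# dims nx ny nz pitch`` header line is present.
    Tokens are plain integers or run-length ``<value>r<count>`` pairs.
    """
    header = None
    values: list[np.ndarray] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*dims\s+(\d+)\s+(\d+)\s+(\d+)\s+([\d.eE+-]+)", line)
            if m:
                header = {
                    "dims": (int(m.group(1)), int(m.group(2)), int(m.group(3))),
                    "pitch": float(m.group(4)),
                }
            continue
        for tok in line.split():
            m = _RUN_TOKEN.match(tok)
            if m:
                val, count = int(m.group(1)), int(m.group(2))
                values.append(np.full(count, val, dtype=np.int64))
            else:
                try:
                    val = int(tok)
                except ValueError:
                    raise ValueError(
                        f"fill card line {lineno}: non-integer token {tok!r}"
                    ) from None
                values.append(np.array([val], dtype=np.int64))
            if not (0 <= val <= 255):
                raise ValueError(
                    f"fill card line {lineno}: ID {val} outside 0-255"
                )
    linear = np.concatenate(values) if values else np.empty(0, dtype=np.int64)
    return linear, header


def write_fill_card(stream, linear, dims=None, pitch=None, run_threshold=4):
    """Write a fill card in canonical form.

    Runs of ``run_threshold`` or more identical IDs are emitted as
    ``<value>r<count>``; shorter runs as literals.  A header line is
    written when ``dims`` and ``pitch`` are given.
    """
    linear = np.asarray(linear).ravel()
    if dims is not None and pitch is not None:
        stream.write(f"# dims {dims[0]} {dims[1]} {dims[2]} {pitch}\n")
    if linear.size == 0:
        return
    # run-length encode
    change = np.flatnonzero(np.diff(linear)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [linear.size])))
    tokens: list[str] = []
    for s, ln in zip(starts, lengths):
        v = int(linear[s])
        if ln >= run_threshold:
            tokens.append(f"{v}r{ln}")
        else:
            tokens.extend([str(v)] * int(ln))
    for i in range(0, len(tokens), 16):
        stream.write(" ".join(tokens[i:i + 16]) + "\n")


def write_phantom_fill_card(stream, phantom: VoxelPhantom) -> None:
    write_fill_card(stream, flatten_lattice(phantom), phantom.dims, phantom.pitch)


def populate_lattice(linear, dims, pitch=1.0, registry=None,
                     outside_id=OUTSIDE_ID) -> VoxelPhantom:
    """Fill a ``(nz, ny, nx)`` grid from a linear ID array, x fastest.

    ``dims`` is ``(nx, ny, nz)``; element ``(z, y, x)`` of the grid is
    ``linear[z*ny*nx + y*nx + x]``.
    """
    nx, ny, nz = dims
    linear = np.asarray(linear)
    if linear.size != nx * ny * nz:
        raise ValueError(
            f"linear array has {linear.size} entries, dims {dims} need {nx * ny * nz}"
        )
    grid = linear.reshape(nz, ny, nx).astype(np.int16)
    if registry is None:
        registry = _registry_from_grid(grid, outside_id)
    return VoxelPhantom(grid, pitch, registry, outside_id)


def _registry_from_grid(grid, outside_id) -> OrganRegistry:
    """Minimal water-like registry covering every ID present in a grid."""
    ids = sorted(int(v) for v in np.unique(grid)
                 if v not in (outside_id, VOID_ID))
    water = {"H": 0.1119, "O": 0.8881}
    return OrganRegistry(
        [OrganSpec(i, f"organ_{i}", 1.0, dict(water)) for i in ids]
    )


def flatten_lattice(phantom: VoxelPhantom) -> np.ndarray:
    """Inverse of :func:`populate_lattice`: the linear fill-order array."""
    return phantom.ids.ravel().copy()


# ----------------------------------------------------------------------
# Slices

_AXIS_MAP = {"coronal": 2, "sagittal": 1, "transverse": 0}


def slice_view(phantom: VoxelPhantom, axis: str, index: int) -> np.ndarray:
    """Extract a 2D ID map.

    ``coronal`` slices at fixed x (depth), returning (z, y); ``sagittal``
    at fixed y, returning (z, x); ``transverse`` at fixed z, returning
    (y, x).
    """
    if axis not in _AXIS_MAP:
        raise ValueError(f"axis must be one of {sorted(_AXIS_MAP)}, got {axis!r}")
    nz, ny, nx = phantom.ids.shape
    n = {"coronal": nx, "sagittal": ny, "transverse": nz}[axis]
    if not (0 <= index < n):
        raise IndexError(f"{axis} index {index} out of range 0-{n - 1}")
    if axis == "coronal":
        return phantom.ids[:, :, index]
    if axis == "sagittal":
        return phantom.ids[:, index, :]
    return phantom.ids[index]


def organ_color_table(registry: OrganRegistry, cmap_name: str = "tab20"):
    """Stable RGBA colour per organ ID for slice rendering."""
    import matplotlib.cm as cm

    cmap = cm.get_cmap(cmap_name)
    return {o.id: cmap(i % cmap.N) for i, o in enumerate(registry)}


def render_slice(phantom: VoxelPhantom, axis: str, index: int,
                 selected_ids=None, cmap_name: str = "tab20") -> np.ndarray:
    """RGBA image of a slice; organs not in ``selected_ids`` (when given)
    and the outside air are rendered transparent."""
    ids2d = slice_view(phantom, axis, index)
    colors = organ_color_table(phantom.registry, cmap_name)
    img = np.zeros(ids2d.shape + (4,), dtype=float)
    for oid, rgba in colors.items():
        if selected_ids is not None and oid not in selected_ids:
            continue
        img[ids2d == oid] = rgba
    return img
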
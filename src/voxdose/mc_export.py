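"""Export phantom runs as Monte Carlo input decks (XML card files).

Writes the four-card XML family used by lattice-based MC photon codes -
materials, geometry, settings and tallies - so a phantom prepared here
can be handed to an external full-physics code.  The dialect is
structural: every export round-trips through this module's own parsers
back to the originating objects, which is how the decks are validated
(the external code is never executed here).

Geometry follows the usual voxel-phantom construction: a rectangular
lattice whose every element is filled by a one-material universe
numbered by organ ID, an outer universe of air (ID 255), and two
concentric bounding spheres - the inner one delimiting the lattice
region, the outer one the vacuum boundary of the calculation.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import (
    AIR_COMPOSITION,
    AIR_DENSITY,
    OUTSIDE_ID,
    OrganRegistry,
    OrganSpec,
    VoxelPhantom,
)
from .transport import MeshTallySpec, PlanarSource


@dataclass(frozen=True)
class ExportConfig:
    """Deck-level parameters: bounding spheres, outside universe, run size."""

    inner_radius: float = 750.0
    outer_radius: float = 800.0
    outside_universe: int = OUTSIDE_ID
    batches: int = 10
    particles_per_batch: int = 80_000_000
    tally_kinds: tuple[str, ...] = ("heating-by-universe",)

    def __post_init__(self):
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner sphere must lie inside the outer boundary")


# ----------------------------------------------------------------------
# Materials

def export_materials(registry: OrganRegistry) -> ET.Element:
    """One material element per organ, numbered by organ ID, plus air."""
    root = ET.Element("materials")
    for organ in list(registry) + [None]:
        if organ is None:
            mid, name, density, comp = OUTSIDE_ID, "air", AIR_DENSITY, AIR_COMPOSITION
        else:
            mid, name, density, comp = (organ.id, organ.name, organ.density,
                                        organ.composition)
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name}: mass fractions sum to {total}")
        mat = ET.SubElement(root, "material", id=str(mid), name=name)
        ET.SubElement(mat, "density", value=repr(float(density)), units="g/cm3")
        if organ is not None:
            mat.set("weight_class", organ.weight_class)
        for el, frac in comp.items():
            ET.SubElement(mat, "element", name=el, fraction=repr(float(frac)),
                          type="wo")
    return root


def parse_materials(root: ET.Element) -> OrganRegistry:
    """Inverse of :func:`export_materials` (air entry dropped)."""
    organs = []
    for mat in root.findall("material"):
        mid = int(mat.get("id"))
        if mid == OUTSIDE_ID:
            continue
        density = float(mat.find("density").get("value"))
        comp = {el.get("name"): float(el.get("fraction"))
                for el in mat.findall("element")}
        organs.append(OrganSpec(mid, mat.get("name"), density, comp,
                                mat.get("weight_class", "remainder")))
    return OrganRegistry(organs)


# ----------------------------------------------------------------------
# Geometry

def export_geometry(phantom: VoxelPhantom,
                    config: ExportConfig = ExportConfig()) -> ET.Element:
    """Rectangular lattice + bounding spheres.

    The lattice's universe map is the phantom ID grid written in fill
    order (x fastest); note that for full-resolution phantoms this is a
    large text node.
    """
    root = ET.Element("geometry")
    lat = ET.SubElement(root, "lattice", id="1", name="voxel phantom")
    nx, ny, nz = phantom.dims
    ET.SubElement(lat, "dimension").text = f"{nx} {ny} {nz}"
    ET.SubElement(lat, "pitch").text = " ".join([repr(float(phantom.pitch))] * 3)
    ET.SubElement(lat, "lower_left").text = " ".join(
        repr(float(v)) for v in phantom.lower_left)
    ET.SubElement(lat, "outer").text = str(config.outside_universe)
    ET.SubElement(lat, "universes").text = " ".join(
        str(int(v)) for v in phantom.ids.ravel())
    ET.SubElement(root, "surface", id="1", type="sphere",
                  coeffs=f"0 0 0 {config.inner_radius!r}")
    ET.SubElement(root, "surface", id="2", type="sphere",
                  coeffs=f"0 0 0 {config.outer_radius!r}", boundary="vacuum")
    ET.SubElement(root, "cell", id="1", fill="1", region="-1")
    ET.SubElement(root, "cell", id="2", material=str(config.outside_universe),
                  region="1 -2")
    return root


def parse_geometry(root: ET.Element, registry: OrganRegistry | None = None):
    """Inverse of :func:`export_geometry`: (phantom, config)."""
    lat = root.find("lattice")
    nx, ny, nz = (int(v) for v in lat.find("dimension").text.split())
    pitch = float(lat.find("pitch").text.split()[0])
    outer = int(lat.find("outer").text)
    linear = np.array(lat.find("universes").text.split(), dtype=np.int64)
    grid = linear.reshape(nz, ny, nx).astype(np.int16)
    radii = sorted(
        float(s.get("coeffs").split()[3]) for s in root.findall("surface"))
    config = ExportConfig(inner_radius=radii[0], outer_radius=radii[-1],
                          outside_universe=outer)
    if registry is None:
        from .phantom import _registry_from_grid
        registry = _registry_from_grid(grid, outer)
    return VoxelPhantom(grid, pitch, registry, outside_id=outer), config


# ----------------------------------------------------------------------
# Settings

def export_settings(source: PlanarSource,
                    config: ExportConfig = ExportConfig()) -> ET.Element:
    """Fixed-source run: monodirectional +x photon plane source, one
    energy line, batches and particles per batch."""
    root = ET.Element("settings")
    ET.SubElement(root, "run_mode").text = "fixed source"
    ET.SubElement(root, "batches").text = str(config.batches)
    ET.SubElement(root, "particles").text = str(config.particles_per_batch)
    src = ET.SubElement(root, "source", particle="photon")
    space = ET.SubElement(src, "space", type="box")
    ET.SubElement(space, "parameters").text = (
        f"{source.x0!r} {source.y_extent[0]!r} {source.z_extent[0]!r} "
        f"{source.x0!r} {source.y_extent[1]!r} {source.z_extent[1]!r}"
    )
    angle = ET.SubElement(src, "angle", type="monodirectional")
    ET.SubElement(angle, "reference_uvw").text = "1 0 0"
    energy = ET.SubElement(src, "energy", type="discrete")
    ET.SubElement(energy, "parameters").text = f"{source.energy_mev * 1e6!r} 1.0"
    return root


def parse_settings(root: ET.Element) -> tuple[PlanarSource, int, int]:
    """Inverse of :func:`export_settings`: (source, batches, particles)."""
    batches = int(root.find("batches").text)
    particles = int(root.find("particles").text)
    src = root.find("source")
    p = [float(v) for v in src.find("space/parameters").text.split()]
    e_ev = float(src.find("energy/parameters").text.split()[0])
    source = PlanarSource(
        x0=p[0], y_extent=(p[1], p[4]), z_extent=(p[2], p[5]),
        energy_mev=e_ev / 1e6, particles_per_batch=particles, batches=batches,
    )
    return source, batches, particles


# ----------------------------------------------------------------------
# Tallies

def export_tallies(config: ExportConfig, registry: OrganRegistry | None = None,
                   mesh: MeshTallySpec | None = None) -> ET.Element:
    """Heating tally filtered by the organ universes and/or a flux mesh."""
    if not config.tally_kinds:
        raise ValueError("no tally kinds requested")
    root = ET.Element("tallies")
    tid = 0
    for kind in config.tally_kinds:
        tid += 1
        if kind == "heating-by-universe":
            if registry is None:
                raise ValueError("heating tally needs an organ registry")
            tally = ET.SubElement(root, "tally", id=str(tid), name="organ heating")
            ET.SubElement(tally, "filter", type="universe",
                          bins=" ".join(str(o.id) for o in registry))
            ET.SubElement(tally, "filter", type="particle", bins="photon")
            ET.SubElement(tally, "scores").text = "heating"
        elif kind == "mesh-flux":
            m = mesh or MeshTallySpec((1, 1000, 1000), (-11.0, -20.0, 0.0),
                                      (-10.0, 20.0, 67.0))
            me = ET.SubElement(root, "mesh", id=str(tid))
            ET.SubElement(me, "dimension").text = " ".join(str(v) for v in m.dims)
            ET.SubElement(me, "lower_left").text = " ".join(
                repr(float(v)) for v in m.lower_left)
            ET.SubElement(me, "upper_right").text = " ".join(
                repr(float(v)) for v in m.upper_right)
            tally = ET.SubElement(root, "tally", id=str(tid), name="radiograph")
            ET.SubElement(tally, "filter", type="mesh", bins=str(tid))
            ET.SubElement(tally, "filter", type="particle", bins="photon")
            ET.SubElement(tally, "scores").text = "flux"
        else:
            raise ValueError(f"unknown tally kind {kind!r}")
    return root


def parse_tallies(root: ET.Element):
    """Inverse of :func:`export_tallies`: (universe bins, mesh spec or None)."""
    universes = None
    mesh = None
    for tally in root.findall("tally"):
        for f in tally.findall("filter"):
            if f.get("type") == "universe":
                universes = [int(v) for v in f.get("bins").split()]
    m = root.find("mesh")
    if m is not None:
        dims = tuple(int(v) for v in m.find("dimension").text.split())
        ll = tuple(float(v) for v in m.find("lower_left").text.split())
        ur = tuple(float(v) for v in m.find("upper_right").text.split())
        mesh = MeshTallySpec(dims, ll, ur)
    return universes, mesh


# ----------------------------------------------------------------------
# Whole deck

def to_string(root: ET.Element) -> str:
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def write_deck(out_dir, phantom: VoxelPhantom, source: PlanarSource,
               config: ExportConfig = ExportConfig(),
               mesh: MeshTallySpec | None = None) -> dict:
    """Write materials/geometry/settings/tallies XML plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "materials": export_materials(phantom.registry),
        "geometry": export_geometry(phantom, config),
        "settings": export_settings(source, config),
        "tallies": export_tallies(config, phantom.registry, mesh),
    }
    for name, root in files.items():
        (out / f"{name}.xml").write_text(to_string(root))
    manifest = {
        "dims": list(phantom.dims),
        "pitch": phantom.pitch,
        "energy_MeV": source.energy_mev,
        "batches": config.batches,
        "particles_per_batch": config.particles_per_batch,
        "inner_radius_cm": config.inner_radius,
        "outer_radius_cm": config.outer_radius,
        "tally_kinds": list(config.tally_kinds),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
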
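"""File formats: HDF5 frame stacks, geometry configs, PDB coordinates and
map output (CCP4-style binary grid, CSV interchange, JSON sidecar).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import CrystalFrame, DetectorGeometry, DiffractionFrame
from .mapping import DiffuseMap
from .models import AtomicModel
from .synthetic import FrameStack

# --------------------------------------------------------------------------
# geometry / crystal config


def load_config(path) -> tuple[DetectorGeometry, CrystalFrame]:
    """Read a YAML or JSON config mirroring the geometry/crystal fields."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    g = data["detector"]
    geometry = DetectorGeometry(
        distance=g["distance"], pixel_size=g["pixel_size"],
        n_fast=g["n_fast"], n_slow=g["n_slow"],
        beam_center=tuple(g["beam_center"]), wavelength=g["wavelength"],
        polarization_fraction=g.get("polarization_fraction", 0.5),
        polarization_plane_normal=tuple(g.get("polarization_plane_normal",
                                              (0.0, 1.0, 0.0))),
        rotation_axis=tuple(g.get("rotation_axis", (1.0, 0.0, 0.0))),
    )
    c = data["crystal"]
    crystal = CrystalFrame(
        unit_cell=tuple(c["unit_cell"]),
        spacegroup_label=c.get("spacegroup", "P1"),
        orientation=np.asarray(c["orientation"]) if "orientation" in c else None,
    )
    return geometry, crystal


def save_config(path, geometry: DetectorGeometry, crystal: CrystalFrame) -> None:
    data = {
        "detector": {
            "distance": geometry.distance, "pixel_size": geometry.pixel_size,
            "n_fast": geometry.n_fast, "n_slow": geometry.n_slow,
            "beam_center": [float(x) for x in geometry.beam_center],
            "wavelength": geometry.wavelength,
            "polarization_fraction": geometry.polarization_fraction,
            "polarization_plane_normal":
                [float(x) for x in geometry.polarization_plane_normal],
            "rotation_axis": [float(x) for x in geometry.rotation_axis],
        },
        "crystal": {
            "unit_cell": [float(x) for x in crystal.unit_cell],
            "spacegroup": crystal.spacegroup_label,
            "orientation": np.asarray(crystal.orientation).tolist(),
        },
    }
    Path(path).write_text(yaml.safe_dump(data))


# --------------------------------------------------------------------------
# frame stacks


def save_frame_stack(path, stack: FrameStack) -> None:
    """Write frames to the standard multi-frame HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=np.stack([f.pixels for f in stack.frames]))
        h5.create_dataset("valid",
                          data=np.stack([f.valid_mask for f in stack.frames]))
        h5.create_dataset("phi_start",
                          data=[f.phi_start for f in stack.frames])
        h5.create_dataset("phi_width",
                          data=[f.phi_width for f in stack.frames])
        h5.create_dataset("scale", data=[f.scale_factor for f in stack.frames])
        g = stack.geometry
        h5.attrs["geometry"] = json.dumps({
            "distance": g.distance, "pixel_size": g.pixel_size,
            "n_fast": g.n_fast, "n_slow": g.n_slow,
            "beam_center": list(g.beam_center), "wavelength": g.wavelength,
            "polarization_fraction": g.polarization_fraction,
            "polarization_plane_normal": list(g.polarization_plane_normal),
            "rotation_axis": list(g.rotation_axis)})
        c = stack.crystal
        h5.attrs["crystal"] = json.dumps({
            "unit_cell": list(c.unit_cell),
            "spacegroup": c.spacegroup_label,
            "orientation": np.asarray(c.orientation).tolist()})


def load_frame_stack(path) -> FrameStack:
    with h5py.File(path, "r") as h5:
        data = h5["data"][...]
        valid = h5["valid"][...] if "valid" in h5 else np.ones_like(data, bool)
        phi_start = h5["phi_start"][...]
        phi_width = h5["phi_width"][...]
        scale = h5["scale"][...]
        gdict = json.loads(h5.attrs["geometry"])
        cdict = json.loads(h5.attrs["crystal"])
    geometry = DetectorGeometry(
        distance=gdict["distance"], pixel_size=gdict["pixel_size"],
        n_fast=gdict["n_fast"], n_slow=gdict["n_slow"],
        beam_center=tuple(gdict["beam_center"]), wavelength=gdict["wavelength"],
        polarization_fraction=gdict["polarization_fraction"],
        polarization_plane_normal=tuple(gdict["polarization_plane_normal"]),
        rotation_axis=tuple(gdict["rotation_axis"]))
    crystal = CrystalFrame(unit_cell=tuple(cdict["unit_cell"]),
                           spacegroup_label=cdict["spacegroup"],
                           orientation=np.asarray(cdict["orientation"]))
    frames = [DiffractionFrame(data[i], valid[i].astype(bool),
                               float(phi_start[i]), float(phi_width[i]),
                               float(scale[i]))
              for i in range(len(data))]
    return FrameStack(frames, geometry, crystal)


# --------------------------------------------------------------------------
# coordinates


def read_pdb(path, cell=None, spacegroup: str = "P1") -> AtomicModel:
    """Load an atomic model from PDB, honoring occupancy and B columns."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, extra_fields=["occupancy",
                                                          "b_factor"])
    if cell is None:
        box = atoms.box
        if box is None:
            raise ValueError("PDB lacks CRYST1 and no cell was supplied")
        lengths = np.linalg.norm(box, axis=1)
        def angle(u, v):
            return np.degrees(np.arccos(u @ v / (np.linalg.norm(u)
                                                 * np.linalg.norm(v))))
        cell = (lengths[0], lengths[1], lengths[2],
                angle(box[1], box[2]), angle(box[0], box[2]),
                angle(box[0], box[1]))
    return AtomicModel(list(atoms.element), np.asarray(atoms.coord, float),
                       np.asarray(atoms.occupancy, float),
                       np.asarray(atoms.b_factor, float),
                       tuple(float(x) for x in cell), spacegroup)


# --------------------------------------------------------------------------
# reference profiles


def read_reference_profile(path):
    """Two-column whitespace table (|q| in 1/A, intensity) -> interpolator."""
    table = np.loadtxt(path)
    qs, ys = table[:, 0], table[:, 1]

    def ref(q):
        return np.interp(np.asarray(q), qs, ys)
    return ref


# --------------------------------------------------------------------------
# map output


def write_map_csv(dmap: DiffuseMap, path) -> None:
    """Flat (h, k, l, intensity, n_obs, multiplicity, snr) table."""
    hkl = dmap.grid.hkl()
    d = dmap.defined
    cols = np.column_stack([hkl[d], dmap.intensity[d], dmap.n_obs[d],
                            dmap.multiplicity[d], dmap.snr[d]])
    header = "h,k,l,intensity,n_obs,multiplicity,snr"
    np.savetxt(path, cols, delimiter=",", header=header, comments="")


def write_map_json(dmap: DiffuseMap, path) -> None:
    d = dmap.defined
    vals = dmap.intensity[d]
    meta = {
        "unit_cell": list(dmap.grid.crystal.unit_cell),
        "spacegroup": dmap.grid.crystal.spacegroup_label,
        "oversampling": dmap.grid.oversampling,
        "extent": dmap.grid.extent,
        "n_defined": int(d.sum()),
        "n_voxels": int(dmap.grid.n_voxels),
        "intensity_min": float(vals.min()) if d.any() else None,
        "intensity_max": float(vals.max()) if d.any() else None,
        "intensity_mean": float(vals.mean()) if d.any() else None,
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def write_map_ccp4(dmap: DiffuseMap, path) -> None:
    """Minimal CCP4/MRC (mode 2) volume; undefined voxels written as zero."""
    n = dmap.grid.size
    arr = np.nan_to_num(dmap.as_3d()).astype("<f4")
    cell = dmap.grid.crystal.unit_cell
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, n, n, n)          # NC, NR, NS
    struct.pack_into("<i", header, 12, 2)                # MODE float32
    struct.pack_into("<3i", header, 16, -(n // 2), -(n // 2), -(n // 2))
    struct.pack_into("<3i", header, 28, n, n, n)         # intervals
    struct.pack_into("<6f", header, 40, *[float(x) for x in cell])
    struct.pack_into("<3i", header, 64, 1, 2, 3)         # axis order
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()),
                     float(arr.mean()))
    struct.pack_into("<i", header, 88, 1)                # ISPG
    header[208:212] = b"MAP "
    struct.pack_into("<4B", header, 212, 0x44, 0x41, 0, 0)  # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # CCP4 column-fastest ordering: write transposed
        fh.write(np.ascontiguousarray(arr.T).tobytes())
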
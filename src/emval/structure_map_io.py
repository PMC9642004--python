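"""Structure and density-map I/O with explicit geometric conventions.

All physical positions are in Angstroms in the map frame.  The centre of
voxel ``(i, j, k)`` of a :class:`DensityMap` lies at
``origin + (i * sx, j * sy, k * sz)``; the data array is always stored with
axis order ``(x, y, z)`` regardless of the axis permutation of the file it
was read from.

Map files are MRC2014 / CCP4 format (modes 0, 1 and 2 only).  Atomic models
are read from PDB or mmCIF via biotite; the in-memory hierarchy is a plain
chain -> residue -> atom tree so downstream scoring code never depends on a
particular I/O library.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "Atom",
    "Residue",
    "Chain",
    "AtomicModel",
    "MapFormatError",
    "ModelFormatError",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
]

#: Residue names treated as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: The twenty standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class MapFormatError(ValueError):
    """Raised for malformed or unsupported MRC/CCP4 files."""


class ModelFormatError(ValueError):
    """Raised for unreadable or empty atomic-model files."""


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """A 3-D voxel grid with physical geometry.

    Attributes
    ----------
    data:
        Density values indexed ``[ix, iy, iz]`` (x, y, z order).
    voxel_size:
        Voxel edge lengths ``(sx, sy, sz)`` in Angstrom.
    origin:
        Position in Angstrom of the centre of voxel ``(0, 0, 0)``.
    axis_order:
        The file-axis permutation the data was normalised from, as a tuple
        of 1-based axis ids in (column, row, section) order.  Purely
        informational.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"map data must be 3-D, got shape {self.data.shape}")
        if any(n < 8 for n in self.data.shape):
            raise ValueError(
                f"map dimensions must each be >= 8 voxels, got {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if any(not np.isfinite(v) or v <= 0 for v in vs):
            raise ValueError(f"voxel_size components must be positive, got {vs}")
        self.voxel_size = vs
        og = tuple(float(v) for v in self.origin)
        if any(not np.isfinite(v) for v in og):
            raise ValueError(f"origin must be finite, got {og}")
        self.origin = og

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self, data: np.ndarray | None = None) -> "DensityMap":
        """A deep copy, optionally substituting the data array."""
        return DensityMap(
            data=self.data.copy() if data is None else np.asarray(data),
            voxel_size=self.voxel_size,
            origin=self.origin,
            axis_order=self.axis_order,
        )

    def same_grid(self, other: "DensityMap", tol: float = 1e-4) -> bool:
        """True when the two maps share shape, voxel size and origin."""
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def voxel_centres_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def position_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for physical positions (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)


_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


def read_map(path) -> DensityMap:
    """Read an MRC2014/CCP4 map and normalise it to (x, y, z) axis order.

    The origin is taken from the ORIGIN header record when set, otherwise
    derived from NXSTART/NYSTART/NZSTART times the voxel size.  When both
    are set and disagree, ORIGIN wins and a warning is logged.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise MapFormatError(f"{path}: truncated header ({len(header)} bytes)")
        (nc, nr, ns, mode) = struct.unpack("<4i", header[0:16])
        nstart = struct.unpack("<3i", header[16:28])
        mxyz = struct.unpack("<3i", header[28:40])
        cella = struct.unpack("<3f", header[40:52])
        mapcrs = struct.unpack("<3i", header[64:76])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        origin_rec = struct.unpack("<3f", header[196:208])
        map_id = header[208:212]
        if map_id not in (b"MAP ", b"MAP\x00"):
            raise MapFormatError(
                f"{path}: bad MAP identifier {map_id!r} (word 53); not MRC2014"
            )
        if mode not in _MODE_DTYPES:
            raise MapFormatError(
                f"{path}: unsupported MODE {mode}; only modes 0/1/2 are accepted"
            )
        if sorted(mapcrs) != [1, 2, 3]:
            raise MapFormatError(
                f"{path}: MAPC/MAPR/MAPS must be a permutation of 1,2,3, got {mapcrs}"
            )
        if any(n <= 0 for n in (nc, nr, ns)):
            raise MapFormatError(f"{path}: non-positive grid dimensions {(nc, nr, ns)}")
        if any(m <= 0 for m in mxyz):
            raise MapFormatError(f"{path}: non-positive MX/MY/MZ {mxyz}")
        if any(c <= 0 for c in cella):
            raise MapFormatError(f"{path}: non-positive CELLA {cella}")
        fh.seek(1024 + nsymbt)
        dtype = _MODE_DTYPES[mode]
        n_values = nc * nr * ns
        raw = np.fromfile(fh, dtype=np.dtype(dtype).newbyteorder("<"), count=n_values)
        if raw.size != n_values:
            raise MapFormatError(
                f"{path}: expected {n_values} voxels, file holds {raw.size}"
            )

    arr = raw.reshape(ns, nr, nc)  # sections slowest, columns fastest
    # file dims (0=section,1=row,2=column) map to cell axes (maps,mapr,mapc)
    file_axis_of = {mapcrs[2] - 1: 0, mapcrs[1] - 1: 1, mapcrs[0] - 1: 2}
    perm = (file_axis_of[0], file_axis_of[1], file_axis_of[2])
    data = np.ascontiguousarray(np.transpose(arr, perm)).astype(np.float32, copy=False)

    voxel = tuple(cella[a] / mxyz[a] for a in range(3))
    # nstart triples follow (column, row, section) order
    nstart_axis = [0, 0, 0]
    nstart_axis[mapcrs[0] - 1] = nstart[0]
    nstart_axis[mapcrs[1] - 1] = nstart[1]
    nstart_axis[mapcrs[2] - 1] = nstart[2]
    origin_from_nstart = tuple(nstart_axis[a] * voxel[a] for a in range(3))

    if any(v != 0.0 for v in origin_rec):
        origin = tuple(float(v) for v in origin_rec)
        if any(n != 0 for n in nstart_axis) and not np.allclose(
            origin, origin_from_nstart, atol=1e-3
        ):
            logger.warning(
                "%s: ORIGIN %s and NSTART-derived origin %s disagree; using ORIGIN",
                path, origin, origin_from_nstart,
            )
    else:
        origin = origin_from_nstart

    return DensityMap(
        data=data,
        voxel_size=voxel,
        origin=origin,
        axis_order=tuple(mapcrs),
    )


def write_map(density_map: DensityMap, path) -> None:
    """Write a DensityMap as an MRC2014 file (mode 2, float32)."""
    path = Path(path)
    data = np.asarray(density_map.data, dtype=np.float32)
    nx, ny, nz = data.shape
    voxel = density_map.voxel_size
    cella = (nx * voxel[0], ny * voxel[1], nz * voxel[2])

    # NSTART is written when the origin is an exact voxel multiple, which
    # keeps files readable by tools that ignore the ORIGIN record.
    nstart = [0, 0, 0]
    for a in range(3):
        q = density_map.origin[a] / voxel[a]
        if abs(q - round(q)) < 1e-4:
            nstart[a] = int(round(q))

    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 16, *nstart)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ISPG = 1 (P1)
    struct.pack_into("<i", header, 92, 0)  # NSYMBT
    struct.pack_into("<3f", header, 196, *density_map.origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian MACHST
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)
    header[224:224 + 80] = b"Written by emval".ljust(80)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # x is the column (fastest) axis in the file
        np.ascontiguousarray(np.transpose(data, (2, 1, 0))).tofile(fh)


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom; coordinates in Angstrom, B-factor in Angstrom^2."""

    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 30.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom coord must be length-3, got {self.coord.shape}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy must be in [0, 1], got {self.occupancy} for atom {self.name}"
            )
        if not self.element:
            raise ValueError(f"atom {self.name} has no element")
        self.element = self.element.strip().upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        """First atom with the given name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid]


@dataclass
class AtomicModel:
    """Ordered chain -> residue -> atom hierarchy."""

    chains: list[Chain] = field(default_factory=list)

    def __iter__(self):
        return iter(self.chains)

    def residues(self):
        for chain in self.chains:
            for residue in chain.residues:
                yield chain, residue

    def atoms(self):
        for chain in self.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    yield chain, residue, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        """(n, 3) coordinate array over all atoms."""
        coords = [
            a.coord
            for _, _, a in self.atoms()
            if not (heavy_only and a.is_hydrogen)
        ]
        if not coords:
            return np.empty((0, 3))
        return np.array(coords)

    def get_residue(self, chain_id: str, number: int, insertion_code: str = ""):
        """Look up (chain, residue); raises KeyError listing near misses."""
        near = []
        for chain in self.chains:
            for residue in chain.residues:
                if chain.chain_id == chain_id and residue.key == (number, insertion_code):
                    return chain, residue
                if chain.chain_id == chain_id and abs(residue.number - number) <= 2:
                    near.append(f"{chain_id}/{residue.number}{residue.insertion_code}")
        raise KeyError(
            f"residue {chain_id}/{number}{insertion_code} not in model; "
            f"near misses: {near if near else 'none'}"
        )

    def primary_conformer(self) -> "AtomicModel":
        """Reduce alt-locs to the highest-occupancy conformer per atom.

        Ties are broken alphabetically by alt-loc id, which makes
        single-conformer scoring deterministic.
        """
        new_chains = []
        for chain in self.chains:
            new_residues = []
            for residue in chain.residues:
                by_name: dict[str, Atom] = {}
                for atom in residue.atoms:
                    prev = by_name.get(atom.name)
                    if prev is None:
                        by_name[atom.name] = atom
                    elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
                        prev.occupancy, _altloc_rank(prev.altloc)
                    ):
                        by_name[atom.name] = atom
                new_residues.append(
                    replace(residue, atoms=list(by_name.values()))
                )
            new_chains.append(Chain(chain.chain_id, new_residues))
        return AtomicModel(new_chains)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            [
                Chain(
                    c.chain_id,
                    [
                        replace(
                            r,
                            atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ]
        )


def _altloc_rank(altloc: str) -> float:
    # higher rank wins ties; '' beats 'A' beats 'B' ...
    if altloc in ("", " ", "."):
        return 0.0
    return -ord(altloc[0])


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "cif"
    with open(path, "r", errors="replace") as fh:
        head = fh.read(4096)
    if head.lstrip().startswith("data_") or "_atom_site" in head:
        return "cif"
    return "pdb"


def _atom_array_to_model(array) -> AtomicModel:
    import biotite.structure as struc

    if array.array_length() == 0:
        raise ModelFormatError("no atoms parsed from file")
    altloc_ids = (
        array.get_annotation("altloc_id")
        if "altloc_id" in array.get_annotation_categories()
        else np.full(array.array_length(), "")
    )
    model = AtomicModel()
    chain: Chain | None = None
    residue: Residue | None = None
    for i in range(array.array_length()):
        cid = str(array.chain_id[i])
        if chain is None or chain.chain_id != cid:
            chain = Chain(cid)
            model.chains.append(chain)
            residue = None
        key = (int(array.res_id[i]), str(array.ins_code[i]).strip())
        if residue is None or residue.key != key or residue.name != str(array.res_name[i]):
            residue = Residue(
                name=str(array.res_name[i]),
                number=key[0],
                insertion_code=key[1],
                het=bool(array.hetero[i]),
            )
            chain.residues.append(residue)
        altloc = str(altloc_ids[i]).strip().replace(".", "")
        residue.atoms.append(
            Atom(
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                coord=np.array(array.coord[i], dtype=float),
                b_factor=float(array.b_factor[i]),
                occupancy=float(np.clip(array.occupancy[i], 0.0, 1.0)),
                altloc=altloc,
            )
        )
    return model


def read_model(path) -> AtomicModel:
    """Read a PDB or mmCIF atomic model.

    Format is detected by extension, falling back to content sniffing.
    Waters and other non-polymer entities are retained (tagged via the
    residue ``het`` flag / name); alternate conformers are retained with
    their alt-loc ids.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    extra = ["b_factor", "occupancy"]
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pdb_file = PDBFile.read(str(path))
            array = PDBFile.get_structure(
                pdb_file, model=1, altloc="all", extra_fields=extra
            )
        else:
            from biotite.structure.io.pdbx import CIFFile, get_structure

            cif_file = CIFFile.read(str(path))
            array = get_structure(
                cif_file, model=1, altloc="all", extra_fields=extra
            )
    except ModelFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise library errors
        raise ModelFormatError(f"could not parse {path}: {exc}") from exc
    if array.array_length() == 0:
        raise ModelFormatError(f"no atoms parsed from {path}")
    return _atom_array_to_model(array)


def _model_to_atom_array(model: AtomicModel):
    import biotite.structure as struc

    n = model.n_atoms
    array = struc.AtomArray(n)
    array.add_annotation("b_factor", float)
    array.add_annotation("occupancy", float)
    array.add_annotation("altloc_id", "U1")
    i = 0
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                array.chain_id[i] = chain.chain_id
                array.res_id[i] = residue.number
                array.ins_code[i] = residue.insertion_code
                array.res_name[i] = residue.name
                array.hetero[i] = residue.het
                array.atom_name[i] = atom.name
                array.element[i] = atom.element
                array.coord[i] = atom.coord
                array.b_factor[i] = atom.b_factor
                array.occupancy[i] = atom.occupancy
                array.altloc_id[i] = atom.altloc or ""
                i += 1
    return array


def write_model(model: AtomicModel, path) -> None:
    """Write a model as PDB (fixed columns) or mmCIF depending on extension."""
    path = Path(path)
    fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "cif"
    if fmt == "pdb":
        if model.n_atoms > 99999:
            raise ModelFormatError(
                f"{model.n_atoms} atoms exceed the PDB serial limit (99999); "
                "write mmCIF (.cif) instead"
            )
        for chain in model.chains:
            if len(chain.chain_id) > 1:
                raise ModelFormatError(
                    f"chain id {chain.chain_id!r} does not fit the single-column "
                    "PDB field; write mmCIF (.cif) instead"
                )
    array = _model_to_atom_array(model)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb_file = PDBFile()
        pdb_file.set_structure(array)
        pdb_file.write(str(path))
    else:
        from biotite.structure.io.pdbx import CIFFile, set_structure

        cif_file = CIFFile()
        set_structure(cif_file, array)
        cif_file.write(str(path))
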
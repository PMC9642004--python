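"""Deterministic synthetic inputs: ideal models, simulated maps, controlled defects.

Everything the test-suite and examples need is generated here — ideal
poly-alanine helices built from internal coordinates, simulated noisy maps,
and seeded perturbations (segment shifts, register shifts, rotamer
scrambles, injected clashes, deletions) that emulate real modelling errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_density import simulate_map
from .structure_map_io import Atom, AtomicModel, Chain, DensityMap, Residue

__all__ = [
    "PerturbationSpec",
    "make_helix",
    "make_two_helix_dimer",
    "perturb",
    "make_test_pair",
]

# Ideal backbone internal coordinates (Engh & Huber style values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 109.45
IMPROPER_N_C_CA_CB = 120.0  # L-amino-acid chirality

HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0

_SUPPORTED_RESIDUES = ("ALA", "GLY")


@dataclass
class PerturbationSpec:
    """A controlled model defect.

    ``kind`` is one of ``segment_shift`` (translate a residue range by
    ``magnitude`` A in a seeded random direction), ``register_shift``
    (re-assign side-chain identities ``magnitude`` steps along the backbone),
    ``rotamer_scramble`` (seeded rotation of side chains about CA-CB),
    ``clash_inject`` (push a side-chain atom into a non-bonded neighbour to
    a vdW overlap of ``magnitude`` A) or ``delete_segment``.
    """

    kind: str
    first: int
    last: int
    magnitude: float = 3.0
    seed: int = 0

    KINDS = (
        "segment_shift",
        "register_shift",
        "rotamer_scramble",
        "clash_inject",
        "delete_segment",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.last < self.first:
            raise ValueError("residue range is empty")


# ---------------------------------------------------------------------------
# Internal-coordinate chain building
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, length, angle_deg, dihedral_deg):
    """NeRF placement: position d given three reference atoms a-b-c."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(dihedral),
            length * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(
    n_res: int,
    residue_type: str = "ALA",
    chain_id: str = "A",
    b_factor: float = 30.0,
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
) -> AtomicModel:
    """Ideal alpha-helix (phi=-57, psi=-47, omega=180) with ideal bond geometry.

    Poly-alanine by default (poly-glycine also supported); B = 30 A^2,
    occupancy 1 throughout.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    residue_type = residue_type.upper()
    if residue_type not in _SUPPORTED_RESIDUES:
        raise ValueError(
            f"unsupported residue type {residue_type!r}; "
            f"supported: {_SUPPORTED_RESIDUES}"
        )

    # backbone trace
    n_atoms = [np.array([0.0, 0.0, 0.0])]
    ca_atoms = [np.array([BOND_N_CA, 0.0, 0.0])]
    theta = np.radians(ANGLE_N_CA_C)
    c_atoms = [
        ca_atoms[0]
        + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    ]
    for i in range(1, n_res):
        n_next = _place_atom(
            n_atoms[-1], ca_atoms[-1], c_atoms[-1], BOND_C_N, ANGLE_CA_C_N, psi
        )
        ca_next = _place_atom(
            ca_atoms[-1], c_atoms[-1], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA
        )
        c_next = _place_atom(
            c_atoms[-1], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi
        )
        n_atoms.append(n_next)
        ca_atoms.append(ca_next)
        c_atoms.append(c_next)

    chain = Chain(chain_id)
    for i in range(n_res):
        res = Residue(name=residue_type, number=i + 1)
        res.atoms.append(Atom("N", "N", n_atoms[i], b_factor))
        res.atoms.append(Atom("CA", "C", ca_atoms[i], b_factor))
        res.atoms.append(Atom("C", "C", c_atoms[i], b_factor))
        # carbonyl O anti-planar to the next N (dihedral N-CA-C-O = psi + 180)
        o = _place_atom(
            n_atoms[i], ca_atoms[i], c_atoms[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
        res.atoms.append(Atom("O", "O", o, b_factor))
        if residue_type == "ALA":
            cb = _place_atom(
                n_atoms[i], c_atoms[i], ca_atoms[i],
                BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB,
            )
            res.atoms.append(Atom("CB", "C", cb, b_factor))
        chain.residues.append(res)
    return AtomicModel([chain])


def make_two_helix_dimer(
    n_res: int = 12, separation: float = 10.0, residue_type: str = "ALA"
) -> AtomicModel:
    """Two parallel helices (chains A and B) offset sideways; for contact tests."""
    a = make_helix(n_res, residue_type, chain_id="A")
    b = make_helix(n_res, residue_type, chain_id="B")
    axis = _helix_axis(a)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    for chain in b.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + separation * perp
    return AtomicModel(a.chains + b.chains)


def _helix_axis(model: AtomicModel) -> np.ndarray:
    ca = np.array(
        [r.atom("CA").coord for _, r in model.residues() if r.atom("CA") is not None]
    )
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0]


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O", "OXT")


def perturb(model: AtomicModel, spec: PerturbationSpec) -> AtomicModel:
    """Apply a controlled defect; all other atoms are bit-identical.

    Randomness (shift direction, scramble angles) is fully determined by
    ``spec.seed``.
    """
    out = model.copy()
    rng = np.random.default_rng(spec.seed)
    targets = []
    for chain in out.chains:
        for res in chain.residues:
            if spec.first <= res.number <= spec.last:
                targets.append((chain, res))
    if not targets:
        raise ValueError(
            f"residue range {spec.first}-{spec.last} is outside the model"
        )

    if spec.kind == "segment_shift":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = spec.magnitude * direction
        for _, res in targets:
            for atom in res.atoms:
                atom.coord = atom.coord + shift

    elif spec.kind == "register_shift":
        k = int(round(spec.magnitude))
        for chain in {id(c): c for c, _ in targets}.values():
            residues = chain.residues
            in_range = [r for r in residues if spec.first <= r.number <= spec.last]
            index_of = {id(r): i for i, r in enumerate(residues)}
            donors = []
            for r in in_range:
                j = index_of[id(r)] + k
                donors.append(residues[j] if 0 <= j < len(residues) else None)
            for r, donor in zip(in_range, donors):
                if donor is None:
                    continue
                backbone = [a for a in r.atoms if a.name in _BACKBONE]
                side = [a for a in donor.atoms if a.name not in _BACKBONE]
                r.name = donor.name
                r.atoms = backbone + [
                    Atom(a.name, a.element, a.coord.copy(), a.b_factor,
                         a.occupancy, a.altloc)
                    for a in side
                ]

    elif spec.kind == "rotamer_scramble":
        for _, res in targets:
            ca, cb = res.atom("CA"), res.atom("CB")
            if ca is None or cb is None:
                continue
            angle = rng.uniform(0, 2 * np.pi)
            axis = cb.coord - ca.coord
            axis /= np.linalg.norm(axis)
            rot = _rotation_matrix(axis, angle)
            for atom in res.atoms:
                if atom.name not in _BACKBONE + ("CA", "CB"):
                    atom.coord = ca.coord + rot @ (atom.coord - ca.coord)

    elif spec.kind == "clash_inject":
        from .geometry_validation.refdata import vdw_radius

        all_atoms = [
            (c, r, a)
            for c, r, a in out.atoms()
            if not a.is_hydrogen
        ]
        for chain, res in targets:
            probe = res.atom("CB") or res.atom("O")
            if probe is None:
                continue
            best = None
            for c2, r2, a2 in all_atoms:
                if c2.chain_id == chain.chain_id and abs(r2.number - res.number) < 2:
                    continue
                d = float(np.linalg.norm(a2.coord - probe.coord))
                if best is None or d < best[0]:
                    best = (d, a2)
            if best is None:
                continue
            _, target = best
            vec = target.coord - probe.coord
            dist = np.linalg.norm(vec)
            want = vdw_radius(probe.element) + vdw_radius(target.element) - spec.magnitude
            probe.coord = probe.coord + vec / dist * (dist - want)

    elif spec.kind == "delete_segment":
        for chain in out.chains:
            chain.residues = [
                r for r in chain.residues if not (spec.first <= r.number <= spec.last)
            ]
    return out


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


# ---------------------------------------------------------------------------
# Simulated experimental maps
# ---------------------------------------------------------------------------

def make_test_pair(
    model: AtomicModel,
    resolution: float,
    noise_sigma: float = 0.0,
    box_pad: float = 6.0,
    seed: int = 0,
) -> tuple[DensityMap, AtomicModel]:
    """A simulated 'experimental' map plus the untouched model.

    The grid covers the model extent plus ``box_pad`` A at a voxel size of
    ``resolution / 3``; white Gaussian noise of sd ``noise_sigma`` times the
    in-mask signal RMS is added.  Bit-identical under the same seed.
    """
    if resolution <= 0 or box_pad < 0:
        raise ValueError("resolution and box_pad must be positive")
    voxel = resolution / 3.0
    coords = model.coordinates(heavy_only=True)
    if coords.size == 0:
        raise ValueError("model has no heavy atoms")
    lo = coords.min(axis=0) - box_pad
    hi = coords.max(axis=0) + box_pad
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel)) + 1 for a in range(3))
    shape = tuple(max(s, 8) for s in shape)
    template = DensityMap(
        data=np.zeros(shape, dtype=np.float32),
        voxel_size=(voxel, voxel, voxel),
        origin=tuple(lo),
    )
    clean = simulate_map(model, template, resolution)
    data = clean.data.astype(np.float64)
    if noise_sigma > 0:
        from scipy import ndimage

        ijk = np.round(template.position_to_index(coords)).astype(int)
        occupied = np.zeros(shape, dtype=bool)
        occupied[tuple(ijk.T)] = True
        it = max(1, int(round(3.0 / voxel)))
        mask = ndimage.binary_dilation(occupied, iterations=it)
        signal_rms = float(np.sqrt(np.mean(data[mask] ** 2)))
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma * signal_rms, size=shape)
    return template.copy(data=data.astype(np.float32)), model
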
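"""Steric clash detection and the clashes-per-1000-atoms score.

All non-bonded atom pairs whose van der Waals overlap
``(r1 + r2 - distance)`` reaches the threshold (default 0.4 A) are
reported.  Pairs connected by 1-2, 1-3 or 1-4 bond paths are excluded, as
are donor-hydrogen / acceptor pairs (an H bonded to N, O or S against an N,
O or S), since those contacts are hydrogen bonds, not clashes.  Candidate
pairs come from a KD-tree; an O(n^2) reference implementation is kept for
oracle testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ..structure_map_io import AtomicModel
from .hydrogens import residue_bond_graph
from .refdata import vdw_radius

__all__ = ["ClashRecord", "find_clashes", "find_clashes_brute_force"]

DEFAULT_CLASH_THRESHOLD = 0.4
_HBOND_PARENTS = {"N", "O", "S"}
_ACCEPTORS = {"N", "O", "S"}


@dataclass
class ClashRecord:
    atom_a: str          # "chain/resnum resname/atom"
    atom_b: str
    overlap: float       # A
    midpoint: tuple[float, float, float]


class _FlatAtoms:
    """Flattened atom table with a bond graph over atom indices."""

    def __init__(self, model: AtomicModel):
        self.labels: list[str] = []
        self.coords: list[np.ndarray] = []
        self.radii: list[float] = []
        self.elements: list[str] = []
        self.parent_element: list[str | None] = []
        bonds: list[tuple[int, int]] = []

        index_of: dict[tuple[int, int, str], int] = {}
        prev_c: int | None = None
        prev_chain = None
        for ci, chain in enumerate(model.chains):
            prev_c = None
            for ri, residue in enumerate(chain.residues):
                adj = residue_bond_graph(residue.name) or {}
                local: dict[str, int] = {}
                for atom in residue.atoms:
                    idx = len(self.labels)
                    self.labels.append(
                        f"{chain.chain_id}/{residue.number}{residue.insertion_code} "
                        f"{residue.name}/{atom.name}"
                    )
                    self.coords.append(atom.coord)
                    self.radii.append(vdw_radius(atom.element))
                    self.elements.append(atom.element)
                    self.parent_element.append(None)
                    local[atom.name] = idx
                    index_of[(ci, ri, atom.name)] = idx
                # intra-residue bonds by template name; fall back to distance
                if adj:
                    for name, neighbours in adj.items():
                        if name not in local:
                            continue
                        for nb in neighbours:
                            if nb in local and local[name] < local[nb]:
                                bonds.append((local[name], local[nb]))
                else:
                    items = list(local.items())
                    for (na, ia), (nb, ib) in itertools.combinations(items, 2):
                        d = np.linalg.norm(self.coords[ia] - self.coords[ib])
                        if d < 2.0:
                            bonds.append((ia, ib))
                # peptide bond to previous residue
                n_idx = local.get("N")
                if prev_c is not None and n_idx is not None:
                    if np.linalg.norm(self.coords[prev_c] - self.coords[n_idx]) < 2.5:
                        bonds.append((prev_c, n_idx))
                prev_c = local.get("C")

        n = len(self.labels)
        self.adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in bonds:
            self.adj[i].add(j)
            self.adj[j].add(i)
        for i in range(n):
            if self.elements[i] in ("H", "D") and self.adj[i]:
                parent = next(iter(self.adj[i]))
                self.parent_element[i] = self.elements[parent]
        self.coord_array = (
            np.array(self.coords) if self.coords else np.empty((0, 3))
        )

    def excluded(self, i: int, j: int) -> bool:
        """True for bonded pairs (1-2/1-3/1-4) and hydrogen-bond pairs."""
        # H-bond pair: polar H against an acceptor element
        for a, b in ((i, j), (j, i)):
            if (
                self.elements[a] in ("H", "D")
                and self.parent_element[a] in _HBOND_PARENTS
                and self.elements[b] in _ACCEPTORS
            ):
                return True
        # bond-path distance <= 3 (BFS limited to 3 steps)
        frontier = {i}
        seen = {i}
        for _ in range(3):
            nxt = set()
            for k in frontier:
                nxt |= self.adj[k]
            nxt -= seen
            if j in nxt:
                return True
            seen |= nxt
            frontier = nxt
        return False

    def overlap(self, i: int, j: int) -> float:
        d = float(np.linalg.norm(self.coord_array[i] - self.coord_array[j]))
        return self.radii[i] + self.radii[j] - d


def _collect(flat: _FlatAtoms, pairs, threshold: float) -> list[ClashRecord]:
    records = []
    for i, j in pairs:
        ov = flat.overlap(i, j)
        if ov >= threshold and not flat.excluded(i, j):
            mid = tuple((flat.coord_array[i] + flat.coord_array[j]) / 2.0)
            a, b = sorted((i, j))
            records.append(
                ClashRecord(flat.labels[a], flat.labels[b], round(ov, 4), mid)
            )
    records.sort(key=lambda r: (-r.overlap, r.atom_a, r.atom_b))
    return records


def find_clashes(
    model: AtomicModel, threshold: float = DEFAULT_CLASH_THRESHOLD
) -> tuple[list[ClashRecord], float]:
    """Clash records plus clashscore = 1000 x n_clashes / n_atoms."""
    from scipy.spatial import cKDTree

    flat = _FlatAtoms(model.primary_conformer())
    n_atoms = len(flat.labels)
    if n_atoms == 0:
        return [], 0.0
    max_reach = 2.0 * max(flat.radii) - threshold
    tree = cKDTree(flat.coord_array)
    pairs = tree.query_pairs(max_reach)
    records = _collect(flat, pairs, threshold)
    return records, 1000.0 * len(records) / n_atoms


def find_clashes_brute_force(
    model: AtomicModel, threshold: float = DEFAULT_CLASH_THRESHOLD
) -> tuple[list[ClashRecord], float]:
    """O(n^2) reference implementation (oracle for the KD-tree path)."""
    flat = _FlatAtoms(model.primary_conformer())
    n_atoms = len(flat.labels)
    if n_atoms == 0:
        return [], 0.0
    pairs = itertools.combinations(range(n_atoms), 2)
    records = _collect(flat, pairs, threshold)
    return records, 1000.0 * len(records) / n_atoms
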
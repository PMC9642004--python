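"""Riding-hydrogen placement from ideal residue templates.

Hydrogens are generated per residue from the packaged chemical-component
templates (ideal coordinates + connectivity).  Each template hydrogen is
mapped into the model by superposing the local heavy-atom frame of its
parent (parent, parent's bonded heavy neighbours, and their neighbours)
onto the corresponding model atoms, then the H-parent bond is rescaled to
the template's ideal length exactly.  The backbone amide H is placed
analytically in the peptide plane (anti to the preceding carbonyl); chain
N-termini and prolines get no amide H.  Existing hydrogens are kept, so the
operation is idempotent.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np

from ..structure_map_io import Atom, AtomicModel, Residue

logger = logging.getLogger(__name__)

__all__ = ["add_hydrogens", "template_hydrogens", "residue_bond_graph"]

N_H_LENGTH = 1.01

# template hydrogens never placed on a polymer residue
_SKIP_H = {"H2", "H3", "HXT"}


@lru_cache(maxsize=None)
def _template(res_name: str):
    import biotite.structure.info as info

    try:
        return info.residue(res_name)
    except Exception:  # noqa: BLE001
        return None


@lru_cache(maxsize=None)
def residue_bond_graph(res_name: str) -> dict[str, tuple[str, ...]] | None:
    """Atom-name adjacency for a residue type from the packaged template."""
    tpl = _template(res_name)
    if tpl is None or tpl.bonds is None:
        return None
    names = list(tpl.atom_name)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in tpl.bonds.as_array():
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])
    return {k: tuple(sorted(v)) for k, v in adj.items()}


@lru_cache(maxsize=None)
def template_hydrogens(res_name: str):
    """Hydrogens a polymer residue of this type should carry.

    Returns a list of ``(h_name, parent_name, bond_length, frame_names,
    h_coord, frame_coords)`` tuples, or None for unknown residue types.
    """
    tpl = _template(res_name)
    adj = residue_bond_graph(res_name)
    if tpl is None or adj is None:
        return None
    names = list(tpl.atom_name)
    coord = {n: tpl.coord[i].astype(float) for i, n in enumerate(names)}
    element = {n: e for n, e in zip(names, tpl.element)}
    out = []
    for h_name in names:
        if element[h_name] != "H" or h_name in _SKIP_H:
            continue
        parents = [p for p in adj[h_name] if element[p] != "H"]
        if len(parents) != 1:
            continue
        parent = parents[0]
        if parent == "OXT":
            continue
        # local frame: parent, its heavy neighbours, and their heavy neighbours
        frame = [parent]
        first = [n for n in adj[parent] if element[n] != "H" and n != "OXT"]
        frame += first
        for n in first:
            frame += [
                m for m in adj[n]
                if element[m] != "H" and m not in frame and m != "OXT"
            ]
        if len(frame) < 3:
            continue
        out.append(
            (
                h_name,
                parent,
                float(np.linalg.norm(coord[h_name] - coord[parent])),
                tuple(frame),
                coord[h_name].copy(),
                np.array([coord[n] for n in frame]),
            )
        )
    return out


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Rotation + translation mapping mobile onto target (least squares)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _place_amide_h(residue: Residue, prev_c: np.ndarray) -> Atom | None:
    n = residue.atom("N")
    ca = residue.atom("CA")
    if n is None or ca is None:
        return None
    u1 = prev_c - n.coord
    u2 = ca.coord - n.coord
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    direction = -(u1 + u2)
    norm = np.linalg.norm(direction)
    if norm < 1e-6:
        return None
    return Atom("H", "H", n.coord + N_H_LENGTH * direction / norm, n.b_factor)


def add_hydrogens(model: AtomicModel) -> AtomicModel:
    """Return a copy of the model with riding hydrogens added.

    Nonstandard residues (and waters) are skipped with a warning count;
    existing hydrogens are kept so a second call adds zero atoms.
    """
    out = model.copy()
    n_skipped_residues = 0
    for chain in out.chains:
        prev_res: Residue | None = None
        for residue in chain.residues:
            if not residue.is_amino_acid:
                if not residue.is_water:
                    n_skipped_residues += 1
                prev_res = None
                continue
            existing = {a.name for a in residue.atoms}
            placements = template_hydrogens(residue.name)
            if placements is None:
                n_skipped_residues += 1
                prev_res = residue
                continue

            # amide H: analytic in-plane placement, needs the preceding C
            if (
                residue.name != "PRO"
                and "H" not in existing
                and prev_res is not None
                and prev_res.atom("C") is not None
                and residue.atom("N") is not None
                and np.linalg.norm(prev_res.atom("C").coord - residue.atom("N").coord) < 2.5
            ):
                h = _place_amide_h(residue, prev_res.atom("C").coord)
                if h is not None:
                    residue.atoms.append(h)
                    existing.add("H")

            by_name = {a.name: a for a in residue.atoms}
            for h_name, parent, bond, frame_names, h_tpl, frame_tpl in placements:
                if h_name in existing or h_name == "H":
                    continue
                if parent not in by_name:
                    continue
                model_frame = [by_name.get(n) for n in frame_names]
                keep = [i for i, a in enumerate(model_frame) if a is not None]
                if len(keep) < 3:
                    continue
                target = np.array([model_frame[i].coord for i in keep])
                rot, trans = _kabsch(frame_tpl[keep], target)
                h_pos = rot @ h_tpl + trans
                # snap the bond length to the template ideal exactly
                p = by_name[parent].coord
                vec = h_pos - p
                h_pos = p + vec / np.linalg.norm(vec) * bond
                residue.atoms.append(
                    Atom(h_name, "H", h_pos, by_name[parent].b_factor)
                )
                existing.add(h_name)
            prev_res = residue
    if n_skipped_residues:
        logger.warning(
            "add_hydrogens: %d nonstandard residue(s) skipped", n_skipped_residues
        )
    return out
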
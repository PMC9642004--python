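"""Side-chain rotamer outlier detection from coarse chi-space grids."""

from __future__ import annotations

import pandas as pd

from ..structure_map_io import AtomicModel
from .refdata import CHI1_ATOMS, CHI2_ATOMS, rotamer_model
from .torsion import dihedral

__all__ = ["rotamer_outliers", "RotamerResult", "chi_angles"]


class RotamerResult:
    def __init__(self, table: pd.DataFrame):
        self.table = table
        scored = table[table["rotamer_scored"]]
        self.n_scored = len(scored)
        self.outlier_pct = (
            100.0 * scored["rotamer_outlier"].sum() / len(scored)
            if len(scored)
            else 0.0
        )


def chi_angles(residue) -> list[float] | None:
    """chi1 (and chi2 when defined) for a residue, or None when unscorable."""
    g_name = CHI1_ATOMS.get(residue.name)
    if g_name is None:
        return None
    atoms = [residue.atom(n) for n in ("N", "CA", "CB", g_name)]
    if any(a is None for a in atoms):
        return None
    chis = [dihedral(*(a.coord for a in atoms))]
    chi2_def = CHI2_ATOMS.get(residue.name)
    if chi2_def is not None:
        atoms2 = [residue.atom("CA")] + [residue.atom(n) for n in chi2_def]
        if any(a is None for a in atoms2):
            return None
        chis.append(dihedral(*(a.coord for a in atoms2)))
    return chis


def rotamer_outliers(model: AtomicModel) -> RotamerResult:
    """Flag residues whose chi vector falls below the packaged probability floor.

    ALA/GLY (no chi) and residues with missing side-chain atoms are counted
    as unscorable and excluded from the outlier denominator.
    """
    rows = []
    for chain in model.primary_conformer().chains:
        for res in chain.polymer_residues():
            flag = False
            scored = False
            m = rotamer_model(res.name)
            if m is not None:
                chis = chi_angles(res)
                if chis is not None:
                    scored = True
                    flag = m.is_outlier(*chis)
            rows.append(
                {
                    "chain": chain.chain_id,
                    "resnum": res.number,
                    "icode": res.insertion_code,
                    "resname": res.name,
                    "rotamer_scored": scored,
                    "rotamer_outlier": flag,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "icode", "resname",
            "rotamer_scored", "rotamer_outlier",
        ],
    )
    return RotamerResult(table)
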
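"""CA-trace backbone validation from virtual dihedrals.

For residue ``i`` the virtual dihedrals ``mu_in`` (CA i-2..i+1) and
``mu_out`` (CA i-1..i+2) and the CA virtual angle (CA i-1, i, i+1) are
computed along each continuous CA trace; a residue is flagged when
``(mu_in, mu_out)`` falls below the packaged probability floor.  Traces are
split at CA-CA gaps larger than 4.5 A; the flanking residues of a break are
unscorable, as are chains shorter than five CA atoms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..structure_map_io import AtomicModel
from .refdata import cablam_grid
from .torsion import bond_angle, dihedral

__all__ = ["cablam_flags", "CablamResult"]

CA_BREAK_DISTANCE = 4.5


class CablamResult:
    def __init__(self, table: pd.DataFrame):
        self.table = table
        scored = table.dropna(subset=["cablam_outlier"])
        self.n_scored = len(scored)
        self.outlier_pct = (
            100.0 * scored["cablam_outlier"].sum() / len(scored)
            if len(scored)
            else 0.0
        )


def _ca_segments(residues):
    """Runs of consecutive residues whose CA-CA distances stay below the break cutoff."""
    segment = []
    for res in residues:
        ca = res.atom("CA")
        if ca is None:
            if segment:
                yield segment
            segment = []
            continue
        if segment:
            prev_ca = segment[-1][1]
            if np.linalg.norm(ca.coord - prev_ca) > CA_BREAK_DISTANCE:
                yield segment
                segment = []
        segment.append((res, ca.coord))
    if segment:
        yield segment


def cablam_flags(model: AtomicModel) -> CablamResult:
    grid = cablam_grid()
    rows = []
    for chain in model.primary_conformer().chains:
        residues = chain.polymer_residues()
        scored: dict[tuple[int, str], dict] = {}
        for segment in _ca_segments(residues):
            if len(segment) < 5:
                continue
            ca = np.array([c for _, c in segment])
            for i in range(2, len(segment) - 2):
                res = segment[i][0]
                mu_in = dihedral(ca[i - 2], ca[i - 1], ca[i], ca[i + 1])
                mu_out = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
                ca_angle = bond_angle(ca[i - 1], ca[i], ca[i + 1])
                scored[res.key] = {
                    "mu_in": mu_in,
                    "mu_out": mu_out,
                    "ca_virtual_angle": ca_angle,
                    "cablam_outlier": grid.is_outlier(mu_in, mu_out),
                }
        for res in residues:
            row = {
                "chain": chain.chain_id,
                "resnum": res.number,
                "icode": res.insertion_code,
                "resname": res.name,
                "mu_in": None,
                "mu_out": None,
                "ca_virtual_angle": None,
                "cablam_outlier": None,
            }
            row.update(scored.get(res.key, {}))
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "icode", "resname",
            "mu_in", "mu_out", "ca_virtual_angle", "cablam_outlier",
        ],
    )
    return CablamResult(table)
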
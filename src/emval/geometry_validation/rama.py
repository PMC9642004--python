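"""Ramachandran classification and Z-score."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..structure_map_io import AtomicModel
from .refdata import rama_class_for, rama_grid
from .torsion import dihedral

logger = logging.getLogger(__name__)

__all__ = ["ramachandran", "RamaResult"]

_PEPTIDE_BOND_MAX = 2.5


class RamaResult:
    """Per-residue phi/psi classes plus summary percentages and Z-score."""

    def __init__(self, table: pd.DataFrame):
        self.table = table
        scored = table.dropna(subset=["rama_class"])
        n = len(scored)
        self.n_scored = n
        if n:
            self.favored_pct = 100.0 * (scored["rama_class"] == "favored").sum() / n
            self.outlier_pct = 100.0 * (scored["rama_class"] == "outlier").sum() / n
            mean_logp = scored["rama_logp"].mean()
            ref_mean = scored["ref_mean"].mean()
            ref_sd = float(np.sqrt((scored["ref_sd"] ** 2).mean()))
            self.rama_z = float((mean_logp - ref_mean) / (ref_sd / np.sqrt(n)))
        else:
            self.favored_pct = float("nan")
            self.outlier_pct = float("nan")
            self.rama_z = float("nan")


def _connected(res_a, res_b) -> bool:
    c = res_a.atom("C")
    n = res_b.atom("N")
    return (
        c is not None
        and n is not None
        and np.linalg.norm(c.coord - n.coord) < _PEPTIDE_BOND_MAX
    )


def ramachandran(model: AtomicModel) -> RamaResult:
    """Compute phi/psi, classify each residue and derive the Z-score.

    A residue is scored only when flanked by covalently connected residues
    (phi needs the preceding C, psi the following N).  Chains shorter than
    three residues contribute no rows.
    """
    rows = []
    single = model.primary_conformer()
    any_chain = False
    for chain in single.chains:
        residues = chain.polymer_residues()
        if len(residues) < 3:
            if residues:
                logger.warning(
                    "chain %s has < 3 residues; no Ramachandran rows", chain.chain_id
                )
            continue
        any_chain = True
        for i, res in enumerate(residues):
            row = {
                "chain": chain.chain_id,
                "resnum": res.number,
                "icode": res.insertion_code,
                "resname": res.name,
                "phi": None,
                "psi": None,
                "rama_class": None,
                "rama_logp": None,
                "ref_mean": None,
                "ref_sd": None,
            }
            if 0 < i < len(residues) - 1:
                prev_res, next_res = residues[i - 1], residues[i + 1]
                needed = (
                    prev_res.atom("C"), res.atom("N"), res.atom("CA"),
                    res.atom("C"), next_res.atom("N"),
                )
                if (
                    all(a is not None for a in needed)
                    and _connected(prev_res, res)
                    and _connected(res, next_res)
                ):
                    pc, n_, ca, c, nn = (a.coord for a in needed)
                    phi = dihedral(pc, n_, ca, c)
                    psi = dihedral(n_, ca, c, nn)
                    grid = rama_grid(rama_class_for(res.name, next_res.name))
                    p = grid.probability(phi, psi)
                    row.update(
                        phi=phi,
                        psi=psi,
                        rama_class=grid.classify(phi, psi),
                        rama_logp=float(np.log(p)),
                        ref_mean=grid.ref_mean,
                        ref_sd=grid.ref_sd,
                    )
            rows.append(row)
    if not any_chain:
        logger.warning("no chain with >= 3 residues; Ramachandran table is empty")
    table = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "icode", "resname", "phi", "psi",
            "rama_class", "rama_logp", "ref_mean", "ref_sd",
        ],
    )
    return RamaResult(table)
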
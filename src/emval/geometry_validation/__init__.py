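"""Stereochemical validation: clashes, Ramachandran, rotamers, CA-trace checks
and the logarithmic composite geometry score."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ..structure_map_io import AtomicModel
from .cablam import CablamResult, cablam_flags
from .clashes import ClashRecord, find_clashes, find_clashes_brute_force
from .hydrogens import add_hydrogens
from .rama import RamaResult, ramachandran
from .rotamers import RotamerResult, rotamer_outliers

__all__ = [
    "GeometrySummary",
    "ClashRecord",
    "add_hydrogens",
    "find_clashes",
    "find_clashes_brute_force",
    "ramachandran",
    "rotamer_outliers",
    "cablam_flags",
    "molprobity_score",
    "validate_geometry",
]


@dataclass
class GeometrySummary:
    """All-in-one stereochemistry summary for one model."""

    clashscore: float
    rotamer_outlier_pct: float
    rama_favored_pct: float
    rama_outlier_pct: float
    rama_z: float
    cablam_outlier_pct: float
    molprobity_score: float
    n_atoms: int = 0
    hydrogens_added: bool = True
    parameters: dict = field(default_factory=dict)


def molprobity_score(
    clashscore: float, rotamer_outlier_pct: float, rama_favored_pct: float
) -> float:
    """The published logarithmic composite of the three component scores.

    ``0.426 ln(1 + clashscore)
    + 0.33 ln(1 + max(0, rotamer_outlier_pct - 1))
    + 0.25 ln(1 + max(0, (100 - rama_favored_pct) - 2)) + 0.5``

    A perfectly clean model scores exactly 0.5; the score grows with worse
    geometry and mimics the crystallographic resolution at which such
    geometry would be typical.
    """
    if not all(
        math.isfinite(v)
        for v in (clashscore, rotamer_outlier_pct, rama_favored_pct)
    ):
        raise ValueError("components must be finite")
    if clashscore < 0 or not 0 <= rotamer_outlier_pct <= 100 or not 0 <= rama_favored_pct <= 100:
        raise ValueError("component out of range")
    return (
        0.426 * math.log(1.0 + clashscore)
        + 0.33 * math.log(1.0 + max(0.0, rotamer_outlier_pct - 1.0))
        + 0.25 * math.log(1.0 + max(0.0, (100.0 - rama_favored_pct) - 2.0))
        + 0.5
    )


def _merge_tables(frames: list[pd.DataFrame]) -> pd.DataFrame:
    keys = ["chain", "resnum", "icode", "resname"]
    out = frames[0]
    for frame in frames[1:]:
        out = out.merge(frame, on=keys, how="outer")
    return out.sort_values(["chain", "resnum", "icode"]).reset_index(drop=True)


def validate_geometry(
    model: AtomicModel,
    use_hydrogens: bool = True,
    clash_threshold: float = 0.4,
) -> tuple[GeometrySummary, pd.DataFrame, list[ClashRecord]]:
    """Run the full geometry pipeline on one model.

    Hydrogens are added (riding placement) before clash detection unless
    ``use_hydrogens`` is False, in which case a heavy-atom-only clashscore
    is computed and labelled as such in the summary parameters.
    """
    scored_model = add_hydrogens(model) if use_hydrogens else model
    clash_records, clashscore = find_clashes(scored_model, clash_threshold)
    rama = ramachandran(model)
    rota = rotamer_outliers(model)
    cab = cablam_flags(model)
    summary = GeometrySummary(
        clashscore=clashscore,
        rotamer_outlier_pct=rota.outlier_pct,
        rama_favored_pct=rama.favored_pct,
        rama_outlier_pct=rama.outlier_pct,
        rama_z=rama.rama_z,
        cablam_outlier_pct=cab.outlier_pct,
        molprobity_score=molprobity_score(
            clashscore,
            rota.outlier_pct,
            rama.favored_pct if math.isfinite(rama.favored_pct) else 100.0,
        ),
        n_atoms=scored_model.n_atoms,
        hydrogens_added=use_hydrogens,
        parameters={
            "clash_threshold": clash_threshold,
            "clash_mode": "with-hydrogens" if use_hydrogens else "no-h",
        },
    )
    table = _merge_tables(
        [
            rama.table[["chain", "resnum", "icode", "resname", "phi", "psi",
                        "rama_class", "rama_logp"]],
            rota.table,
            cab.table[["chain", "resnum", "icode", "resname",
                       "mu_in", "mu_out", "ca_virtual_angle", "cablam_outlier"]],
        ]
    )
    return summary, table, clash_records
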
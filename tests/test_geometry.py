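"""Hydrogen placement, clashes, Ramachandran, rotamers, CA-trace checks,
and the composite geometry score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emval.geometry_validation import (
    add_hydrogens,
    cablam_flags,
    find_clashes,
    find_clashes_brute_force,
    molprobity_score,
    ramachandran,
    rotamer_outliers,
    validate_geometry,
)
from emval.geometry_validation.rotamers import chi_angles
from emval.geometry_validation.torsion import bond_angle, dihedral
from emval.structure_map_io import Atom, AtomicModel, Chain, Residue
from emval.synthetic_fixtures import PerturbationSpec, make_helix, perturb


# ---------------------------------------------------------------------------
# hydrogens
# ---------------------------------------------------------------------------


def test_alanine_hydrogen_count(helix30):
    with_h = add_hydrogens(helix30)
    residues = [r for _, r in with_h.residues()]
    # non-N-terminal alanine: HN + HA + 3x HB
    for res in residues[1:]:
        names = {a.name for a in res.atoms if a.is_hydrogen}
        assert names == {"H", "HA", "HB1", "HB2", "HB3"}
    # N-terminal residue gets no amide H
    first = {a.name for a in residues[0].atoms if a.is_hydrogen}
    assert "H" not in first


def test_hydrogen_bond_lengths_ideal(helix30):
    import biotite.structure.info as info

    template = info.residue("ALA")
    names = list(template.atom_name)
    tpl_coord = {n: template.coord[i] for i, n in enumerate(names)}
    ideal = {
        "HA": np.linalg.norm(tpl_coord["HA"] - tpl_coord["CA"]),
        "HB1": np.linalg.norm(tpl_coord["HB1"] - tpl_coord["CB"]),
    }
    with_h = add_hydrogens(helix30)
    res = with_h.chains[0].residues[5]
    parent = {"HA": "CA", "HB1": "CB", "HB2": "CB", "HB3": "CB"}
    for h_name, p_name in parent.items():
        h = res.atom(h_name)
        p = res.atom(p_name)
        d = np.linalg.norm(h.coord - p.coord)
        key = h_name if h_name in ideal else "HB1"
        assert d == pytest.approx(ideal[key], abs=1e-3)


def test_add_hydrogens_idempotent(helix30):
    once = add_hydrogens(helix30)
    twice = add_hydrogens(once)
    assert twice.n_atoms == once.n_atoms


def test_nonstandard_residue_skipped(caplog):
    model = AtomicModel(
        [Chain("A", [Residue("XYZ", 1, atoms=[Atom("C1", "C", [0, 0, 0])])])]
    )
    with caplog.at_level("WARNING"):
        result = add_hydrogens(model)
    assert result.n_atoms == 1
    assert any("skipped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# clashes
# ---------------------------------------------------------------------------


def _free_atoms(positions, element="NE"):
    residues = [
        Residue("UNX", i + 1, het=True, atoms=[Atom("X", element, p)])
        for i, p in enumerate(positions)
    ]
    return AtomicModel([Chain("A", residues)])


def test_no_clash_far_apart():
    model = _free_atoms([(0.0, 0.0, 0.0), (5.0, 0.0, 0.0)], element="C")
    records, score = find_clashes(model)
    assert records == [] and score == 0.0


def test_neon_probe_clash_arithmetic():
    # r = 1.54 A each, 2.6 A apart: overlap = 0.48 -> one clash;
    # 10 atoms total -> clashscore = 1000 * 1 / 10 = 100
    positions = [(0.0, 0.0, 0.0), (2.6, 0.0, 0.0)] + [
        (10.0 * (i + 1), 0.0, 0.0) for i in range(8)
    ]
    model = _free_atoms(positions)
    records, score = find_clashes(model)
    assert len(records) == 1
    assert records[0].overlap == pytest.approx(0.48, abs=1e-6)
    assert score == pytest.approx(100.0)
    brute_records, brute_score = find_clashes_brute_force(model)
    assert brute_score == score


def _random_model(rng, n_atoms=200):
    elements = ["C", "N", "O", "S"]
    residues = []
    for i in range(n_atoms // 10):
        atoms = [
            Atom(f"X{j}", elements[rng.integers(len(elements))], rng.uniform(0, 25, 3))
            for j in range(10)
        ]
        residues.append(Residue("UNX", i + 1, het=True, atoms=atoms))
    return AtomicModel([Chain("A", residues)])


def test_grid_equals_brute_force_on_random_models():
    rng = np.random.default_rng(0)
    for _ in range(50):
        model = _random_model(rng)
        fast_records, fast_score = find_clashes(model)
        slow_records, slow_score = find_clashes_brute_force(model)
        assert fast_score == slow_score
        assert [(r.atom_a, r.atom_b, r.overlap) for r in fast_records] == [
            (r.atom_a, r.atom_b, r.overlap) for r in slow_records
        ]


def test_helix_clash_free(helix30):
    _, score = find_clashes(add_hydrogens(helix30))
    assert score == 0.0


def test_bonded_pairs_excluded(helix30):
    # heavy-atom-only mode: covalent N-CA etc. must not appear as clashes
    records, _ = find_clashes(helix30)
    assert records == []


# ---------------------------------------------------------------------------
# Ramachandran
# ---------------------------------------------------------------------------


def test_ideal_helix_all_favored(helix30):
    result = ramachandran(helix30)
    assert result.favored_pct == 100.0
    assert result.outlier_pct == 0.0


def test_forbidden_region_is_outlier():
    model = make_helix(7, phi=60.0, psi=-120.0)
    result = ramachandran(model)
    scored = result.table.dropna(subset=["rama_class"])
    assert (scored["rama_class"] == "outlier").all()


def test_rama_z_matches_direct_formula(helix30):
    result = ramachandran(helix30)
    scored = result.table.dropna(subset=["rama_class"])
    n = len(scored)
    expected = (scored["rama_logp"].mean() - scored["ref_mean"].mean()) / (
        math.sqrt((scored["ref_sd"] ** 2).mean()) / math.sqrt(n)
    )
    assert result.rama_z == pytest.approx(expected, abs=1e-9)


def test_short_chain_no_rows():
    model = make_helix(5)
    model.chains[0].residues = model.chains[0].residues[:2]
    result = ramachandran(model)
    assert result.n_scored == 0


def test_termini_unscored(helix30):
    result = ramachandran(helix30)
    first = result.table.iloc[0]
    assert first["rama_class"] is None or (isinstance(first["rama_class"], float) and math.isnan(first["rama_class"]))


# ---------------------------------------------------------------------------
# rotamers
# ---------------------------------------------------------------------------


def _leucine_with_chi(chi1, chi2):
    """Build a LEU residue from the ideal template, then drive chi angles."""
    import biotite.structure.info as info

    template = info.residue("LEU")
    heavy = [
        Atom(str(n), str(e), template.coord[i].astype(float))
        for i, (n, e) in enumerate(zip(template.atom_name, template.element))
        if e != "H" and n != "OXT"
    ]
    residue = Residue("LEU", 2, atoms=heavy)
    _set_chi(residue, ("N", "CA", "CB", "CG"), chi1, moving_root="CB")
    _set_chi(residue, ("CA", "CB", "CG", "CD1"), chi2, moving_root="CG")
    return residue


def _set_chi(residue, atom_names, target, moving_root):
    a, b, c, d = (residue.atom(n).coord for n in atom_names)
    current = dihedral(a, b, c, d)
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    angle = np.radians(target - current)
    cos, sin = np.cos(angle), np.sin(angle)

    def rotate(v):
        v = v - b
        return (
            v * cos + np.cross(axis, v) * sin + axis * np.dot(axis, v) * (1 - cos) + b
        )

    # rotate everything beyond the bond b-c (descendants of moving_root)
    downstream = {
        "CB": {"CG", "CD1", "CD2"},
        "CG": {"CD1", "CD2"},
    }[moving_root]
    for atom in residue.atoms:
        if atom.name in downstream:
            atom.coord = rotate(atom.coord)


def test_leucine_canonical_not_outlier():
    residue = _leucine_with_chi(-60.0, 180.0)
    chis = chi_angles(residue)
    assert chis == pytest.approx([-60.0, 180.0], abs=1e-6)
    model = AtomicModel([Chain("A", [residue])])
    result = rotamer_outliers(model)
    assert result.table["rotamer_outlier"].sum() == 0
    assert result.n_scored == 1


def test_leucine_eclipsed_is_outlier():
    residue = _leucine_with_chi(120.0, 180.0)
    model = AtomicModel([Chain("A", [residue])])
    result = rotamer_outliers(model)
    assert result.table["rotamer_outlier"].sum() == 1
    assert result.outlier_pct == 100.0


def test_ala_gly_unscorable(helix30):
    result = rotamer_outliers(helix30)
    assert result.n_scored == 0
    assert result.outlier_pct == 0.0


def test_missing_side_chain_unscored():
    residue = _leucine_with_chi(-60.0, 180.0)
    residue.atoms = [a for a in residue.atoms if a.name != "CD1"]
    model = AtomicModel([Chain("A", [residue])])
    result = rotamer_outliers(model)
    assert result.n_scored == 0


# ---------------------------------------------------------------------------
# CA-trace validation
# ---------------------------------------------------------------------------


def test_ideal_helix_no_cablam_flags(helix30):
    result = cablam_flags(helix30)
    assert result.outlier_pct == 0.0


def test_displaced_segment_flagged(helix30):
    # seed 2 gives a displacement that keeps the CA trace unbroken
    displaced = perturb(helix30, PerturbationSpec("segment_shift", 10, 14, 3.0, seed=2))
    table = cablam_flags(displaced).table
    flagged = table[table["cablam_outlier"] == True]  # noqa: E712
    assert len(flagged) >= 1
    assert flagged["resnum"].between(8, 16).all()


def test_chain_break_splits_trace(helix30):
    broken = helix30.copy()
    for chain in broken.chains:
        for res in chain.residues:
            if res.number > 15:
                for atom in res.atoms:
                    atom.coord = atom.coord + np.array([50.0, 0.0, 0.0])
    table = cablam_flags(broken).table
    # flanking residues of the break are unscorable
    near_break = table[table["resnum"].isin([14, 15, 16, 17])]
    assert near_break["cablam_outlier"].isna().all()
    assert table["cablam_outlier"].sum() == 0


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent formulation: atan2(|b1| b0.(b1 x b2), (b0 x b1).(b1 x b2))."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    y = np.linalg.norm(b1) * np.dot(b0, np.cross(b1, b2))
    x = np.dot(np.cross(b0, b1), np.cross(b1, b2))
    return np.degrees(np.arctan2(y, x))


def test_dihedral_against_reference_implementation():
    import biotite.structure as struc

    rng = np.random.default_rng(1)
    for _ in range(25):
        p = rng.normal(size=(4, 3)) * 5
        assert dihedral(*p) == pytest.approx(_dihedral_oracle(*p), abs=1e-9)
        # biotite works in float32, hence the looser agreement
        expected = np.degrees(struc.dihedral(p[0], p[1], p[2], p[3]))
        assert dihedral(*p) == pytest.approx(expected, abs=1e-3)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_torsion_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(4, 3)) * 4
    base = dihedral(*points)
    # random rotation (QR of a Gaussian matrix) + translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(size=3) * 10
    moved = points @ q.T + t
    assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
    assert bond_angle(*moved[:3]) == pytest.approx(bond_angle(*points[:3]), abs=1e-9)


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------


def test_molprobity_perfect():
    assert molprobity_score(0.0, 0.0, 100.0) == 0.5


def test_molprobity_direct_evaluation():
    expected = (
        0.426 * math.log(11) + 0.33 * math.log(5) + 0.25 * math.log(9) + 0.5
    )
    assert molprobity_score(10.0, 5.0, 90.0) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(
    clash=st.floats(min_value=0, max_value=100),
    rot=st.floats(min_value=0, max_value=100),
    fav=st.floats(min_value=0, max_value=100),
    d=st.floats(min_value=0.1, max_value=10),
)
def test_molprobity_monotonicity(clash, rot, fav, d):
    base = molprobity_score(clash, rot, fav)
    assert molprobity_score(min(clash + d, 1e6), rot, fav) >= base
    assert molprobity_score(clash, min(rot + d, 100.0), fav) >= base
    assert molprobity_score(clash, rot, max(fav - d, 0.0)) >= base
    assert base >= 0.5


def test_molprobity_validation():
    with pytest.raises(ValueError):
        molprobity_score(-1.0, 0.0, 100.0)
    with pytest.raises(ValueError):
        molprobity_score(float("nan"), 0.0, 100.0)


# ---------------------------------------------------------------------------
# all-green baseline
# ---------------------------------------------------------------------------


def test_ideal_helix_all_green(helix30):
    summary, table, clashes = validate_geometry(helix30)
    assert summary.clashscore == 0.0
    assert summary.rotamer_outlier_pct == 0.0
    assert summary.rama_favored_pct == 100.0
    assert summary.rama_outlier_pct == 0.0
    assert summary.cablam_outlier_pct == 0.0
    assert summary.molprobity_score == 0.5
    assert clashes == []
    assert len(table) == 30
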
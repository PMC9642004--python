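"""Packaged reference data for geometry validation.

Ships coarse, smoothed probability surfaces for backbone phi/psi space,
side-chain chi space and the CA-trace virtual-dihedral space, built as
wrapped-Gaussian mixtures centred on the canonical conformations observed
in high-resolution structures (helix/sheet/ppII basins, staggered chi
rotamers, helical/extended CA-trace regimes).  The surfaces are coarse by
design: classification uses contour levels (favored >= the level enclosing
98% of reference mass, outlier < the 99.95% level), so only the shape of
the basins matters, not their absolute calibration.  Absolute outlier
percentages may therefore differ from probe-based validators by small
margins; every threshold is a declared constant here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "vdw_radius",
    "rama_grid",
    "rama_class_for",
    "rotamer_model",
    "cablam_grid",
    "VDW_RADII",
    "CHI1_ATOMS",
    "CHI2_ATOMS",
    "FAVORED_MASS",
    "OUTLIER_MASS",
    "ROTAMER_OUTLIER_MASS",
    "CABLAM_OUTLIER_MASS",
]

# ---------------------------------------------------------------------------
# van der Waals radii (single element table; declared deviation from
# probe-style per-context radii)
# ---------------------------------------------------------------------------

VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "NE": 1.54,
}
_DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), _DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Wrapped-Gaussian mixture grids
# ---------------------------------------------------------------------------

#: contour masses for Ramachandran classification
FAVORED_MASS = 0.98
OUTLIER_MASS = 0.9995
#: contour mass below which a chi vector is a rotamer outlier
ROTAMER_OUTLIER_MASS = 0.997
#: contour mass for CA-trace (mu_in, mu_out) outliers
CABLAM_OUTLIER_MASS = 0.99

GRID_STEP = 2.0      # degrees, Ramachandran
COARSE_STEP = 10.0   # degrees, chi and CA-trace grids
_BACKGROUND = 1e-8   # per-bin floor so log-probabilities stay finite


def _wrap(delta: np.ndarray) -> np.ndarray:
    return (delta + 180.0) % 360.0 - 180.0


def _mixture_grid(step: float, components, ndim: int = 2) -> np.ndarray:
    """Normalised mixture of wrapped Gaussians on a (360/step)^ndim grid."""
    n = int(round(360.0 / step))
    axis = -180.0 + (np.arange(n) + 0.5) * step
    if ndim == 1:
        total = np.full(n, _BACKGROUND)
        for (c, s, w) in components:
            total += w * np.exp(-0.5 * (_wrap(axis - c) / s) ** 2)
    else:
        g1, g2 = np.meshgrid(axis, axis, indexing="ij")
        total = np.full((n, n), _BACKGROUND)
        for (c1, c2, s1, s2, w) in components:
            total += w * np.exp(
                -0.5 * ((_wrap(g1 - c1) / s1) ** 2 + (_wrap(g2 - c2) / s2) ** 2)
            )
    return total / total.sum()


def _contour_level(grid: np.ndarray, mass: float) -> float:
    """Density level such that bins with density >= level hold ``mass`` of the total."""
    flat = np.sort(grid.ravel())[::-1]
    cum = np.cumsum(flat)
    i = int(np.searchsorted(cum, mass * flat.sum()))
    return float(flat[min(i, len(flat) - 1)])


def _lookup(grid: np.ndarray, step: float, *angles: float) -> float:
    idx = tuple(
        int(((a + 180.0) % 360.0) / step) % grid.shape[0] for a in angles
    )
    return float(grid[idx])


# -- Ramachandran -----------------------------------------------------------

_RAMA_COMPONENTS = {
    "general": [
        (-63, -43, 11, 13, 0.42),   # alpha helix
        (-118, 128, 24, 24, 0.28),  # beta sheet
        (-65, 148, 14, 18, 0.13),   # ppII
        (-100, -15, 22, 20, 0.07),  # alpha tail / bridge
        (57, 40, 10, 10, 0.05),    # left-handed alpha
    ],
    "GLY": [
        (-63, -43, 15, 15, 0.24),
        (63, 43, 15, 15, 0.24),
        (-100, 150, 30, 25, 0.17),
        (100, -150, 30, 25, 0.17),
        (180, 180, 30, 30, 0.18),
    ],
    "PRO": [
        (-63, -35, 9, 14, 0.45),
        (-63, 145, 9, 18, 0.55),
    ],
    "prepro": [
        (-63, -43, 12, 14, 0.30),
        (-120, 130, 25, 25, 0.40),
        (-65, 148, 15, 18, 0.18),
        (57, 40, 10, 10, 0.12),
    ],
}


class RamaGrid:
    """A phi/psi probability grid with contour levels and Z-score moments."""

    def __init__(self, name: str, grid: np.ndarray):
        self.name = name
        self.grid = grid
        self.favored_level = _contour_level(grid, FAVORED_MASS)
        self.outlier_level = _contour_level(grid, OUTLIER_MASS)
        # reference moments of log-probability under the favored-restricted
        # distribution; used by the Z-score without external calibration
        fav = grid[grid >= self.favored_level]
        w = fav / fav.sum()
        logp = np.log(fav)
        self.ref_mean = float(np.sum(w * logp))
        self.ref_sd = float(np.sqrt(np.sum(w * (logp - self.ref_mean) ** 2)))

    def probability(self, phi: float, psi: float) -> float:
        return _lookup(self.grid, GRID_STEP, phi, psi)

    def classify(self, phi: float, psi: float) -> str:
        p = self.probability(phi, psi)
        if p >= self.favored_level:
            return "favored"
        if p >= self.outlier_level:
            return "allowed"
        return "outlier"


@lru_cache(maxsize=None)
def rama_grid(name: str) -> RamaGrid:
    return RamaGrid(name, _mixture_grid(GRID_STEP, _RAMA_COMPONENTS[name]))


def rama_class_for(res_name: str, next_res_name: str | None) -> str:
    if res_name == "GLY":
        return "GLY"
    if res_name == "PRO":
        return "PRO"
    if next_res_name == "PRO":
        return "prepro"
    return "general"


# -- Rotamers ---------------------------------------------------------------

CHI1_ATOMS = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

CHI2_ATOMS = {
    "ARG": ("CB", "CG", "CD"), "GLN": ("CB", "CG", "CD"),
    "GLU": ("CB", "CG", "CD"), "ILE": ("CB", "CG1", "CD1"),
    "LEU": ("CB", "CG", "CD1"), "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "SD"), "PHE": ("CB", "CG", "CD1"),
    "TRP": ("CB", "CG", "CD1"), "TYR": ("CB", "CG", "CD1"),
    "HIS": ("CB", "CG", "ND1"), "ASN": ("CB", "CG", "OD1"),
    "ASP": ("CB", "CG", "OD1"),
}

_CHI1_DEFAULT = [(-65, 12, 0.52), (180, 12, 0.33), (65, 12, 0.15)]
_CHI1_PRO = [(-28, 10, 0.5), (28, 10, 0.5)]

_CHI2_STAGGERED = [(180, 14, 0.50), (-65, 14, 0.30), (65, 14, 0.20)]
_CHI2_AROMATIC = [(90, 30, 0.5), (-90, 30, 0.5)]
_CHI2_BROAD = [(0, 60, 1.0)]  # terminal sp2 groups: effectively unrestrained

_CHI2_CLASS = {
    "ARG": _CHI2_STAGGERED, "GLN": _CHI2_STAGGERED, "GLU": _CHI2_STAGGERED,
    "ILE": _CHI2_STAGGERED, "LEU": _CHI2_STAGGERED, "LYS": _CHI2_STAGGERED,
    "MET": _CHI2_STAGGERED,
    "PHE": _CHI2_AROMATIC, "TYR": _CHI2_AROMATIC, "TRP": _CHI2_AROMATIC,
    "HIS": _CHI2_AROMATIC,
    "ASN": _CHI2_BROAD, "ASP": _CHI2_BROAD,
}


class RotamerModel:
    """Coarse chi1(/chi2) probability grid for one residue type."""

    def __init__(self, res_name: str):
        self.res_name = res_name
        chi1 = _CHI1_PRO if res_name == "PRO" else _CHI1_DEFAULT
        chi2 = _CHI2_CLASS.get(res_name) if res_name != "PRO" else None
        if chi2 is None:
            self.grid = _mixture_grid(COARSE_STEP, chi1, ndim=1)
            self.n_chi = 1
        else:
            g1 = _mixture_grid(COARSE_STEP, chi1, ndim=1)
            g2 = _mixture_grid(COARSE_STEP, chi2, ndim=1)
            self.grid = np.outer(g1, g2)
            self.grid /= self.grid.sum()
            self.n_chi = 2
        self.outlier_level = _contour_level(self.grid, ROTAMER_OUTLIER_MASS)

    def probability(self, *chis: float) -> float:
        return _lookup(self.grid, COARSE_STEP, *chis[: self.n_chi])

    def is_outlier(self, *chis: float) -> bool:
        return self.probability(*chis) < self.outlier_level


@lru_cache(maxsize=None)
def rotamer_model(res_name: str) -> RotamerModel | None:
    if res_name not in CHI1_ATOMS:
        return None  # ALA/GLY: no chi, unscorable
    return RotamerModel(res_name)


# -- CA-trace virtual dihedrals --------------------------------------------

# (mu_in, mu_out) regimes measured on ideal secondary structure:
# alpha helix ~ (51.5, 51.5), beta strand ~ (-168, -168), ppII ~ (-109, -109)
_CABLAM_COMPONENTS = [
    (51.5, 51.5, 12, 12, 0.45),
    (-168, -168, 20, 20, 0.28),
    (-109, -109, 20, 20, 0.15),
    (-60, 140, 25, 25, 0.06),   # turns / loop crossover
    (140, -60, 25, 25, 0.06),
]


class CablamGrid:
    def __init__(self):
        self.grid = _mixture_grid(COARSE_STEP, _CABLAM_COMPONENTS)
        self.outlier_level = _contour_level(self.grid, CABLAM_OUTLIER_MASS)

    def probability(self, mu_in: float, mu_out: float) -> float:
        return _lookup(self.grid, COARSE_STEP, mu_in, mu_out)

    def is_outlier(self, mu_in: float, mu_out: float) -> bool:
        return self.probability(mu_in, mu_out) < self.outlier_level


@lru_cache(maxsize=None)
def cablam_grid() -> CablamGrid:
    return CablamGrid()
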
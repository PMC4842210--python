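"""Ramachandran region classification and dihedral knowledge-based scores.

The bundled tables are *not* Rosetta's: they are built from a documented
Gaussian-mixture prior over the canonical phi/psi basins (right-handed
alpha, beta, PPII, bridge, and a low-weight left-handed alpha), with the
four residue classes of the Rampage scheme (general, glycine, proline,
pre-proline).  Only relative proper-vs-mirror comparisons matter for
mirror detection, and those depend solely on the right-handed dominance
of the basins — absolute values will not match any Rosetta term.

Two scores are exposed:

* ``rama_score``   — sum of -ln density(phi, psi) per residue class
  (Ramachandran-preference potential);
* ``p_aa_p_score`` — sum of -ln P(amino acid | phi/psi bin) from a
  pseudocount-smoothed conditional table.

Lower scores are more native-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path

import numpy as np

from .geometry import backbone_dihedrals
from .structure_io import STANDARD_AA3, StructureModel

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_CLASSES = ("general", "glycine", "proline", "preproline")

GRID_STEP = 2.0          # degrees per region/density grid cell
PAA_BIN = 10.0           # degrees per p_aa_p bin
DENSITY_FLOOR = 1e-6     # minimum density before -ln
PSEUDOCOUNT = 1.0        # Laplace smoothing of the aa-given-bin counts
_PSEUDO_N = 1e6          # pseudo-observation total behind the smoothed table

# Region contours, as fractions of the per-class maximum density.  The
# favored cut sits above the left-handed-alpha peak of the general class
# (~6 % of the global maximum) so that basin is allowed, never favored;
# the allowed cut sits above the density floor so outliers exist at all.
FAVORED_LEVEL = 0.08
ALLOWED_LEVEL = 0.004


class Region(str, Enum):
    FAVORED = "favored"
    ALLOWED = "allowed"
    OUTLIER = "outlier"


# --------------------------------------------------------------------------
# Gaussian-mixture prior: (weight, phi0, psi0, sigma_phi, sigma_psi)
# --------------------------------------------------------------------------

_BASINS: dict[str, list[tuple[float, float, float, float, float]]] = {
    "general": [
        (0.45, -63.0, -43.0, 12.0, 14.0),   # right-handed alpha
        (0.28, -120.0, 130.0, 26.0, 22.0),  # beta
        (0.17, -65.0, 145.0, 15.0, 15.0),   # PPII
        (0.08, -90.0, -5.0, 14.0, 16.0),    # bridge / alpha-beta junction
        (0.02, 60.0, 45.0, 11.0, 11.0),     # left-handed alpha (low weight)
    ],
    "glycine": [
        (0.26, -63.0, -41.0, 13.0, 14.0),
        (0.26, 63.0, 41.0, 13.0, 14.0),     # Gly populates LH-alpha freely
        (0.18, -85.0, 170.0, 20.0, 18.0),
        (0.18, 85.0, -170.0, 20.0, 18.0),
        (0.12, 180.0, 180.0, 22.0, 22.0),
    ],
    "proline": [
        (0.45, -63.0, -35.0, 9.0, 13.0),
        (0.55, -63.0, 150.0, 9.0, 15.0),
    ],
    "preproline": [
        (0.28, -63.0, -43.0, 12.0, 14.0),
        (0.32, -120.0, 130.0, 26.0, 22.0),
        (0.30, -65.0, 145.0, 15.0, 15.0),
        (0.08, -90.0, -5.0, 14.0, 16.0),
        (0.02, 60.0, 45.0, 11.0, 11.0),
    ],
}

# Per-amino-acid multipliers on the (alpha, beta) basin weights used to
# build the conditional P(aa | bin) table.  Coarse secondary-structure
# propensities; Gly and Pro instead use their own class mixtures.
_HELIX_PROP = {
    "A": 1.4, "C": 0.9, "D": 0.9, "E": 1.3, "F": 1.0, "G": 0.5, "H": 0.9,
    "I": 1.0, "K": 1.1, "L": 1.2, "M": 1.1, "N": 0.8, "P": 0.4, "Q": 1.1,
    "R": 1.1, "S": 0.8, "T": 0.8, "V": 0.9, "W": 1.0, "Y": 0.9,
}
_SHEET_PROP = {
    "A": 0.8, "C": 1.1, "D": 0.6, "E": 0.8, "F": 1.2, "G": 0.6, "H": 0.9,
    "I": 1.3, "K": 0.9, "L": 1.0, "M": 1.0, "N": 0.7, "P": 0.4, "Q": 0.9,
    "R": 0.9, "S": 0.9, "T": 1.1, "V": 1.4, "W": 1.2, "Y": 1.2,
}


def _wrapped_gauss2(phi: np.ndarray, psi: np.ndarray,
                    phi0: float, psi0: float, sp: float, ss: float) -> np.ndarray:
    """Periodic (minimum-image) 2-D Gaussian, unnormalised mixture component."""
    dphi = (phi - phi0 + 180.0) % 360.0 - 180.0
    dpsi = (psi - psi0 + 180.0) % 360.0 - 180.0
    z = (dphi / sp) ** 2 + (dpsi / ss) ** 2
    return np.exp(-0.5 * z) / (2.0 * np.pi * sp * ss)


def _mixture_density(phi: np.ndarray, psi: np.ndarray,
                     basins: list[tuple[float, float, float, float, float]]) -> np.ndarray:
    out = np.zeros(np.broadcast(phi, psi).shape)
    for w, p0, s0, sp, ss in basins:
        out = out + w * _wrapped_gauss2(phi, psi, p0, s0, sp, ss)
    return out


def _aa_basins(aa: str) -> list[tuple[float, float, float, float, float]]:
    if aa == "G":
        return _BASINS["glycine"]
    if aa == "P":
        return _BASINS["proline"]
    h, s = _HELIX_PROP[aa], _SHEET_PROP[aa]
    raw = [
        (0.45 * h, -63.0, -43.0, 12.0, 14.0),
        (0.28 * s, -120.0, 130.0, 26.0, 22.0),
        (0.17, -65.0, 145.0, 15.0, 15.0),
        (0.08, -90.0, -5.0, 14.0, 16.0),
        (0.01, 60.0, 45.0, 11.0, 11.0),
    ]
    total = sum(b[0] for b in raw)
    return [(w / total, *rest) for w, *rest in raw]


@dataclass
class RamaTables:
    """Region contours, phi/psi densities, and the P(aa | bin) table.

    ``density``/``region`` grids are per residue class, indexed
    [phi_cell, psi_cell] over [-180, 180) at :data:`GRID_STEP` degrees.
    ``aa_given_bin`` is (nbin, nbin, 20) over :data:`PAA_BIN`-degree bins,
    each bin's 20 probabilities summing to 1.
    """

    density: dict[str, np.ndarray]
    region: dict[str, np.ndarray]
    aa_given_bin: np.ndarray
    grid_step: float = GRID_STEP
    paa_bin: float = PAA_BIN

    @property
    def n_cells(self) -> int:
        return int(round(360.0 / self.grid_step))

    def cell_index(self, phi: float, psi: float) -> tuple[int, int]:
        n = self.n_cells
        i = int(np.floor((phi + 180.0) / self.grid_step)) % n
        j = int(np.floor((psi + 180.0) / self.grid_step)) % n
        return i, j

    def paa_index(self, phi: float, psi: float) -> tuple[int, int]:
        n = int(round(360.0 / self.paa_bin))
        i = int(np.floor((phi + 180.0) / self.paa_bin)) % n
        j = int(np.floor((psi + 180.0) / self.paa_bin)) % n
        return i, j

    # -- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write all grids as plain CSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for cls in RESIDUE_CLASSES:
            np.savetxt(directory / f"density_{cls}.csv", self.density[cls],
                       delimiter=",", fmt="%.8e")
            np.savetxt(directory / f"region_{cls}.csv", self.region[cls],
                       delimiter=",", fmt="%d")
        n = self.aa_given_bin.shape[0]
        flat = self.aa_given_bin.reshape(n * n, 20)
        header = ",".join(AA_ORDER)
        np.savetxt(directory / "aa_given_bin.csv", flat, delimiter=",",
                   fmt="%.8e", header=header, comments="")

    @classmethod
    def load(cls, directory: str | Path) -> "RamaTables":
        directory = Path(directory)
        density = {}
        region = {}
        for rc in RESIDUE_CLASSES:
            density[rc] = np.loadtxt(directory / f"density_{rc}.csv", delimiter=",")
            region[rc] = np.loadtxt(directory / f"region_{rc}.csv",
                                    delimiter=",").astype(np.int8)
        flat = np.loadtxt(directory / "aa_given_bin.csv", delimiter=",", skiprows=1)
        n = int(round(np.sqrt(flat.shape[0])))
        return cls(density=density, region=region,
                   aa_given_bin=flat.reshape(n, n, 20))


def build_tables(seed: int = 0) -> RamaTables:
    """Build the bundled tables from the analytic mixture prior.

    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators and currently unused.
    """
    del seed
    n = int(round(360.0 / GRID_STEP))
    centers = -180.0 + GRID_STEP * (np.arange(n) + 0.5)
    phi_grid, psi_grid = np.meshgrid(centers, centers, indexing="ij")
    cell_area = GRID_STEP * GRID_STEP

    density: dict[str, np.ndarray] = {}
    region: dict[str, np.ndarray] = {}
    for cls_name in RESIDUE_CLASSES:
        d = _mixture_density(phi_grid, psi_grid, _BASINS[cls_name])
        # floor slightly above the advertised minimum so the renormalised
        # grid still satisfies density >= DENSITY_FLOOR everywhere
        d = np.maximum(d, 1.2 * DENSITY_FLOOR)
        d = d / (d.sum() * cell_area)
        density[cls_name] = d
        peak = d.max()
        # keep the allowed cut above the floored plateau, otherwise flat
        # classes (glycine) would have no outlier region at all
        allowed_cut = max(ALLOWED_LEVEL * peak, 3.0 * DENSITY_FLOOR)
        reg = np.zeros_like(d, dtype=np.int8)
        reg[d >= allowed_cut] = 1
        reg[d >= FAVORED_LEVEL * peak] = 2
        region[cls_name] = reg

    nb = int(round(360.0 / PAA_BIN))
    bc = -180.0 + PAA_BIN * (np.arange(nb) + 0.5)
    bphi, bpsi = np.meshgrid(bc, bc, indexing="ij")
    counts = np.zeros((nb, nb, 20))
    for k, aa in enumerate(AA_ORDER):
        counts[:, :, k] = _mixture_density(bphi, bpsi, _aa_basins(aa))
    counts *= _PSEUDO_N / counts.sum()
    probs = (counts + PSEUDOCOUNT) / (
        counts.sum(axis=2, keepdims=True) + 20.0 * PSEUDOCOUNT
    )
    return RamaTables(density=density, region=region, aa_given_bin=probs)


@lru_cache(maxsize=1)
def default_tables() -> RamaTables:
    return build_tables()


# --------------------------------------------------------------------------
# residue classes and classification
# --------------------------------------------------------------------------

def residue_classes(model: StructureModel) -> list[str]:
    """Rampage-style class per residue; pre-proline overrides general."""
    seq = model.sequence
    classes = []
    for i, aa in enumerate(seq):
        if aa == "G":
            classes.append("glycine")
        elif aa == "P":
            classes.append("proline")
        elif i + 1 < len(seq) and seq[i + 1] == "P":
            classes.append("preproline")
        else:
            classes.append("general")
    return classes


def classify_region(phi: float, psi: float, residue_class: str = "general",
                    tables: RamaTables | None = None) -> Region:
    """Favored/allowed/outlier by nearest-grid-cell lookup."""
    if np.isnan(phi) or np.isnan(psi):
        raise ValueError("cannot classify an undefined phi/psi pair")
    if residue_class not in RESIDUE_CLASSES:
        raise ValueError(f"unknown residue class {residue_class!r}")
    tables = tables or default_tables()
    i, j = tables.cell_index(phi, psi)
    code = tables.region[residue_class][i, j]
    return (Region.OUTLIER, Region.ALLOWED, Region.FAVORED)[code]


@dataclass
class RegionFractions:
    favored: float   # percent
    allowed: float
    outlier: float
    n_classified: int

    def as_dict(self) -> dict[str, float]:
        return {"favored": self.favored, "allowed": self.allowed,
                "outlier": self.outlier}


def region_fractions(model: StructureModel,
                     tables: RamaTables | None = None) -> RegionFractions:
    """Percentage of residues (with both angles defined) in each region."""
    tables = tables or default_tables()
    series = backbone_dihedrals(model)
    classes = residue_classes(model)
    counts = {Region.FAVORED: 0, Region.ALLOWED: 0, Region.OUTLIER: 0}
    n = 0
    for i in range(len(model)):
        if np.isnan(series.phi[i]) or np.isnan(series.psi[i]):
            continue
        counts[classify_region(series.phi[i], series.psi[i], classes[i], tables)] += 1
        n += 1
    if n == 0:
        raise ValueError("no residue has both phi and psi defined")
    return RegionFractions(
        favored=100.0 * counts[Region.FAVORED] / n,
        allowed=100.0 * counts[Region.ALLOWED] / n,
        outlier=100.0 * counts[Region.OUTLIER] / n,
        n_classified=n,
    )


def count_lh_alpha(model: StructureModel) -> int:
    """Residues with both phi > 0 and psi > 0 (left-handed-helix region)."""
    series = backbone_dihedrals(model)
    mask = (series.phi > 0) & (series.psi > 0)  # NaN compares False
    return int(np.sum(mask))


# --------------------------------------------------------------------------
# knowledge-based scores
# --------------------------------------------------------------------------

def _bilinear_density(tables: RamaTables, cls_name: str,
                      phi: float, psi: float) -> float:
    """Bilinear interpolation on the periodic density grid (cell centers)."""
    grid = tables.density[cls_name]
    n = tables.n_cells
    step = tables.grid_step
    # continuous cell-center coordinates
    u = (phi + 180.0) / step - 0.5
    v = (psi + 180.0) / step - 0.5
    i0 = int(np.floor(u))
    j0 = int(np.floor(v))
    fu = u - i0
    fv = v - j0
    i0 %= n
    j0 %= n
    i1 = (i0 + 1) % n
    j1 = (j0 + 1) % n
    val = (grid[i0, j0] * (1 - fu) * (1 - fv)
           + grid[i1, j0] * fu * (1 - fv)
           + grid[i0, j1] * (1 - fu) * fv
           + grid[i1, j1] * fu * fv)
    return float(val)


def rama_score(model: StructureModel, tables: RamaTables | None = None) -> float:
    """Sum of -ln density(phi, psi) over residues with both angles defined."""
    tables = tables or default_tables()
    series = backbone_dihedrals(model)
    classes = residue_classes(model)
    total = 0.0
    n = 0
    for i in range(len(model)):
        if np.isnan(series.phi[i]) or np.isnan(series.psi[i]):
            continue
        d = _bilinear_density(tables, classes[i], series.phi[i], series.psi[i])
        total += -np.log(max(d, DENSITY_FLOOR))
        n += 1
    if n == 0:
        raise ValueError("no residue has both phi and psi defined")
    return total


def p_aa_p_score(model: StructureModel, tables: RamaTables | None = None) -> float:
    """Sum of -ln P(amino acid | phi/psi bin) over classifiable residues."""
    tables = tables or default_tables()
    series = backbone_dihedrals(model)
    total = 0.0
    n = 0
    for i, res in enumerate(model.residues):
        if np.isnan(series.phi[i]) or np.isnan(series.psi[i]):
            continue
        bi, bj = tables.paa_index(series.phi[i], series.psi[i])
        aa = res.one_letter
        if aa == "X" or aa not in AA_ORDER:
            logger.warning("unknown residue %r scored as uniform 1/20", res.name)
            p = 1.0 / 20.0
        else:
            p = float(tables.aa_given_bin[bi, bj, AA_ORDER.index(aa)])
        total += -np.log(p)
        n += 1
    if n == 0:
        raise ValueError("no residue has both phi and psi defined")
    return total
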
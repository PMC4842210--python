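"""PDB input/output and validated backbone-only structure models.

Models are reduced to their N/CA/C/O backbone: that is all the downstream
dihedral and superposition machinery needs, and reconstruction pipelines
typically emit single-chain backbone-only coordinate files anyway.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in STANDARD_AA3.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: consecutive residues whose C(i)-N(i+1) distance exceeds this are a chain break
PEPTIDE_BOND_MAX = 2.0
PEPTIDE_BOND_MIN = 1.0


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be turned into a valid model."""


@dataclass
class AtomRecord:
    """A single coordinate record as read from an ATOM line."""

    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    altloc: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_AA3


@dataclass
class Residue:
    """Backbone atoms of one residue; ``O`` may be absent."""

    name: str
    atoms: dict[str, np.ndarray]
    index: int = 0
    #: True when the peptide bond to the *following* residue is broken/absent
    chain_break_after: bool = False

    @property
    def one_letter(self) -> str:
        return STANDARD_AA3.get(self.name, "X")

    def coord(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


@dataclass
class StructureModel:
    """Ordered backbone of a single-chain protein model."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        for res in self.residues:
            missing = [a for a in ("N", "CA", "C") if a not in res.atoms]
            if missing:
                raise PDBFormatError(
                    f"model {self.id}: residue {res.index} {res.name} lacks {missing}"
                )
        self._flag_chain_breaks()

    def _flag_chain_breaks(self) -> None:
        for prev, nxt in zip(self.residues, self.residues[1:]):
            d = float(np.linalg.norm(nxt.coord("N") - prev.coord("C")))
            if not (PEPTIDE_BOND_MIN <= d <= PEPTIDE_BOND_MAX):
                prev.chain_break_after = True

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA positions in residue order."""
        return np.array([r.coord("CA") for r in self.residues])

    def copy(self, new_id: str | None = None) -> "StructureModel":
        residues = [
            Residue(
                name=r.name,
                atoms={k: v.copy() for k, v in r.atoms.items()},
                index=r.index,
                chain_break_after=r.chain_break_after,
            )
            for r in self.residues
        ]
        return StructureModel(id=new_id or self.id, residues=residues)


def read_pdb(path: str | Path, model_policy: str = "first") -> StructureModel:
    """Read a single-chain backbone model from a PDB file.

    Only the first MODEL is used (``model_policy="first"`` is the sole
    supported policy); HETATM records are skipped; of alternate locations
    only blank or 'A' is kept.  Residues missing any of N/CA/C are dropped
    with a warning, and the neighbouring residues are flagged as chain
    breaks via the distance check in :class:`StructureModel`.
    """
    path = Path(path)
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy: {model_policy!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))

    models = list(structure.get_models())
    if not models:
        raise PDBFormatError(f"{path}: no coordinate models found")
    chains = [c for c in models[0].get_chains()]
    chains = [c for c in chains if any(r.id[0] == " " for r in c)]
    if not chains:
        raise PDBFormatError(f"{path}: no polymer ATOM records")
    if len(chains) > 1:
        names = ", ".join(c.id for c in chains)
        raise PDBFormatError(f"{path}: expected a single chain, found: {names}")

    residues: list[Residue] = []
    for res in chains[0]:
        if res.id[0] != " ":  # HETATM / water
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res.get_unpacked_list():
            if atom.get_altloc() not in (" ", "", "A"):
                continue
            if atom.get_name() in BACKBONE_ATOMS and atom.get_name() not in atoms:
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        if any(a not in atoms for a in ("N", "CA", "C")):
            logger.warning(
                "%s: dropping residue %s%s (incomplete backbone)",
                path.name, res.get_resname(), res.id[1],
            )
            continue
        residues.append(Residue(name=res.get_resname(), atoms=atoms, index=res.id[1]))

    if len(residues) < 3:
        raise PDBFormatError(f"{path}: fewer than 3 complete backbone residues")
    return StructureModel(id=path.stem, residues=residues)


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as standard fixed-width ATOM records (single chain A)."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    serial = 1
    with open(path, "w") as fh:
        for i, res in enumerate(model.residues, start=1):
            for atom in BACKBONE_ATOMS:
                if atom not in res.atoms:
                    continue
                x, y, z = res.atoms[atom]
                name = atom if len(atom) >= 4 else f" {atom}"
                fh.write(_ATOM_FMT.format(
                    serial=serial, name=name, altloc=" ", resname=res.name,
                    chain="A", resseq=res.index or i, icode=" ",
                    x=x, y=y, z=z, occ=1.0, b=0.0, element=atom[0],
                ))
                serial += 1
        fh.write("TER\nEND\n")


def load_score_table(path: str | Path) -> pd.DataFrame:
    """Load an externally computed per-model score table.

    CSV with a header row: a ``model_id`` column plus one or more numeric
    term columns (term names are preserved verbatim).  Returns a DataFrame
    indexed by model_id.
    """
    df = pd.read_csv(path)
    if "model_id" not in df.columns:
        raise ValueError(f"{path}: score table must have a 'model_id' header column")
    if df["model_id"].duplicated().any():
        dups = df.loc[df["model_id"].duplicated(), "model_id"].tolist()
        raise ValueError(f"{path}: duplicate model_id entries: {dups}")
    if len(df.columns) < 2:
        raise ValueError(f"{path}: no term columns")
    terms = [c for c in df.columns if c != "model_id"]
    for col in terms:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in term column {col!r}") from exc
    return df.set_index("model_id")
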
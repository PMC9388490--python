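"""Structural model containers and file I/O.

A *target* is a protein sequence whose native structure is sought; each
target has a pool of computationally generated structural models (decoys).
This module defines the in-memory containers for residues, models and
per-target model sets, plus readers/writers for the artifacts the pipeline
exchanges: PDB models, FASTA target sequences and tab-separated feature
tables.

Residue correspondence between a model and its target sequence is
positional: the PDB residue number is interpreted as the 1-based index
into the target sequence (the convention of CASP server models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class PDBFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class MappingError(ValueError):
    """Raised when no residue of a model maps onto the target sequence."""


@dataclass
class Residue:
    """One residue of a structural model.

    ``seq_position`` is the 1-based position in the target sequence;
    ``atoms`` holds ``(atom_name, element, xyz)`` triples with coordinates
    in Angstrom; ``ca_xyz`` is the alpha-carbon position, or ``None`` when
    the residue was modeled without a CA atom.
    """

    seq_position: int
    aa_type: str
    atoms: list = field(default_factory=list)
    ca_xyz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.seq_position < 1:
            raise ValueError(f"seq_position must be >= 1, got {self.seq_position}")
        if self.ca_xyz is not None:
            self.ca_xyz = np.asarray(self.ca_xyz, dtype=float)
            if not np.all(np.isfinite(self.ca_xyz)) or self.ca_xyz.shape != (3,):
                raise ValueError("ca_xyz must be a finite 3-vector")


@dataclass
class ModelStructure:
    """An ordered single-chain structural model of one target."""

    model_id: str
    target_id: str
    residues: list  # list[Residue], sorted by seq_position, no duplicates

    def __post_init__(self) -> None:
        positions = [r.seq_position for r in self.residues]
        if sorted(set(positions)) != positions:
            raise ValueError("residues must be strictly increasing in seq_position")
        if sum(1 for r in self.residues if r.ca_xyz is not None) < 3:
            raise ValueError(
                f"model {self.model_id!r} has fewer than 3 CA atoms; "
                "superposition is impossible"
            )
        self._ca_cache = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(positions, coords)`` for residues that carry a CA atom.

        ``positions`` is an int array of 1-based sequence positions and
        ``coords`` the matching ``(n, 3)`` float array, both cached.
        """
        if self._ca_cache is None:
            pos, xyz = [], []
            for r in self.residues:
                if r.ca_xyz is not None:
                    pos.append(r.seq_position)
                    xyz.append(r.ca_xyz)
            self._ca_cache = (
                np.asarray(pos, dtype=np.int64),
                np.asarray(xyz, dtype=np.float64).reshape(-1, 3),
            )
        return self._ca_cache

    def carbon_atoms(self) -> tuple[np.ndarray, np.ndarray, list]:
        """All carbon atoms as ``(residue_index, coords, names)``."""
        idx, xyz, names = [], [], []
        for i, r in enumerate(self.residues):
            for name, element, coord in r.atoms:
                if element == "C":
                    idx.append(i)
                    xyz.append(coord)
                    names.append(name)
        return (
            np.asarray(idx, dtype=np.int64),
            np.asarray(xyz, dtype=np.float64).reshape(-1, 3),
            names,
        )


@dataclass
class TargetSet:
    """A target sequence, its model pool and (optionally) native structure.

    ``filtered_flag`` marks targets excluded from every *training* fold of
    cross-validation; flagged targets are still evaluated as test folds.
    """

    target_id: str
    sequence: str
    models: list  # list[ModelStructure], non-empty
    native: Optional[ModelStructure] = None
    filtered_flag: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("TargetSet requires at least one model")
        for m in self.models:
            if m.target_id != self.target_id:
                raise ValueError(
                    f"model {m.model_id!r} belongs to {m.target_id!r}, "
                    f"not {self.target_id!r}"
                )
            last = m.residues[-1].seq_position if m.residues else 0
            if last > len(self.sequence):
                raise ValueError(
                    f"model {m.model_id!r} extends past the target sequence"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)


def read_pdb_model(
    path,
    target_sequence: str,
    model_id: Optional[str] = None,
    target_id: str = "",
) -> ModelStructure:
    """Parse a single-chain PDB model and map it onto the target sequence.

    The first chain of the first model is used; alternate locations other
    than blank/'A' are dropped; insertion codes are rejected.  Residues
    whose number falls outside ``[1, len(target_sequence)]`` are dropped
    with a warning; if none remain, a :class:`MappingError` is raised.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise PDBFormatError(f"{path} contains no chains")
    chain = st[0][0]
    n_target = len(target_sequence)
    residues = []
    for res in chain:
        if res.seqid.icode not in (" ", "\0", ""):
            raise PDBFormatError(
                f"{path}: insertion code {res.seqid.icode!r} at residue "
                f"{res.seqid.num} is not supported"
            )
        pos = res.seqid.num
        if pos < 1 or pos > n_target:
            logger.warning(
                "%s: residue %d outside target range [1, %d]; dropped",
                path.name, pos, n_target,
            )
            continue
        aa = AA3_TO_1.get(res.name, "X")
        if aa != "X" and aa != target_sequence[pos - 1]:
            logger.warning(
                "%s: residue %d is %s in the model but %s in the sequence",
                path.name, pos, aa, target_sequence[pos - 1],
            )
        atoms = []
        ca = None
        for atom in res:
            if atom.altloc not in ("", "\0", "A"):
                continue
            coord = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            atoms.append((atom.name, atom.element.name, coord))
            if atom.name == "CA" and atom.element.name == "C":
                ca = coord
        if atoms:
            residues.append(Residue(pos, aa, atoms, ca))
    if not residues:
        raise MappingError(
            f"{path}: no residue maps within [1, {n_target}] of the target"
        )
    residues.sort(key=lambda r: r.seq_position)
    return ModelStructure(
        model_id=model_id or path.stem, target_id=target_id, residues=residues
    )


def read_fasta_target(path) -> tuple[str, str]:
    """Read a single-record FASTA; returns ``(target_id, sequence)``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected a single FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper().replace(" ", "")
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"{path}: non-amino-acid characters {sorted(bad)}")
    return rec.id, seq


def write_fasta_target(target_id: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{target_id}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def write_pdb_model(model: ModelStructure, sequence: str, path) -> None:
    """Write a model as a standard single-chain PDB file (ATOM records)."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in model.residues:
        gr = gemmi.Residue()
        gr.name = AA1_TO_3.get(r.aa_type, "ALA")
        gr.seqid = gemmi.SeqId(r.seq_position, " ")
        gr.het_flag = "A"
        for name, element, coord in r.atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.occ = 1.0
            at.pos = gemmi.Position(*coord)
            gr.add_atom(at)
        chain.add_residue(gr)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Feature tables
#
# A feature table is a pandas DataFrame indexed by (target_id, model_id)
# with named numeric columns; the observed label column, when present, is
# named LABEL_COLUMN and lies in [0, 1].

LABEL_COLUMN = "observed_gdt_ts"
INDEX_NAMES = ("target_id", "model_id")


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.shape[1] == 0:
        raise ValueError("feature table has no columns")
    if table.index.nlevels != 2:
        raise ValueError("feature table index must be (target_id, model_id)")
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate (target_id, model_id) keys: {dups[:5]}")
    if table.columns.duplicated().any():
        raise ValueError("duplicate column names in feature table")
    if LABEL_COLUMN in table.columns:
        lab = table[LABEL_COLUMN]
        if (lab < 0).any() or (lab > 1).any():
            raise ValueError(f"{LABEL_COLUMN} must lie in [0, 1]")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    validate_feature_table(table)
    table.reset_index().to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    for name in INDEX_NAMES:
        if name not in df.columns:
            raise ValueError(f"{path}: missing key column {name!r}")
    df = df.set_index(list(INDEX_NAMES))
    return validate_feature_table(df)
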
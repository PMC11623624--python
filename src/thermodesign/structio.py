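"""Structure and sequence I/O.

Reads PDB/mmCIF files into lightweight backbone-centric records, writes them
back, and handles FASTA. Residues are renumbered to contiguous 1-based
numbering per chain on load (original author numbering is kept as metadata);
alternate locations keep the highest-occupancy conformer and insertion codes
are collapsed by the renumbering. Per-residue confidence (pLDDT, 0-100) is
taken from the B-factor column, but only when the caller declares the model
``source="predicted"`` — it is never guessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.sequence.io.fasta import FastaFile
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20-letter order used throughout

_BACKBONE = ("N", "CA", "C", "O")

# Ideal CB direction in the local backbone frame (b = CA-N, c = C-CA, a = b x c),
# normalised to a 1.52 A bond from CA.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)
CB_BOND_LENGTH = 1.52


class StructureError(ValueError):
    """Malformed structure content (parse failure, missing atoms, bad chain)."""


@dataclass
class ResidueRecord:
    """One standard amino-acid residue with backbone (and optional side-chain)
    coordinates in Angstrom."""

    aa: str
    resnum: int
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    o_xyz: np.ndarray
    cb_xyz: np.ndarray | None = None
    sidechain_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    confidence: float | None = None
    orig_resnum: int | None = None

    def backbone(self) -> np.ndarray:
        """(4, 3) array of N, CA, C, O coordinates."""
        return np.stack([self.n_xyz, self.ca_xyz, self.c_xyz, self.o_xyz])

    def heavy_atoms(self) -> dict[str, np.ndarray]:
        atoms = {"N": self.n_xyz, "CA": self.ca_xyz, "C": self.c_xyz, "O": self.o_xyz}
        if self.cb_xyz is not None:
            atoms["CB"] = self.cb_xyz
        atoms.update(self.sidechain_atoms)
        return atoms


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRecord]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class BackboneStructure:
    """A (possibly multi-chain) protein structure reduced to the records the
    pipeline needs: backbone frames, sequence, confidence, charged side chains."""

    id: str
    chains: list[ChainRecord]
    source: str = "experimental"  # "experimental" | "predicted"

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def sequence(self) -> str:
        return "".join(c.sequence for c in self.chains)

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def residues(self) -> Iterable[tuple[str, ResidueRecord]]:
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def mean_confidence(self) -> float:
        vals = [r.confidence for _, r in self.residues()]
        if any(v is None for v in vals):
            raise StructureError(f"structure {self.id!r} has residues without confidence")
        return float(np.mean(vals))

    def validate(self) -> None:
        """Raise :class:`StructureError` on any invariant violation."""
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain identifiers in {self.id!r}: {ids}")
        for chain in self.chains:
            prev = None
            for res in chain.residues:
                if res.aa not in AA1_TO_3:
                    raise StructureError(
                        f"{self.id}/{chain.chain_id}{res.resnum}: non-standard letter {res.aa!r}")
                for name, xyz in (("N", res.n_xyz), ("CA", res.ca_xyz),
                                  ("C", res.c_xyz), ("O", res.o_xyz)):
                    if xyz is None or not np.all(np.isfinite(xyz)):
                        raise StructureError(
                            f"{self.id}/{chain.chain_id}{res.resnum}: non-finite {name}")
                if prev is not None and res.resnum <= prev:
                    raise StructureError(
                        f"{self.id}/{chain.chain_id}: residue numbers not increasing "
                        f"({prev} -> {res.resnum})")
                prev = res.resnum
                if self.source == "predicted" and res.confidence is None:
                    raise StructureError(
                        f"{self.id}/{chain.chain_id}{res.resnum}: predicted model "
                        "without per-residue confidence")


def infer_cb(residue: ResidueRecord) -> np.ndarray:
    """Ideal CB position from the backbone frame.

    Returns the residue's own CB when present. Otherwise places a virtual CB
    at tetrahedral geometry, 1.52 A from CA, in the L-amino-acid orientation —
    needed because glycine has no CB yet interface detection is CB-based.
    """
    if residue.cb_xyz is not None:
        return residue.cb_xyz
    for name, xyz in (("N", residue.n_xyz), ("CA", residue.ca_xyz), ("C", residue.c_xyz)):
        if xyz is None or not np.all(np.isfinite(np.asarray(xyz, dtype=float))):
            raise StructureError(
                f"cannot infer CB for residue {residue.aa}{residue.resnum}: missing {name}")
    b = residue.ca_xyz - residue.n_xyz
    c = residue.c_xyz - residue.ca_xyz
    a = np.cross(b, c)
    direction = _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * c
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise StructureError(
            f"degenerate backbone frame at residue {residue.aa}{residue.resnum}")
    return residue.ca_xyz + CB_BOND_LENGTH * direction / norm


# ---------------------------------------------------------------------------
# reading


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto", source: str = "experimental",
                   id: str | None = None) -> BackboneStructure:
    """Read a PDB or mmCIF file into a :class:`BackboneStructure`.

    Non-standard residues are skipped with a logged warning; chains left with
    fewer than 2 standard residues are rejected with a diagnostic. B-factors
    are interpreted as pLDDT confidence only when ``source="predicted"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            pdb_file = PDBFile.read(str(path))
            atoms = pdb_file.get_structure(
                model=1, altloc="occupancy", extra_fields=["b_factor"])
        elif fmt == "mmcif":
            cif_file = CIFFile.read(str(path))
            atoms = cif_get_structure(
                cif_file, model=1, altloc="occupancy", extra_fields=["b_factor"])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except Exception as exc:  # biotite raises various parse errors
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return structure_from_atoms(
        atoms, id=id or path.stem, source=source)


def structure_from_atoms(atoms: struc.AtomArray, id: str,
                         source: str = "experimental") -> BackboneStructure:
    """Convert a biotite AtomArray (single model) into backbone records."""
    atoms = atoms[~atoms.hetero]
    chains: list[ChainRecord] = []
    for chain_id in np.unique(atoms.chain_id):
        chain_atoms = atoms[atoms.chain_id == chain_id]
        residues: list[ResidueRecord] = []
        res_starts = struc.get_residue_starts(chain_atoms)
        for i, start in enumerate(res_starts):
            stop = res_starts[i + 1] if i + 1 < len(res_starts) else len(chain_atoms)
            res_atoms = chain_atoms[start:stop]
            res_name = res_atoms.res_name[0]
            orig_resnum = int(res_atoms.res_id[0])
            if res_name not in AA3_TO_1:
                logger.warning("%s/%s %s%d: skipping non-standard residue",
                               id, chain_id, res_name, orig_resnum)
                continue
            coords = {}
            side = {}
            for atom, xyz in zip(res_atoms, res_atoms.coord):
                name = atom.atom_name
                if name in _BACKBONE:
                    coords[name] = np.asarray(xyz, dtype=float)
                elif name == "CB":
                    coords["CB"] = np.asarray(xyz, dtype=float)
                elif not name.startswith("H"):
                    side[name] = np.asarray(xyz, dtype=float)
            if any(k not in coords for k in _BACKBONE):
                missing = [k for k in _BACKBONE if k not in coords]
                logger.warning("%s/%s %s%d: skipping residue with missing backbone %s",
                               id, chain_id, res_name, orig_resnum, missing)
                continue
            confidence = float(res_atoms.b_factor.mean()) if source == "predicted" else None
            residues.append(ResidueRecord(
                aa=AA3_TO_1[res_name],
                resnum=len(residues) + 1,
                n_xyz=coords["N"], ca_xyz=coords["CA"],
                c_xyz=coords["C"], o_xyz=coords["O"],
                cb_xyz=coords.get("CB"),
                sidechain_atoms=side,
                confidence=confidence,
                orig_resnum=orig_resnum,
            ))
        if len(residues) < 2:
            logger.warning("rejecting chain %s of %s: only %d standard residues",
                           chain_id, id, len(residues))
            continue
        chains.append(ChainRecord(chain_id=str(chain_id), residues=residues))
    if not chains:
        raise StructureError(f"structure {id!r}: no chain with >= 2 standard residues")
    structure = BackboneStructure(id=id, chains=chains, source=source)
    structure.validate()
    return structure


# ---------------------------------------------------------------------------
# writing


def structure_to_atoms(structure: BackboneStructure) -> struc.AtomArray:
    atoms = []
    for chain in structure.chains:
        for res in chain.residues:
            named = [("N", res.n_xyz), ("CA", res.ca_xyz), ("C", res.c_xyz),
                     ("O", res.o_xyz)]
            if res.cb_xyz is not None:
                named.append(("CB", res.cb_xyz))
            named.extend(sorted(res.sidechain_atoms.items()))
            for name, xyz in named:
                atom = struc.Atom(
                    np.asarray(xyz, dtype=np.float32),
                    chain_id=chain.chain_id,
                    res_id=res.resnum,
                    res_name=AA1_TO_3[res.aa],
                    atom_name=name,
                    element=name[0],
                    hetero=False,
                )
                atoms.append(atom)
    arr = struc.array(atoms)
    b = []
    for chain in structure.chains:
        for res in chain.residues:
            n_atoms = 4 + (res.cb_xyz is not None) + len(res.sidechain_atoms)
            b.extend([res.confidence if res.confidence is not None else 0.0] * n_atoms)
    arr.set_annotation("b_factor", np.asarray(b, dtype=float))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return arr


def write_structure(structure: BackboneStructure, path) -> None:
    """Write to PDB (or mmCIF when the suffix says so). Coordinates survive a
    round trip to within format precision (1e-3 A for PDB)."""
    path = Path(path)
    arr = structure_to_atoms(structure)
    if path.suffix.lower() in (".cif", ".mmcif"):
        from biotite.structure.io.pdbx import set_structure as cif_set_structure
        cif_file = CIFFile()
        cif_set_structure(cif_file, arr, data_block=structure.id)
        cif_file.write(str(path))
    else:
        pdb_file = PDBFile()
        pdb_file.set_structure(arr)
        pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Sequence[tuple[str, str]], path, chars_per_line: int = 60) -> None:
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    fasta = FastaFile(chars_per_line=chars_per_line)
    for rid, sequence in records:
        fasta[rid] = str(sequence)
    fasta.write(str(path))


def read_fasta(path) -> list[tuple[str, str]]:
    fasta = FastaFile.read(str(path))
    return [(rid, str(sequence)) for rid, sequence in fasta.items()]


def validate_sequence(sequence: str) -> str:
    """Return the sequence if it is non-empty and within the 20-letter
    alphabet; otherwise raise listing the offending symbols."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted({c for c in sequence if c not in ALPHABET})
    if bad:
        raise ValueError(f"non-standard letters in sequence: {bad}")
    return sequence
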
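"""Protein structure input, motif resolution and functional-atom selection.

A *motif* is an ordered set of 3-5 catalytic residues (CSA style:
chain / author residue number / residue type).  Each residue is reduced to
a single *functional atom* -- the side-chain (or backbone) atom taken to
represent it in all distance and electrostatic-potential calculations,
e.g. Ser OG, His NE2, Asp OD1, Gly backbone N.

Parsing goes through Biopython's PDB parser; only the first model is kept,
and for alternate locations the highest-occupancy conformer wins (ties
break to altloc 'A') so that downstream geometry is single-conformer and
deterministic.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import MissingAtomError, MotifResolutionError, ParseError

STANDARD_AAS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Default representative ("reactive") atom per residue type.  Polar side
#: chains use their canonical interaction atom; hydrophobics and glycine
#: fall back to the backbone nitrogen.
DEFAULT_FUNCTIONAL_ATOMS: Mapping[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("NE2",),
    "ASP": ("OD1",),
    "GLU": ("OE1",),
    "ASN": ("OD1",),
    "GLN": ("NE2",),
    "CYS": ("SG",),
    "LYS": ("NZ",),
    "ARG": ("NH1",),
    "TRP": ("NE1",),
    "MET": ("SD",),
    "GLY": ("N",),
    "ALA": ("N",),
    "VAL": ("N",),
    "LEU": ("N",),
    "ILE": ("N",),
    "PHE": ("N",),
    "PRO": ("N",),
}

#: Chemically symmetric side-chain atom pairs (carboxylate / amide termini).
SYMMETRIC_ALTERNATES: Mapping[str, Mapping[str, str]] = {
    "ASP": {"OD1": "OD2"},
    "GLU": {"OE1": "OE2"},
    "ASN": {"OD1": "ND2"},
    "GLN": {"NE2": "OE1"},
}


@dataclass(frozen=True)
class Atom:
    """A single atom with author identifiers and Cartesian coordinates (A)."""

    chain_id: str
    res_seq: int
    icode: str
    res_type: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.label} has non-finite position")
        object.__setattr__(self, "position", pos)

    @property
    def label(self) -> str:
        """Table-style concatenated label, e.g. ``GLY38N``."""
        return f"{self.res_type}{self.res_seq}{self.icode.strip()}{self.atom_name}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.res_seq == other.res_seq
            and self.icode == other.icode
            and self.res_type == other.res_type
            and self.atom_name == other.atom_name
            and np.allclose(self.position, other.position)
        )

    def __hash__(self) -> int:
        return hash((self.chain_id, self.res_seq, self.icode, self.atom_name))


@dataclass(frozen=True)
class Residue:
    chain_id: str
    res_seq: int
    icode: str
    res_type: str
    atoms: tuple[Atom, ...]
    is_hetatm: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_type in STANDARD_AAS and not self.is_hetatm

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Residue({self.res_type}{self.res_seq}{self.icode.strip()}:{self.chain_id})"


@dataclass
class Structure:
    """A parsed protein: ordered residues of the first model, in file order."""

    structure_id: str
    residues: list[Residue]
    source: str = "<stream>"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"structure {self.structure_id!r} contains no residues")

    def searchable_residues(self, chain_id: Optional[str] = None) -> list[Residue]:
        """Standard amino-acid residues, optionally restricted to one chain."""
        out = [r for r in self.residues if r.is_standard]
        if chain_id is not None:
            out = [r for r in out if r.chain_id == chain_id]
        return out

    def find(self, chain_id: str, res_seq: int, icode: str = " ") -> Optional[Residue]:
        for r in self.residues:
            if r.key == (chain_id, res_seq, icode):
                return r
        return None


@dataclass
class FunctionalAtomTable:
    """Residue type -> ordered preference list of representative atom names."""

    table: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONAL_ATOMS)
    )

    def atom_names(self, res_type: str) -> tuple[str, ...]:
        try:
            return tuple(self.table[res_type])
        except KeyError:
            raise MissingAtomError(f"no functional-atom entry for residue type {res_type!r}")


@dataclass
class Motif:
    """Ordered catalytic residues (3-5, one chain) resolved in a structure."""

    structure_id: str
    residues: tuple[Residue, ...]
    groups: Optional[tuple] = None  # parallel tuple of StereoGroup or None

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id

    @property
    def residue_keys(self) -> frozenset:
        return frozenset(r.key for r in self.residues)


def _select_altloc(bio_atom):
    """Highest-occupancy conformer; ties break to the smallest altloc id."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def load_structure(pdb_text: str, structure_id: str = "STRUCT", source: str = "<stream>") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Keeps the first model only.  HETATM residues are retained (flagged,
    excluded from motif search).  Raises :class:`ParseError` for empty
    input, input without ATOM/HETATM records, or malformed records.
    """
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise ParseError("no ATOM records in input")
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise ParseError(f"malformed PDB record: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"malformed PDB field: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise ParseError("no ATOM records in input")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, res_seq, icode = res.get_id()
            atoms = []
            seen = set()
            for bio_atom in res:
                sel = _select_altloc(bio_atom)
                name = sel.get_name()
                if name in seen:
                    continue
                seen.add(name)
                atoms.append(
                    Atom(
                        chain_id=chain.id,
                        res_seq=res_seq,
                        icode=icode,
                        res_type=res.get_resname().strip(),
                        atom_name=name,
                        position=np.array(sel.get_coord(), dtype=float),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.id,
                        res_seq=res_seq,
                        icode=icode,
                        res_type=res.get_resname().strip(),
                        atoms=tuple(atoms),
                        is_hetatm=hetflag.strip() != "",
                    )
                )
    return Structure(structure_id=structure_id, residues=residues, source=source)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (fixed-column ATOM records)."""
    lines = []
    serial = 1
    for res in structure.residues:
        record = "HETATM" if res.is_hetatm else "ATOM  "
        for atom in res.atoms:
            name = atom.atom_name
            # PDB atom-name alignment: <4-char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.position
            lines.append(
                f"{record}{serial:5d} {padded:<4s} {res.res_type:<3s} {res.chain_id}"
                f"{res.res_seq:4d}{res.icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def resolve_motif(
    structure: Structure,
    spec: Sequence[tuple[str, int, str]],
    groups: Optional[Sequence] = None,
) -> Motif:
    """Resolve (chain, res_seq, res_type) entries against a structure.

    Enforces the motif validity rules: 3-5 residues, all on one chain,
    residue types matching the structure.
    """
    n = len(spec)
    if not 3 <= n <= 5:
        raise MotifResolutionError(f"motif must have 3-5 residues, got {n}")
    chains = {chain for chain, _, _ in spec}
    if len(chains) != 1:
        raise MotifResolutionError(
            f"motif must be confined to one polypeptide chain, got chains {sorted(chains)}"
        )
    if groups is not None and len(groups) != n:
        raise MotifResolutionError("groups, when given, must parallel the motif positions")

    missing, mismatched, resolved = [], [], []
    for chain, res_seq, res_type in spec:
        res = structure.find(chain, int(res_seq))
        if res is None:
            missing.append(f"{chain}:{res_type}:{res_seq}")
            continue
        if res.res_type != res_type.upper():
            mismatched.append(
                f"{chain}:{res_seq} is {res.res_type}, spec says {res_type.upper()}"
            )
            continue
        resolved.append(res)
    if missing:
        raise MotifResolutionError(f"motif residues not found: {', '.join(missing)}")
    if mismatched:
        raise MotifResolutionError(f"residue type mismatch: {'; '.join(mismatched)}")
    if len({r.key for r in resolved}) != n:
        raise MotifResolutionError("motif spec resolves to duplicate residues")
    return Motif(
        structure_id=structure.structure_id,
        residues=tuple(resolved),
        groups=tuple(groups) if groups is not None else None,
    )


def functional_atom(residue: Residue, table: Optional[FunctionalAtomTable] = None) -> Atom:
    """First available atom from the residue type's preference list."""
    table = table or FunctionalAtomTable()
    names = table.atom_names(residue.res_type)
    for name in names:
        atom = residue.atom(name)
        if atom is not None:
            return atom
    raise MissingAtomError(
        f"{residue.res_type}{residue.res_seq}:{residue.chain_id} lacks functional "
        f"atom(s) {'/'.join(names)} (truncated side chain?)"
    )


def parse_motif_string(text: str) -> list[tuple[str, int, str]]:
    """Parse ``"A:GLY:38,A:ASN:101,A:GLU:59"`` into motif spec triples."""
    spec = []
    for part in text.split(","):
        fields = part.strip().split(":")
        if len(fields) != 3:
            raise ParseError(f"bad motif entry {part!r}, expected CHAIN:RES:SEQ")
        chain, res_type, seq = fields
        try:
            spec.append((chain.strip(), int(seq), res_type.strip().upper()))
        except ValueError:
            raise ParseError(f"bad residue number in motif entry {part!r}")
    return spec


def parse_motif_csv(text: str, structure_id: Optional[str] = None) -> list[tuple[str, int, str]]:
    """CSA-style CSV (pdb_id, chain, res_type, res_seq per row) -> spec triples.

    When *structure_id* is given only matching rows are used.
    """
    spec = []
    reader = csv.reader(io.StringIO(text))
    for row in reader:
        if not row or row[0].strip().lower() in ("pdb_id", "pdb"):
            continue
        if len(row) < 4:
            raise ParseError(f"bad motif CSV row {row!r}")
        pdb_id, chain, res_type, seq = (f.strip() for f in row[:4])
        if structure_id is not None and pdb_id.upper() != structure_id.upper():
            continue
        try:
            spec.append((chain, int(seq), res_type.upper()))
        except ValueError:
            raise ParseError(f"bad residue number in motif CSV row {row!r}")
    if not spec:
        raise ParseError("motif CSV contained no usable rows")
    return spec
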
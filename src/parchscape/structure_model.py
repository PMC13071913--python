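"""Hierarchical structure model and legacy-PDB I/O.

The model is deliberately small: atoms with names, elements and
coordinates, grouped into residues keyed by ``(chain_id, seq_id,
icode)``, grouped into a :class:`Structure`.  Residue *kind* (protein,
DNA, water, ion) is a pure function of the residue name, driven by the
name tables below.

Two dialects are written:

* plain legacy PDB (``ATOM``/``HETATM``/``TER``/``END``);
* the hydropathy-annotated dialect, where every atom line carries the
  residue's PARCH value in a fixed-width ``%8.2f`` field appended after
  the element column (columns 81-88).  The annotated PDB is a
  convenience for molecular viewers; the authoritative machine-readable
  artifact is the sidecar TSV written by :meth:`PVTable.to_tsv`.

DNA atoms are partitioned into the sugar-phosphate backbone (BB) and the
nucleobase (NB).  Sugar atoms, including the C1' bridge to the base,
belong to BB so that NB is exactly the base ring plus its exocyclic
substituents.  Hydrogens are excluded from partitions and from every
distance computation by default (crystal structures rarely resolve
them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import numpy as np

from .errors import GeometryError, ParseError, PartitionError

__all__ = [
    "Atom",
    "Residue",
    "ResidueKind",
    "Moiety",
    "Structure",
    "ResidueKey",
    "residue_kind",
    "parse_pdb",
    "read_parch_pdb",
    "write_pdb",
    "write_parch_pdb",
    "partition_dna_atoms",
    "center_of_geometry",
    "BACKBONE_ATOMS",
    "NUCLEOBASE_ATOMS",
]

ResidueKey = tuple[str, int, str]


class ResidueKind(Enum):
    PROTEIN = "PROTEIN"
    DNA = "DNA"
    WATER = "WATER"
    ION = "ION"
    OTHER = "OTHER"


class Moiety(str, Enum):
    """Scoring group of a residue: whole protein residue, DNA backbone, or nucleobase."""

    PROT = "PROT"
    BB = "BB"
    NB = "NB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


AMINO_ACIDS: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

#: residue-name aliases mapped onto the canonical template name
DNA_ALIASES: dict[str, str] = {
    "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT", "DI": "DI",
    "5CM": "5CM",
    # the methylated-cytosine label used by some pipelines
    "FMC": "5CM",
    # legacy single-letter deoxynucleotide names
    "A": "DA", "C": "DC", "G": "DG", "T": "DT",
}

WATER_NAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"}
ION_NAMES = {
    "NA", "CL", "K", "MG", "ZN", "MN", "FE", "CA", "CS", "LI", "BR",
    "IOD", "SOD", "CLA", "POT",
}


def residue_kind(name: str) -> ResidueKind:
    """Residue kind from the residue name alone (table-driven)."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return ResidueKind.PROTEIN
    if name in DNA_ALIASES:
        return ResidueKind.DNA
    if name in WATER_NAMES:
        return ResidueKind.WATER
    if name in ION_NAMES:
        return ResidueKind.ION
    return ResidueKind.OTHER


# ---------------------------------------------------------------------------
# DNA backbone / nucleobase partition templates
# ---------------------------------------------------------------------------

#: sugar-phosphate backbone heavy atoms shared by all deoxynucleotides
BACKBONE_ATOMS: frozenset[str] = frozenset(
    {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}
)

_PYRIMIDINE_RING = {"N1", "C2", "N3", "C4", "C5", "C6"}
_PURINE_RING = _PYRIMIDINE_RING | {"N7", "C8", "N9"}

#: nucleobase heavy atoms per canonical residue name (base ring + substituents)
NUCLEOBASE_ATOMS: dict[str, frozenset[str]] = {
    "DA": frozenset(_PURINE_RING | {"N6"}),
    "DG": frozenset(_PURINE_RING | {"O6", "N2"}),
    "DI": frozenset(_PURINE_RING | {"O6"}),
    "DC": frozenset(_PYRIMIDINE_RING | {"O2", "N4"}),
    "DT": frozenset(_PYRIMIDINE_RING | {"O2", "O4", "C7"}),
    "5CM": frozenset(_PYRIMIDINE_RING | {"O2", "N4", "C5M"}),
}

#: legacy atom-name spellings normalized before template lookup
_ATOM_NAME_ALIASES = {
    "O1P": "OP1",
    "O2P": "OP2",
    "C5A": "C5M",  # alternative methyl-carbon name for 5-methylcytosine
    "C7M": "C5M",
}

#: terminal/capping atoms silently kept with the backbone when present
_BACKBONE_EXTRAS = {"OP3", "O3T", "HO3'", "HO5'"}


def normalize_atom_name(name: str) -> str:
    name = name.strip().upper().replace("*", "'")
    return _ATOM_NAME_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Core dataclasses
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    serial: int = 0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    kind: ResidueKind | None = None

    def __post_init__(self) -> None:
        if self.kind is None:
            self.kind = residue_kind(self.name)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.icode)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coord_array(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])

    def get_atom(self, name: str) -> Atom | None:
        name = normalize_atom_name(name)
        for a in self.atoms:
            if normalize_atom_name(a.name) == name:
                return a
        return None


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    unit_labels: dict[ResidueKey, int] | None = None
    title: str = ""

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residues_of_kind(self, kind: ResidueKind) -> list[Residue]:
        return [r for r in self.residues if r.kind is kind]

    def protein_residues(self) -> list[Residue]:
        return self.residues_of_kind(ResidueKind.PROTEIN)

    def dna_residues(self) -> list[Residue]:
        return self.residues_of_kind(ResidueKind.DNA)

    def get(self, key: ResidueKey) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def heavy_coords(self, kinds: Iterable[ResidueKind] | None = None) -> np.ndarray:
        kinds = set(kinds) if kinds is not None else None
        blocks = [
            r.coord_array()
            for r in self.residues
            if (kinds is None or r.kind in kinds) and r.heavy_atoms()
        ]
        if not blocks:
            return np.empty((0, 3))
        return np.vstack(blocks)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def center_of_geometry(atoms: Iterable[Atom] | np.ndarray) -> np.ndarray:
    """Unweighted mean coordinate of a non-empty atom set."""
    if isinstance(atoms, np.ndarray):
        coords = atoms
    else:
        coords = np.array([a.coords for a in atoms])
    if coords.size == 0:
        raise GeometryError("center of geometry of an empty atom set is undefined")
    return coords.reshape(-1, 3).mean(axis=0)


def partition_dna_atoms(
    residue: Residue, include_hydrogens: bool = False
) -> tuple[set[str], set[str]]:
    """Split a DNA residue's atoms into backbone and nucleobase name sets.

    Atoms absent from the residue (5'-terminal phosphates and the like)
    are silently skipped; an atom name matching no template entry raises
    :class:`PartitionError`.
    """
    if residue.kind is not ResidueKind.DNA:
        raise PartitionError(
            f"residue {residue.name} {residue.key} is not DNA; cannot partition"
        )
    canonical = DNA_ALIASES.get(residue.name.strip().upper())
    nb_template = NUCLEOBASE_ATOMS.get(canonical or "")
    if nb_template is None:
        raise PartitionError(f"no nucleobase template for residue name {residue.name!r}")
    bb: set[str] = set()
    nb: set[str] = set()
    for atom in residue.atoms:
        if atom.is_hydrogen and not include_hydrogens:
            continue
        name = normalize_atom_name(atom.name)
        if name in BACKBONE_ATOMS or name in _BACKBONE_EXTRAS:
            bb.add(name)
        elif name in nb_template:
            nb.add(name)
        elif atom.is_hydrogen:
            # hydrogens, when requested, follow the sugar/base split of
            # their name: primed hydrogens sit on the sugar
            (bb if "'" in name else nb).add(name)
        else:
            raise PartitionError(
                f"atom {atom.name!r} of residue {residue.name} {residue.key} "
                "matches no backbone or nucleobase template entry"
            )
    return bb, nb


def moiety_atoms(residue: Residue, moiety: Moiety) -> list[Atom]:
    """Heavy atoms of a residue belonging to the given scoring group."""
    if moiety is Moiety.PROT:
        return residue.heavy_atoms()
    bb, nb = partition_dna_atoms(residue)
    wanted = bb if moiety is Moiety.BB else nb
    return [
        a for a in residue.heavy_atoms() if normalize_atom_name(a.name) in wanted
    ]


# ---------------------------------------------------------------------------
# Legacy-PDB reading
# ---------------------------------------------------------------------------


def _infer_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse(text: str, collect_pv: bool):
    if not text.strip():
        raise ParseError("empty input: no ATOM/HETATM records")
    residues: list[Residue] = []
    index: dict[ResidueKey, Residue] = {}
    # per (residue, atom name): list of (alt_loc, occupancy, Atom)
    alt_candidates: dict[tuple[ResidueKey, str], list[tuple[str, float, Atom]]] = {}
    pv_atoms: dict[tuple[ResidueKey, str], float] = {}
    title = ""
    models_seen = 0
    in_skipped_model = False
    n_atom_records = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
            continue
        if record.startswith("MODEL"):
            models_seen += 1
            if models_seen > 1:
                in_skipped_model = True
            continue
        if record.startswith("ENDMDL"):
            continue
        if not (record.startswith("ATOM") or record.startswith("HETATM")):
            continue
        if in_skipped_model:
            continue
        n_atom_records += 1
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = n_atom_records
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip() or line[17:21].strip()
        chain_id = line[21].strip()
        try:
            seq_id = int(line[22:26])
        except ValueError as exc:
            raise ParseError(f"bad residue sequence number {line[22:26]!r}", lineno) from exc
        icode = line[26].strip()
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"malformed coordinate fields {line[30:54]!r}", lineno) from exc
        try:
            occupancy = float(line[54:60])
        except (ValueError, IndexError):
            occupancy = 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name)
        pv: float | None = None
        if collect_pv and len(line) > 80:
            tail = line[80:89].strip()
            if tail:
                try:
                    pv = float(tail)
                except ValueError:
                    pv = None
        try:
            atom = Atom(name=name, element=element, coords=(x, y, z),
                        serial=serial, alt_loc=alt_loc)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc

        key: ResidueKey = (chain_id, seq_id, icode)
        if key not in index:
            res = Residue(chain_id=chain_id, seq_id=seq_id, icode=icode, name=res_name)
            index[key] = res
            residues.append(res)
        alt_candidates.setdefault((key, name), []).append((alt_loc, occupancy, atom))
        if pv is not None:
            pv_atoms[(key, name)] = pv

    if n_atom_records == 0:
        raise ParseError("no ATOM/HETATM records found")
    if models_seen > 1:
        warnings.warn(
            f"multi-model file: kept model 1 of {models_seen}", stacklevel=3
        )

    # alt-loc policy: highest occupancy wins, ties broken by alt-loc character order
    for (key, _name), cands in alt_candidates.items():
        best = sorted(cands, key=lambda c: (-c[1], c[0]))[0]
        index[key].atoms.append(best[2])
    for res in residues:
        res.atoms.sort(key=lambda a: a.serial)
    return Structure(residues=residues, title=title), pv_atoms


def parse_pdb(text: str) -> Structure:
    """Parse legacy-PDB text into a :class:`Structure`.

    Residues appear in file order; kind is assigned from the residue
    name; for alternate locations the highest-occupancy conformer is
    kept.  Only the first model of a multi-model file is read (with a
    warning).
    """
    structure, _ = _parse(text, collect_pv=False)
    return structure


def read_parch_pdb(text: str):
    """Parse an annotated PDB, recovering both the structure and its PV table.

    Returns ``(structure, pv_table)`` where the table is rebuilt from
    the per-atom annotation column via the backbone/nucleobase
    partition.
    """
    from .parch_core import PVTable  # local import to avoid a cycle

    structure, pv_atoms = _parse(text, collect_pv=True)
    table = PVTable()
    for res in structure.residues:
        if res.kind is ResidueKind.PROTEIN:
            for atom in res.atoms:
                v = pv_atoms.get((res.key, atom.name))
                if v is not None:
                    table.set(res.key, Moiety.PROT, v, res_name=res.name)
                    break
        elif res.kind is ResidueKind.DNA:
            bb, nb = partition_dna_atoms(res)
            for names, moiety in ((bb, Moiety.BB), (nb, Moiety.NB)):
                for atom in res.atoms:
                    if normalize_atom_name(atom.name) in names:
                        v = pv_atoms.get((res.key, atom.name))
                        if v is not None:
                            table.set(res.key, moiety, v, res_name=res.name)
                            break
    return structure, table


# ---------------------------------------------------------------------------
# Legacy-PDB writing
# ---------------------------------------------------------------------------

_POLYMER_KINDS = (ResidueKind.PROTEIN, ResidueKind.DNA)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(record: str, serial: int, atom: Atom, res: Residue,
               pv: float | None) -> str:
    line = (
        f"{record:<6s}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.alt_loc or ' ':1s}{res.name:>3s} {res.chain_id or ' ':1s}"
        f"{res.seq_id:>4d}{res.icode or ' ':1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}  "
    )
    if pv is not None:
        line += f"{pv:8.2f}"
    return line


def write_pdb(structure: Structure, pv_table=None) -> str:
    """Serialize a structure to legacy-PDB text.

    When ``pv_table`` is given, every protein atom line carries the
    residue's PROT value and every DNA atom line the BB or NB value of
    its partition, appended as a fixed-width column (the annotated
    dialect); waters, ions and unknown residues are written without the
    extra column.
    """
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    serial = 0
    prev_chain: str | None = None
    prev_polymer = False
    for res in structure.residues:
        polymer = res.kind in _POLYMER_KINDS
        if prev_polymer and prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        record = "ATOM" if polymer else "HETATM"
        moiety_of: dict[str, Moiety] = {}
        if pv_table is not None and res.kind is ResidueKind.DNA:
            bb, nb = partition_dna_atoms(res)
            moiety_of = {n: Moiety.BB for n in bb}
            moiety_of.update({n: Moiety.NB for n in nb})
        for atom in res.atoms:
            serial += 1
            pv = None
            if pv_table is not None:
                if res.kind is ResidueKind.PROTEIN:
                    pv = pv_table.get(res.key, Moiety.PROT)
                elif res.kind is ResidueKind.DNA:
                    m = moiety_of.get(normalize_atom_name(atom.name))
                    pv = pv_table.get(res.key, m) if m is not None else None
            lines.append(_atom_line(record, serial, atom, res, pv))
        prev_chain = res.chain_id
        prev_polymer = polymer
    if prev_polymer:
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_parch_pdb(structure: Structure, pv_table) -> str:
    """Annotated-PDB text with the hydropathy column (coverage checked).

    Every non-water, non-ion residue must be covered by the table: a
    PROT value for protein residues, both BB and NB values for DNA
    residues.  Missing records raise :class:`InputError` listing the
    offending residues.
    """
    from .errors import InputError

    missing: list[str] = []
    for res in structure.residues:
        if res.kind is ResidueKind.PROTEIN:
            if pv_table.get(res.key, Moiety.PROT) is None:
                missing.append(f"{res.name} {res.key} PROT")
        elif res.kind is ResidueKind.DNA:
            for m in (Moiety.BB, Moiety.NB):
                if pv_table.get(res.key, m) is None:
                    missing.append(f"{res.name} {res.key} {m.value}")
    if missing:
        raise InputError(
            "PV table does not cover: " + "; ".join(missing[:20])
            + ("" if len(missing) <= 20 else f" ... ({len(missing)} total)")
        )
    return write_pdb(structure, pv_table=pv_table)
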
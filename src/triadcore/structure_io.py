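"""Structural and sequence file I/O and the object model the pipeline works on.

Structures are read from PDB-format text (gemmi does the record-level
parsing) into a light chain/residue/atom hierarchy with the conventions the
rest of the pipeline assumes: Ångström coordinates, author (1-based) residue
numbering, one atom per name after alternate-location resolution, waters and
non-amino-acid heteroatoms dropped, first MODEL only.

Alignments (gapped FASTA or Clustal) are read through Bio.AlignIO.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import AlignIO, SeqIO


class StructureParseError(ValueError):
    """Raised when PDB-format text cannot be turned into a StructureModel."""


class AlignmentParseError(ValueError):
    """Raised when alignment text is malformed (e.g. ragged rows)."""


#: 3-letter -> 1-letter translation for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class AtomRecord:
    """One atom: label, element, Å coordinates, occupancy, B-factor, altloc."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]; clamping",
                stacklevel=2,
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)


@dataclass
class ResidueView:
    """One residue: 3-letter name, author seq id, insertion code, atoms."""

    res_name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def residue_id(self) -> str:
        """Author-style id string, e.g. ``"57"`` or ``"57A"``."""
        return f"{self.seq_id}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_complete_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))


@dataclass
class ChainView:
    """One chain: id plus residues ordered by (seq_id, insertion_code)."""

    chain_id: str
    residues: list[ResidueView] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.seq_id, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"chain {self.chain_id}: duplicate (seq_id, insertion_code)")
        if keys != sorted(keys):
            raise ValueError(f"chain {self.chain_id}: residues not ordered by (seq_id, icode)")

    def residue(self, seq_id: int, insertion_code: str = "") -> ResidueView | None:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        return None

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates for residues that have a CA atom, in chain order."""
        cas = [r.atom("CA") for r in self.residues]
        return np.array([a.coords for a in cas if a is not None], dtype=float)


@dataclass
class StructureModel:
    """A parsed structure: accession, free-text taxon label, chains."""

    model_id: str
    taxon_label: str = ""
    chains: list[ChainView] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"{self.model_id}: structure must have at least one chain")
        if self.atom_count() == 0:
            raise ValueError(f"{self.model_id}: structure must contain atoms")

    def chain(self, chain_id: str) -> ChainView:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.model_id}: no chain {chain_id!r}")

    def iter_atoms(self):
        """Yield (chain, residue, atom) over the whole model."""
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def all_coords(self) -> np.ndarray:
        return np.array([a.coords for _, _, a in self.iter_atoms()], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    replace(a, coords=rotation @ a.coords + translation)
                    for a in r.atoms
                ]
                residues.append(replace(r, atoms=atoms))
            chains.append(ChainView(c.chain_id, residues))
        return StructureModel(self.model_id, self.taxon_label, chains)


@dataclass
class SequenceRecord:
    """A named 1-letter amino-acid sequence (alphabet ACDEFGHIKLMNPQRSTVWY + X)."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        self.residues = self.residues.upper()


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: list[SequenceRecord]
    n_cols: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
        self.n_cols = lengths.pop()

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"no alignment row {seq_id!r}")


# ---------------------------------------------------------------------------
# PDB reading / writing


def _check_coordinate_fields(text: str) -> None:
    # gemmi is forgiving about bad numeric fields; pre-scan so the error can
    # name the offending line.
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    v = float(fld)
                except ValueError:
                    raise StructureParseError(
                        f"line {i}: malformed coordinate field {fld!r}"
                    ) from None
                if not math.isfinite(v):
                    raise StructureParseError(f"line {i}: non-finite coordinate {fld!r}")


def _select_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # Keep, per atom name, the highest-occupancy alternate location
    # (ties broken by the alphabetically first altloc tag).
    by_name: dict[str, list[tuple[int, AtomRecord]]] = {}
    for i, a in enumerate(atoms):
        by_name.setdefault(a.name, []).append((i, a))
    kept = []
    for group in by_name.values():
        kept.append(min(group, key=lambda ia: (-ia[1].occupancy, ia[1].altloc)))
    kept.sort(key=lambda ia: ia[0])
    return [a for _, a in kept]


def parse_structure(text: str, model_id: str, taxon_label: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    First MODEL only; waters and non-amino-acid HETATMs are dropped; for
    alternate locations the highest-occupancy conformer is kept (ties ->
    alphabetically first tag).

    Raises
    ------
    StructureParseError
        If no ATOM/HETATM records survive or a coordinate field is malformed
        (the message names the line number).
    """
    _check_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{model_id}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{model_id}: no ATOM/HETATM records found")
    model = st[0]

    chains: list[ChainView] = []
    for ch in model:
        residues: list[ResidueView] = []
        for res in ch:
            if res.name in _WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = (info is not None and info.is_amino_acid()) or res.name in THREE_TO_ONE
            if not is_aa:
                continue
            atoms = []
            for at in res:
                altloc = at.altloc if at.altloc not in ("\x00", " ") else ""
                atoms.append(
                    AtomRecord(
                        name=at.name,
                        element=at.element.name or "X",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        b_factor=float(at.b_iso),
                        altloc=altloc,
                    )
                )
            atoms = _select_altlocs(atoms)
            if not atoms:
                continue
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            residues.append(ResidueView(res.name, res.seqid.num, icode, atoms))
        residues.sort(key=lambda r: (r.seq_id, r.insertion_code))
        if residues:
            chains.append(ChainView(ch.name, residues))
    if not chains or sum(len(r.atoms) for c in chains for r in c.residues) == 0:
        raise StructureParseError(f"{model_id}: no amino-acid atoms found")
    return StructureModel(model_id, taxon_label, chains)


def write_structure(model: StructureModel) -> str:
    """Serialize a StructureModel as fixed-width PDB ATOM records (8.3f coords)."""
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{a.altloc or ' ':1s}{res.res_name:>3s} "
                    f"{chain.chain_id:1s}{res.seq_id:4d}{res.insertion_code or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequence(chain: ChainView) -> SequenceRecord:
    """Translate a chain's residues to a 1-letter sequence (unknown names -> X)."""
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id}: empty")
    seq = "".join(THREE_TO_ONE.get(r.res_name, "X") for r in chain.residues)
    return SequenceRecord(chain.chain_id, seq)


# ---------------------------------------------------------------------------
# Alignment reading / writing


def parse_alignment(text: str) -> Alignment:
    """Parse a gapped-FASTA or Clustal alignment (consensus line ignored)."""
    stripped = text.lstrip()
    if stripped.upper().startswith("CLUSTAL"):
        try:
            msa = AlignIO.read(io.StringIO(text), "clustal")
        except ValueError as exc:
            raise AlignmentParseError(str(exc)) from exc
        rows = [SequenceRecord(rec.id, str(rec.seq)) for rec in msa]
    else:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) < 2:
            raise AlignmentParseError("alignment needs at least 2 sequences")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            ref_len = len(records[0].seq)
            bad = next(r.id for r in records if len(r.seq) != ref_len)
            raise AlignmentParseError(f"row {bad!r}: length differs from first row")
        rows = [SequenceRecord(rec.id, str(rec.seq)) for rec in records]
    return Alignment(rows)


def write_alignment(aln: Alignment) -> str:
    """Serialize an Alignment as gapped FASTA."""
    out = []
    for row in aln.rows:
        out.append(f">{row.seq_id}")
        out.append(row.residues)
    return "\n".join(out) + "\n"
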
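"""Sequence-level analyses: pairwise global alignment, conservation
occupancy with Clustal-style column symbols, reference (chymotrypsin)
numbering, and physico-chemical composition profiles.

The global aligner is a plain Needleman–Wunsch with linear gap scoring and a
fixed, deterministic tie-break (diagonal > up > left), which is what the
superposition stage needs to seed a reproducible residue correspondence.
Column symbols follow the Clustal convention: ``*`` fully conserved, ``:``
all residues in one strong group, ``.`` one weak group, blank otherwise.
Composition classes follow the EMBOSS pepstats convention, with polar
defined as the complement of nonpolar over the 20 standard residues so that
nonpolar + polar = 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .structure_io import Alignment, ChainView, SequenceRecord, chain_sequence

# Clustal conservation groups (overridable in column_conservation).
STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
    "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
]

# EMBOSS pepstats physico-chemical classes. Polar is the complement of
# nonpolar over the 20 standard residues (keeps nonpolar + polar = 100%).
_NONPOLAR = set("ACFGILMPVWY")
COMPOSITION_CLASSES: dict[str, set[str]] = {
    "tiny": set("ACGST"),
    "small": set("ACDGNPSTV"),
    "aliphatic": set("AILV"),
    "aromatic": set("FHWY"),
    "nonpolar": _NONPOLAR,
    "polar": set("ACDEFGHIKLMNPQRSTVWY") - _NONPOLAR,
    "charged": set("DEHKR"),
    "basic": set("HKR"),
    "acidic": set("DE"),
}


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment: gapped rows, score, % identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column gapped in both rows")


@dataclass
class AlignmentColumnStats:
    """Occupancy (% of rows carrying the modal non-gap residue) and symbol."""

    col: int  # 1-based
    occupancy_pct: float
    symbol: str  # "*", ":", ".", " "


@dataclass
class CompositionProfile:
    """Molar percentage per physico-chemical class (classes overlap)."""

    molar_pct: dict[str, float]

    def __getitem__(self, cls: str) -> float:
        return self.molar_pct[cls]


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment under linear gap scoring.

    Ties are broken deterministically, preferring diagonal over up (gap in
    ``b``) over left (gap in ``a``) during traceback.
    """
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(sa), len(sb)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    # 0 = diag, 1 = up, 2 = left; initial edges are forced moves
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(sb.encode(), dtype="S1") == sa[i - 1].encode(),
                       match, mismatch)
        for j in range(1, m + 1):
            options = (
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )
            k = int(np.argmax(options))  # argmax takes the first max: diag > up > left
            score[i, j] = options[k]
            move[i, j] = k

    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        k = move[i, j]
        if k == 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif k == 1:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ident = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score[n, m]),
        identity_pct=100.0 * ident / len(aligned_a),
    )


def alignment_residue_pairs(
    ref_chain: ChainView, tgt_chain: ChainView, **align_kwargs
) -> list[tuple[str, str]]:
    """Residue-id pairs for match columns of a global alignment of two chains.

    Convenience bridge to :func:`triadcore.superposition.iterative_core_superpose`.
    """
    aln = global_align(chain_sequence(ref_chain), chain_sequence(tgt_chain), **align_kwargs)
    pairs = []
    i = j = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            pairs.append((ref_chain.residues[i].residue_id,
                          tgt_chain.residues[j].residue_id))
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return pairs


def column_conservation(
    aln: Alignment,
    strong_groups: list[str] | None = None,
    weak_groups: list[str] | None = None,
) -> list[AlignmentColumnStats]:
    """Per-column occupancy percentage and Clustal-style conservation symbol.

    Occupancy counts the rows carrying the column's most frequent non-gap
    residue, over *all* rows (gapped rows stay in the denominator).  ``*``
    requires every row non-gap and identical; ``:``/``.`` require all
    non-gap residues to fall within a single strong/weak group and tolerate
    gaps.
    """
    strong = [set(g) for g in (strong_groups or STRONG_GROUPS)]
    weak = [set(g) for g in (weak_groups or WEAK_GROUPS)]
    n_rows = len(aln.rows)
    stats = []
    for col in range(aln.n_cols):
        residues = [row.residues[col] for row in aln.rows]
        nongap = [r for r in residues if r != "-"]
        counts = Counter(nongap)
        occupancy = 100.0 * max(counts.values()) / n_rows if counts else 0.0
        present = set(nongap)
        if present and len(present) == 1 and len(nongap) == n_rows:
            symbol = "*"
        elif present and any(present <= g for g in strong):
            symbol = ":"
        elif present and any(present <= g for g in weak):
            symbol = "."
        else:
            symbol = " "
        stats.append(AlignmentColumnStats(col + 1, occupancy, symbol))
    return stats


def map_reference_numbering(
    aln: Alignment, reference_id: str, ref_start: int = 1
) -> dict[tuple[str, int], int | str]:
    """Number every aligned residue by the reference row's residue indices.

    Returns a map from (sequence id, 1-based residue index in that sequence)
    to the reference residue number, or the string ``"insertion"`` where the
    reference is gapped.  Using a chymotrypsin row as reference yields
    chymotrypsin numbering (e.g. the catalytic His57/Asp102/Ser195 labels).
    """
    ref = aln.row(reference_id)  # KeyError if absent
    ref_number = []
    k = ref_start - 1
    for c in ref.residues:
        if c == "-":
            ref_number.append(None)
        else:
            k += 1
            ref_number.append(k)
    mapping: dict[tuple[str, int], int | str] = {}
    for row in aln.rows:
        idx = 0
        for col, c in enumerate(row.residues):
            if c == "-":
                continue
            idx += 1
            num = ref_number[col]
            mapping[(row.seq_id, idx)] = num if num is not None else "insertion"
    return mapping


def composition_profile(seq: SequenceRecord) -> CompositionProfile:
    """Molar percentage of each physico-chemical class (X excluded)."""
    counted = [r for r in seq.residues if r != "X" and r != "-"]
    if not counted:
        raise ValueError(f"{seq.seq_id}: no standard residues to profile")
    n = len(counted)
    counts = Counter(counted)
    pct = {
        cls: 100.0 * sum(counts[r] for r in members) / n
        for cls, members in COMPOSITION_CLASSES.items()
    }
    return CompositionProfile(pct)


def flag_composition_outliers(
    profiles: list[tuple[str, CompositionProfile]],
) -> list[tuple[str, str, str]]:
    """Flag per-class outliers: value strictly outside mean ± sample SD.

    Returns (label, class, "high"|"low") tuples.  Requires ≥3 profiles so
    the dispersion estimate is meaningful.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to flag outliers")
    flags = []
    for cls in COMPOSITION_CLASSES:
        values = np.array([p[cls] for _, p in profiles])
        mean = values.mean()
        sd = values.std(ddof=1)
        for (label, _), v in zip(profiles, values):
            if v > mean + sd:
                flags.append((label, cls, "high"))
            elif v < mean - sd:
                flags.append((label, cls, "low"))
    return flags
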
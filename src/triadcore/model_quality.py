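"""Geometry-based model validation.

Three families of metrics, all computable from coordinates alone:

* backbone φ/ψ/ω dihedrals and a four-region Ramachandran summary
  (most favoured / additional allowed / generously allowed / disallowed),
  classified on a bundled 10°×10° grid map;
* an all-atom clashscore — steric overlaps > 0.4 Å per 1000 heavy atoms,
  with pairs up to 3 covalent bonds apart excluded (bond graph inferred
  from distance + element);
* RMS deviation of backbone bond lengths and angles from the Engh–Huber
  standard values.

Hydrogens are not modelled: depositions this pipeline targets are X-ray
structures without them, so the clashscore is a heavy-atom score and the
hydrogen-dependent criteria are approximated accordingly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainView, StructureModel

#: Heavy-atom van der Waals radii (Å) used by the clashscore.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Covalent radii (Å) for distance-based bond inference.
COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "H": 0.37}

#: Engh–Huber standard backbone bond lengths (Å). "C:N" is the peptide bond.
STANDARD_BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("C", "N"): 1.329,
}

#: Engh–Huber standard backbone bond angles (degrees); "+" marks the next
#: residue's atom across the peptide bond, "-" the previous residue's.
STANDARD_BOND_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N+"): 116.2,
    ("O", "C", "N+"): 123.0,
    ("C-", "N", "CA"): 121.7,
}

#: Maximum peptide C–N distance (Å); larger gaps are treated as chain breaks.
CHAIN_BREAK_CN = 2.5

_REGION_NAMES = {
    "M": "most_favoured",
    "A": "additional_allowed",
    "G": "generously_allowed",
    "D": "disallowed",
}
_REGION_ORDER = ["most_favoured", "additional_allowed", "generously_allowed", "disallowed"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DihedralRecord:
    """φ/ψ/ω (degrees, in (−180, 180]) for one residue; None where undefined."""

    residue_id: str
    res_name: str
    phi: float | None
    psi: float | None
    omega: float | None


@dataclass
class RamachandranSummary:
    """Counts and percentages of (φ,ψ) pairs per Ramachandran region."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_defined: int

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "RamachandranSummary":
        """Build the summary (and its percentage arithmetic) from raw counts."""
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no defined (phi, psi) pairs")
        pct = {
            k: round_half_away(100.0 * counts.get(k, 0) / total, 1)
            for k in _REGION_ORDER
        }
        full = {k: counts.get(k, 0) for k in _REGION_ORDER}
        return cls(counts=full, percentages=pct, n_defined=total)


@dataclass
class BondGeometryResult:
    """RMSD of backbone bond lengths (Å) and angles (°) vs standard values."""

    length_rmsd: float
    angle_rmsd: float
    n_lengths: int
    n_angles: int
    n_skipped_bonds: int


@dataclass
class QualityReport:
    """Per-structure validation bundle."""

    clashscore: float
    bond_length_rmsd: float
    bond_angle_rmsd: float
    rama: RamachandranSummary


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, in (−180, 180]) over four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def backbone_dihedrals(chain: ChainView) -> list[DihedralRecord]:
    """φ/ψ/ω per residue; termini, missing atoms and chain breaks -> None.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i);  ψ(i) = N(i)–CA(i)–C(i)–N(i+1);
    ω(i) = CA(i−1)–C(i−1)–N(i)–CA(i).  A C–N distance above
    ``CHAIN_BREAK_CN`` severs the link between consecutive residues.
    """
    res = chain.residues
    coords = [{a.name: a.coords for a in r.atoms} for r in res]

    def linked(i: int) -> bool:
        # peptide link between residue i and i+1
        c = coords[i].get("C")
        n = coords[i + 1].get("N") if i + 1 < len(res) else None
        return (
            c is not None and n is not None
            and float(np.linalg.norm(c - n)) <= CHAIN_BREAK_CN
        )

    out = []
    for i, r in enumerate(res):
        cur = coords[i]
        phi = psi = omega = None
        if i > 0 and linked(i - 1):
            prev = coords[i - 1]
            if all(k in cur for k in ("N", "CA", "C")) and "C" in prev:
                phi = dihedral_angle(prev["C"], cur["N"], cur["CA"], cur["C"])
            if all(k in cur for k in ("N", "CA")) and all(k in prev for k in ("CA", "C")):
                omega = dihedral_angle(prev["CA"], prev["C"], cur["N"], cur["CA"])
        if i + 1 < len(res) and linked(i):
            nxt = coords[i + 1]
            if all(k in cur for k in ("N", "CA", "C")) and "N" in nxt:
                psi = dihedral_angle(cur["N"], cur["CA"], cur["C"], nxt["N"])
        out.append(DihedralRecord(r.residue_id, r.res_name, phi, psi, omega))
    return out


# --- Ramachandran classification -------------------------------------------


def load_rama_map(path=None) -> np.ndarray:
    """Load a 36×36 region grid (rows = φ bins from −180, cols = ψ bins).

    The bundled default approximates the classic four-region map; any file
    with 36 lines of 36 characters from {M, A, G, D} can replace it.
    """
    if path is None:
        text = resources.files("triadcore.data").joinpath("rama_map.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    grid = np.array([list(r) for r in rows])
    if grid.shape != (36, 36) or not set(grid.ravel()) <= set("MAGD"):
        raise ValueError("Ramachandran map must be 36×36 over {M,A,G,D}")
    return grid


def classify_phi_psi(phi: float, psi: float, rama_map: np.ndarray) -> str:
    """Region name for one (φ, ψ) pair via the 10°×10° grid map."""
    i = min(int((phi + 180.0) // 10), 35)
    j = min(int((psi + 180.0) // 10), 35)
    return _REGION_NAMES[rama_map[i, j]]


def ramachandran_summary(
    dihedrals: list[DihedralRecord], rama_map: np.ndarray | None = None
) -> RamachandranSummary:
    """Classify every residue with both φ and ψ defined; summarize by region.

    Glycine and proline go through the same map as everything else; the
    denominator is exactly the number of residues with both angles defined.
    """
    if rama_map is None:
        rama_map = load_rama_map()
    counts = {k: 0 for k in _REGION_ORDER}
    for d in dihedrals:
        if d.phi is not None and d.psi is not None:
            counts[classify_phi_psi(d.phi, d.psi, rama_map)] += 1
    return RamachandranSummary.from_counts(counts)


# --- clashscore --------------------------------------------------------------


def _covalent_bond_graph(coords: np.ndarray, elements: list[str]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    if len(elements) < 2:
        return g
    rcov = np.array([COVALENT_RADII.get(e, 0.77) for e in elements])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(2.0 * rcov.max() + 0.45):
        d = np.linalg.norm(coords[i] - coords[j])
        if 0.4 < d <= rcov[i] + rcov[j] + 0.45:
            g.add_edge(i, j)
    return g


def clashscore(
    model: StructureModel,
    overlap_threshold: float = 0.4,
    radii: dict[str, float] | None = None,
) -> float:
    """Steric clashes per 1000 heavy atoms.

    A clash is an unordered heavy-atom pair with van der Waals overlap
    r(a) + r(b) − d(a,b) strictly greater than ``overlap_threshold``,
    excluding pairs connected by ≤3 covalent bonds (inferred by distance
    and element) and Sγ–Sγ disulfide partners.
    """
    radii = radii or VDW_RADII
    atoms = [(a.element, a.coords) for _, _, a in model.iter_atoms() if a.element != "H"]
    if not atoms:
        return 0.0
    elements = [e for e, _ in atoms]
    coords = np.array([c for _, c in atoms])
    rv = np.array([radii.get(e, 1.70) for e in elements])

    graph = _covalent_bond_graph(coords, elements)
    excluded: set[frozenset] = set()
    for i in graph.nodes:
        for j, dist in nx.single_source_shortest_path_length(graph, i, cutoff=3).items():
            if j != i:
                excluded.add(frozenset((i, j)))

    tree = cKDTree(coords)
    clashes = 0
    for i, j in tree.query_pairs(2.0 * rv.max()):
        if frozenset((i, j)) in excluded:
            continue
        # disulfide partners (also caught by the bond graph in most cases)
        if elements[i] == "S" and elements[j] == "S":
            if np.linalg.norm(coords[i] - coords[j]) <= 2.3:
                continue
        overlap = rv[i] + rv[j] - np.linalg.norm(coords[i] - coords[j])
        if overlap > overlap_threshold:
            clashes += 1
    return 1000.0 * clashes / len(atoms)


# --- bond geometry -----------------------------------------------------------


def _angle(a, b, c) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bond_geometry_rmsd(
    model: StructureModel,
    bond_lengths: dict | None = None,
    bond_angles: dict | None = None,
) -> BondGeometryResult:
    """RMSD of observed backbone bond lengths/angles against standard values.

    Backbone bonds and angles with a standard-table entry contribute to the
    RMSDs; other covalent bonds (side chains, ligands) are skipped and
    counted in ``n_skipped_bonds``.
    """
    blen = bond_lengths or STANDARD_BOND_LENGTHS
    bang = bond_angles or STANDARD_BOND_ANGLES
    backbone = {"N", "CA", "C", "O"}
    dl: list[float] = []
    da: list[float] = []
    skipped = 0

    for chain in model.chains:
        res = chain.residues
        coords = [{a.name: a.coords for a in r.atoms} for r in res]
        for i, r in enumerate(res):
            cur = coords[i]
            # intra-residue backbone bonds
            for pair in (("N", "CA"), ("CA", "C"), ("C", "O")):
                if all(k in cur for k in pair):
                    d = float(np.linalg.norm(cur[pair[0]] - cur[pair[1]]))
                    dl.append(d - blen[pair])
            # side-chain / unrecognized covalent bonds: inferred, counted, skipped
            names = list(cur)
            for x, y in itertools.combinations(names, 2):
                if {x, y} <= backbone:
                    continue
                d = float(np.linalg.norm(cur[x] - cur[y]))
                rc = COVALENT_RADII.get(x[0], 0.77) + COVALENT_RADII.get(y[0], 0.77)
                if 0.4 < d <= rc + 0.45:
                    skipped += 1
            # intra-residue angles
            if all(k in cur for k in ("N", "CA", "C")):
                da.append(_angle(cur["N"], cur["CA"], cur["C"]) - bang[("N", "CA", "C")])
            if all(k in cur for k in ("CA", "C", "O")):
                da.append(_angle(cur["CA"], cur["C"], cur["O"]) - bang[("CA", "C", "O")])
            # peptide link to the next residue
            if i + 1 < len(res):
                nxt = coords[i + 1]
                if "C" in cur and "N" in nxt:
                    d = float(np.linalg.norm(cur["C"] - nxt["N"]))
                    if d <= CHAIN_BREAK_CN:
                        dl.append(d - blen[("C", "N")])
                        if "CA" in cur:
                            da.append(_angle(cur["CA"], cur["C"], nxt["N"])
                                      - bang[("CA", "C", "N+")])
                        if "O" in cur:
                            da.append(_angle(cur["O"], cur["C"], nxt["N"])
                                      - bang[("O", "C", "N+")])
                        if "CA" in nxt:
                            da.append(_angle(cur["C"], nxt["N"], nxt["CA"])
                                      - bang[("C-", "N", "CA")])

    length_rmsd = float(np.sqrt(np.mean(np.square(dl)))) if dl else 0.0
    angle_rmsd = float(np.sqrt(np.mean(np.square(da)))) if da else 0.0
    return BondGeometryResult(length_rmsd, angle_rmsd, len(dl), len(da), skipped)


def quality_report(model: StructureModel, rama_map: np.ndarray | None = None) -> QualityReport:
    """Full geometry-validation bundle for one structure (first chain set)."""
    dihedrals: list[DihedralRecord] = []
    for chain in model.chains:
        dihedrals.extend(backbone_dihedrals(chain))
    rama = ramachandran_summary(dihedrals, rama_map)
    geom = bond_geometry_rmsd(model)
    return QualityReport(
        clashscore=clashscore(model),
        bond_length_rmsd=geom.length_rmsd,
        bond_angle_rmsd=geom.angle_rmsd,
        rama=rama,
    )
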
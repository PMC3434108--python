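"""Catalytic-triad geometry and active-site environment.

The charge-relay triad of chymotrypsin-like serine proteases (His57, Asp102,
Ser195 in chymotrypsin numbering) sits at the interface of the two β-barrels.
This module measures the three inter-residue Cα distances for a located
triad, aggregates them across structures (mean ± sample SD), lists residues
in close proximity to the catalytic site, and detects the stabilizing
contacts discussed for such sites: hydrogen bonds (heavy-atom
distance/angle criterion, since X-ray depositions usually lack hydrogens)
and disulfide bridges (Cys Sγ–Sγ).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueView, StructureModel


class TriadError(ValueError):
    """Raised when a triad locator cannot be resolved on a structure."""


@dataclass(frozen=True)
class ResidueLocator:
    """(chain id, author seq id, insertion code) address of one residue."""

    chain_id: str
    seq_id: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_id}{self.insertion_code}"

    @classmethod
    def parse(cls, text: str) -> "ResidueLocator":
        """Parse ``"A:328"`` / ``"A:57B"`` style locator strings."""
        chain, _, rest = text.partition(":")
        if not chain or not rest:
            raise ValueError(f"bad residue locator {text!r} (expected CHAIN:SEQID)")
        num = rest.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        return cls(chain, int(num), rest[len(num):])


@dataclass
class CatalyticTriad:
    """Locators of the His/Asp/Ser triad plus their reference-numbering labels."""

    his: ResidueLocator
    asp: ResidueLocator
    ser: ResidueLocator
    reference_labels: tuple[int, int, int] = (57, 102, 195)

    def __post_init__(self) -> None:
        if len({self.his, self.asp, self.ser}) != 3:
            raise ValueError("triad members must be three distinct residues")

    def members(self) -> list[tuple[str, ResidueLocator]]:
        return [("HIS", self.his), ("ASP", self.asp), ("SER", self.ser)]


@dataclass
class TriadGeometry:
    """The three catalytic-triad Cα–Cα distances in Å."""

    d_asp_his: float
    d_his_ser: float
    d_asp_ser: float

    def __post_init__(self) -> None:
        d = (self.d_asp_his, self.d_his_ser, self.d_asp_ser)
        if any(x < 0 for x in d):
            raise ValueError("distances must be non-negative")
        for a, b, c in itertools.permutations(d):
            if a > b + c + 1e-9:
                raise ValueError("triad distances violate the triangle inequality")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_asp_his, self.d_his_ser, self.d_asp_ser)


@dataclass
class TriadStats:
    """Per-distance mean and SD over a set of triad geometries.

    ``sd_kind`` records the convention: sample (n−1) SD, zero when n = 1.
    """

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    n: int
    sd_kind: str = "sample"


@dataclass
class StabilizingContact:
    """One stabilizing contact: H-bond or disulfide between two located atoms."""

    kind: str  # "hbond" | "disulfide"
    partners: tuple[str, str]  # "chain:resid:atom" locator strings
    distance: float
    angle: float | None = None  # donor-antecedent–donor–acceptor, H-bonds only


def _resolve(model: StructureModel, loc: ResidueLocator) -> ResidueView:
    try:
        chain = model.chain(loc.chain_id)
    except KeyError as exc:
        raise TriadError(str(exc)) from exc
    res = chain.residue(loc.seq_id, loc.insertion_code)
    if res is None:
        raise TriadError(f"{model.model_id}: residue {loc} not found")
    return res


def _triad_residues(model: StructureModel, triad: CatalyticTriad) -> dict[str, ResidueView]:
    out = {}
    for expected, loc in triad.members():
        res = _resolve(model, loc)
        if res.res_name != expected:
            warnings.warn(
                f"{model.model_id}: {loc} is {res.res_name}, expected {expected}",
                stacklevel=3,
            )
        out[expected] = res
    return out


def triad_geometry(model: StructureModel, triad: CatalyticTriad) -> TriadGeometry:
    """Measure the three Cα–Cα distances of a located catalytic triad."""
    residues = _triad_residues(model, triad)
    cas = {}
    for name, loc in zip(("HIS", "ASP", "SER"), (triad.his, triad.asp, triad.ser)):
        ca = residues[name].atom("CA")
        if ca is None:
            raise TriadError(f"{model.model_id}: residue {loc} has no CA atom")
        cas[name] = ca.coords
    return TriadGeometry(
        d_asp_his=float(np.linalg.norm(cas["ASP"] - cas["HIS"])),
        d_his_ser=float(np.linalg.norm(cas["HIS"] - cas["SER"])),
        d_asp_ser=float(np.linalg.norm(cas["ASP"] - cas["SER"])),
    )


def aggregate_triad_stats(geometries: list[TriadGeometry]) -> TriadStats:
    """Mean and sample SD per distance over ≥1 geometries (SD = 0 when n = 1)."""
    if not geometries:
        raise ValueError("no geometries to aggregate")
    arr = np.array([g.as_tuple() for g in geometries], dtype=float)
    mean = tuple(float(x) for x in arr.mean(axis=0))
    if len(geometries) == 1:
        sd = (0.0, 0.0, 0.0)
    else:
        sd = tuple(float(x) for x in arr.std(axis=0, ddof=1))
    return TriadStats(mean=mean, sd=sd, n=len(geometries))


def proximal_residues(
    model: StructureModel, triad: CatalyticTriad, radius: float = 6.0
) -> list[ResidueLocator]:
    """Residues with any atom strictly within ``radius`` Å of any triad atom.

    Triad members themselves are excluded.  Default 6 Å — the conventional
    bound for "close proximity to the catalytic site".
    """
    residues = _triad_residues(model, triad)
    site = np.array([a.coords for r in residues.values() for a in r.atoms])
    triad_keys = {(loc.chain_id, loc.seq_id, loc.insertion_code)
                  for _, loc in triad.members()}
    tree = cKDTree(site)
    out = []
    for chain in model.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.seq_id, res.insertion_code)
            if key in triad_keys:
                continue
            coords = np.array([a.coords for a in res.atoms])
            dmin = tree.query(coords, k=1)[0].min()
            if dmin < radius:
                out.append(ResidueLocator(*key))
    return out


# --- stabilizing contacts ---------------------------------------------------

# Side-chain H-bond donors: residue name -> [(donor atom, antecedent atom)].
# The backbone amide N (antecedent CA) is a donor for every residue but PRO.
_SIDECHAIN_DONORS = {
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
    "CYS": [("SG", "CB")],
    "LYS": [("NZ", "CE")],
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("ND2", "CG")],
    "GLN": [("NE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "TRP": [("NE1", "CD1")],
}

_ACCEPTOR_ELEMENTS = {"O", "N"}


def detect_stabilizing_contacts(
    model: StructureModel,
    hbond_dmax: float = 3.5,
    hbond_angle_min: float = 120.0,
    ss_dmax: float = 2.3,
) -> list[StabilizingContact]:
    """Detect hydrogen bonds and disulfide bridges.

    H-bond criterion (hydrogens are absent from most X-ray depositions, so a
    heavy-atom rule is used): donor N/O to acceptor N/O distance ≤
    ``hbond_dmax`` and antecedent–donor–acceptor angle ≥ ``hbond_angle_min``.
    Disulfide: Cys Sγ–Sγ distance ≤ ``ss_dmax``.  Each contact is reported
    once; contacts within one residue, or between a backbone amide and the
    carbonyl it is bonded to through the peptide link, are excluded.
    """
    # Flat atom table with residue context.
    entries = []  # (chain, res, atom, index-in-chain)
    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            for atom in res.atoms:
                entries.append((chain, res, atom, i))

    def locator(chain, res, atom) -> str:
        return f"{chain.chain_id}:{res.residue_id}:{atom.name}"

    contacts: list[StabilizingContact] = []
    seen_pairs: set[frozenset] = set()

    # Disulfides.
    sgs = [(c, r, a) for c, r, a, _ in entries if r.res_name == "CYS" and a.name == "SG"]
    for (c1, r1, a1), (c2, r2, a2) in itertools.combinations(sgs, 2):
        d = float(np.linalg.norm(a1.coords - a2.coords))
        if 0 < d <= ss_dmax:
            contacts.append(
                StabilizingContact("disulfide", (locator(c1, r1, a1), locator(c2, r2, a2)), d)
            )

    # Donor list: backbone N + side-chain donors.
    donors = []  # (chain, res, donor atom, antecedent atom, chain index)
    for chain, res, atom, idx in entries:
        if atom.name == "N" and res.res_name != "PRO":
            ca = res.atom("CA")
            if ca is not None:
                donors.append((chain, res, atom, ca, idx))
        for dname, aname in _SIDECHAIN_DONORS.get(res.res_name, ()):
            if atom.name == dname:
                ante = res.atom(aname)
                if ante is not None:
                    donors.append((chain, res, atom, ante, idx))

    # Acceptors: any oxygen, plus side-chain nitrogens (the backbone amide N
    # is protonated and excluded).
    acceptors = [
        (c, r, a, i)
        for c, r, a, i in entries
        if a.element in _ACCEPTOR_ELEMENTS and not (a.element == "N" and a.name == "N")
    ]
    acc_coords = np.array([a.coords for _, _, a, _ in acceptors]) if acceptors else None
    tree = cKDTree(acc_coords) if acceptors else None

    for chain, res, don, ante, idx in donors:
        if tree is None:
            break
        for j in tree.query_ball_point(don.coords, hbond_dmax):
            achain, ares, acc, aidx = acceptors[j]
            if achain is chain and ares is res:
                continue
            # peptide-link neighbours: N(i) vs O/C of residue i-1 are 2 bonds apart
            if (don.name == "N" and acc.name in ("O", "C") and achain is chain
                    and aidx == idx - 1):
                continue
            d = float(np.linalg.norm(don.coords - acc.coords))
            if d <= 1e-6 or d > hbond_dmax:
                continue
            v1 = ante.coords - don.coords
            v2 = acc.coords - don.coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < hbond_angle_min:
                continue
            key = frozenset((locator(chain, res, don), locator(achain, ares, acc)))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            contacts.append(
                StabilizingContact(
                    "hbond",
                    (locator(chain, res, don), locator(achain, ares, acc)),
                    d,
                    angle,
                )
            )
    contacts.sort(key=lambda c: (c.kind, c.partners))
    return contacts
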
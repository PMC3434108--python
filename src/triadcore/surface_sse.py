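"""Secondary-structure assignment, solvent-accessible surface area and a
qualitative Coulomb surface-potential classifier.

Secondary structure is assigned from backbone dihedrals alone (window rule,
not hydrogen-bond patterns): a residue is helix-eligible for φ ∈ [−100, −30]
and ψ ∈ [−80, −5], strand-eligible for φ ∈ [−180, −40] with ψ in the upper
strand band; maximal eligible runs of at least 4 (helix) / 3 (strand)
residues become elements.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-spiral point set.  The surface classifier places formal charges at
side-chain charged-group centroids and evaluates a reduced Coulomb sum
V(p) = Σ qᵢ/d(p, i) (no dielectric — absorbed into the neutral-band
threshold), labelling points negative / neutral / positive.  It is a
qualitative classifier for electronegative/electropositive surface patches,
not a Poisson–Boltzmann substitute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_quality import VDW_RADII, backbone_dihedrals
from .structure_io import ChainView, StructureModel

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -40.0)
STRAND_PSI_UP = (60.0, 180.0)
STRAND_PSI_WRAP = (-180.0, -170.0)
MIN_LENGTH = {"H": 4, "E": 3}

#: Formal charges at side-chain charged-group centroids.  His is neutral by
#: default (protonation is pH-dependent); termini are off by default.
CHARGE_GROUPS = {
    "ASP": (-1.0, ("OD1", "OD2"), "CG"),
    "GLU": (-1.0, ("OE1", "OE2"), "CD"),
    "LYS": (+1.0, ("NZ",), "CE"),
    "ARG": (+1.0, ("NH1", "NH2", "NE"), "CZ"),
}


@dataclass
class SSEAnnotation:
    """Per-residue H/E/C labels plus the maximal elements ≥ minimum length."""

    labels: list[str]
    elements: list[tuple[str, str, str]]  # (type, start residue id, end residue id)


@dataclass
class SASAResult:
    """Shrake–Rupley areas: per atom (Ų), per residue, and the total."""

    atom_areas: np.ndarray
    residue_areas: dict[str, float]
    total: float
    exposed_points: np.ndarray | None = None  # M×3, only when requested


@dataclass
class SurfacePoint:
    """A surface site with its reduced Coulomb potential and class label."""

    coords: np.ndarray
    potential: float
    cls: str  # "negative" | "neutral" | "positive"


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def assign_sse(chain: ChainView) -> SSEAnnotation:
    """Assign H/E/C labels from φ/ψ windows; report maximal elements."""
    dihedrals = backbone_dihedrals(chain)
    eligible = []
    for d in dihedrals:
        if d.phi is None or d.psi is None:
            eligible.append("C")
        elif _in(HELIX_PHI, d.phi) and _in(HELIX_PSI, d.psi):
            eligible.append("H")
        elif _in(STRAND_PHI, d.phi) and (
            _in(STRAND_PSI_UP, d.psi) or _in(STRAND_PSI_WRAP, d.psi)
        ):
            eligible.append("E")
        else:
            eligible.append("C")

    labels = ["C"] * len(eligible)
    elements = []
    i = 0
    while i < len(eligible):
        kind = eligible[i]
        j = i
        while j < len(eligible) and eligible[j] == kind:
            j += 1
        if kind in MIN_LENGTH and j - i >= MIN_LENGTH[kind]:
            for k in range(i, j):
                labels[k] = kind
            elements.append(
                (kind, chain.residues[i].residue_id, chain.residues[j - 1].residue_id)
            )
        i = j
    return SSEAnnotation(labels=labels, elements=elements)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    return_points: bool = False,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area (probe 1.4 Å default).

    Per atom: fraction of ``n_points`` test points on the solvent-extended
    sphere not buried inside any neighbour, times 4π(r+probe)².
    """
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    radii = radii or VDW_RADII
    atoms = [(c, r, a) for c, r, a in model.iter_atoms() if a.element != "H"]
    coords = np.array([a.coords for _, _, a in atoms])
    rads = np.array([radii.get(a.element, 1.70) + probe for _, _, a in atoms])

    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(atoms))
    exposed: list[np.ndarray] = []
    for i in range(len(atoms)):
        pts = coords[i] + rads[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], rads[i] + rads.max())
                      if j != i]
        free = np.ones(n_points, dtype=bool)
        for j in neighbours:
            free &= np.linalg.norm(pts - coords[j], axis=1) >= rads[j]
        areas[i] = free.mean() * 4.0 * np.pi * rads[i] ** 2
        if return_points:
            exposed.append(pts[free])

    residue_areas: dict[str, float] = {}
    for (chain, res, _), area in zip(atoms, areas):
        key = f"{chain.chain_id}:{res.residue_id}"
        residue_areas[key] = residue_areas.get(key, 0.0) + float(area)
    return SASAResult(
        atom_areas=areas,
        residue_areas=residue_areas,
        total=float(areas.sum()),
        exposed_points=np.vstack(exposed) if return_points and exposed else
        (np.empty((0, 3)) if return_points else None),
    )


def charge_sites(
    model: StructureModel,
    his_charge: float = 0.0,
    include_termini: bool = False,
) -> list[tuple[float, np.ndarray]]:
    """(charge, centroid) list for charged side-chain groups.

    Centroid falls back to the branch atom and finally the Cα when
    side-chain atoms are absent (Cα-trace fixtures).
    """
    sites = []
    table = dict(CHARGE_GROUPS)
    if his_charge:
        table["HIS"] = (his_charge, ("ND1", "NE2"), "CG")
    for chain in model.chains:
        for res in chain.residues:
            entry = table.get(res.res_name)
            if entry is None:
                continue
            q, group, fallback = entry
            atoms = [res.atom(n) for n in group]
            atoms = [a for a in atoms if a is not None]
            if not atoms:
                fb = res.atom(fallback) or res.atom("CA")
                if fb is None:
                    continue
                atoms = [fb]
            centroid = np.mean([a.coords for a in atoms], axis=0)
            sites.append((q, centroid))
        if include_termini and chain.residues:
            n = chain.residues[0].atom("N")
            if n is not None:
                sites.append((+1.0, n.coords))
            c_term = chain.residues[-1]
            oxt = c_term.atom("OXT") or c_term.atom("O")
            if oxt is not None:
                sites.append((-1.0, oxt.coords))
    return sites


def surface_potential(
    model: StructureModel,
    points: np.ndarray,
    neutral_band: float = 0.05,
    his_charge: float = 0.0,
    include_termini: bool = False,
) -> list[SurfacePoint]:
    """Classify surface points by reduced Coulomb potential V = Σ qᵢ/dᵢ.

    ``cls`` is negative for V < −neutral_band, positive for V > +neutral_band,
    neutral otherwise (potential in charge/Å; the implicit dielectric is
    absorbed into the band).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sites = charge_sites(model, his_charge=his_charge, include_termini=include_termini)
    out = []
    for p in points:
        v = 0.0
        for q, c in sites:
            d = float(np.linalg.norm(p - c))
            if d > 1e-9:
                v += q / d
        if v < -neutral_band:
            cls = "negative"
        elif v > neutral_band:
            cls = "positive"
        else:
            cls = "neutral"
        out.append(SurfacePoint(coords=p, potential=v, cls=cls))
    return out
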
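"""Synthetic fixtures: toy protease structures and controlled alignments.

Everything here is a geometric stand-in, not a folded protein.  Toy
proteases place a His/Asp/Ser triad at exact, configurable Cα distances
between two strand-built lobes — enough to exercise superposition, triad
geometry, validation and surface code paths end-to-end without downloading
anything.  All generators are deterministic given their seed; no global
random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .catalytic_core import CatalyticTriad, ResidueLocator
from .structure_io import (
    Alignment,
    AtomRecord,
    ChainView,
    ResidueView,
    SequenceRecord,
    StructureModel,
)
from .superposition import RigidTransform

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal backbone internal coordinates (Engh–Huber convention).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

IDEAL_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


@dataclass
class ToyProteaseSpec:
    """Construction parameters for a toy two-lobe protease."""

    n_residues: int = 12  # per lobe
    d_asp_his: float = 6.4
    d_his_ser: float = 8.4
    d_asp_ser: float = 9.8
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        d = sorted((self.d_asp_his, self.d_his_ser, self.d_asp_ser))
        if d[2] > d[0] + d[1]:
            raise ValueError("triad target distances violate the triangle inequality")


@dataclass
class SyntheticAlignmentSpec:
    """Controlled-conservation alignment parameters."""

    n_rows: int = 21
    n_cols: int = 60
    conserved: list[tuple[int, str, float]] = field(default_factory=list)
    gap_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        cols = [c for c, _, _ in self.conserved]
        if len(set(cols)) != len(cols):
            raise ValueError("conserved columns must be distinct")
        for col, _, occ in self.conserved:
            if not 1 <= col <= self.n_cols:
                raise ValueError(f"conserved column {col} out of range 1..{self.n_cols}")
            if not 0 < occ <= 1:
                raise ValueError(f"occupancy {occ} not in (0, 1]")


def _place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = length * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), -math.sin(theta) * math.sin(chi)]
    )
    return c + np.column_stack((bc, m, n)) @ d2


def _backbone_trace(phi: float, psi: float, n: int, omega: float = 180.0):
    """N/CA/C/O coordinates for an n-residue chain at fixed (φ, ψ)."""
    coords = []  # per residue dict
    # first residue laid out in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        prev = coords[-1]
        ni = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        cai = _place_atom(prev["CA"], prev["C"], ni, _B_N_CA, _A_C_N_CA, omega)
        ci = _place_atom(prev["C"], ni, cai, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": ni, "CA": cai, "C": ci})
    for res in coords:
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return coords


def _residues_from_trace(trace, res_name: str, start_id: int) -> list[ResidueView]:
    residues = []
    for i, res in enumerate(trace):
        atoms = [
            AtomRecord(name, "C" if name in ("CA", "C") else name[0], xyz)
            for name, xyz in (("N", res["N"]), ("CA", res["CA"]),
                              ("C", res["C"]), ("O", res["O"]))
        ]
        residues.append(ResidueView(res_name, start_id + i, "", atoms))
    return residues


def make_ideal_sse(kind: str, n: int, chain_id: str = "A") -> ChainView:
    """Ideal helix/strand backbone at (−57, −47) / (−120, 120), Engh–Huber bonds."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    if kind not in IDEAL_PHI_PSI:
        raise ValueError(f"kind must be one of {sorted(IDEAL_PHI_PSI)}")
    phi, psi = IDEAL_PHI_PSI[kind]
    trace = _backbone_trace(phi, psi, n)
    return ChainView(chain_id, _residues_from_trace(trace, "ALA", 1))


def _triad_residue(res_name: str, seq_id: int, ca_target: np.ndarray) -> ResidueView:
    # one-residue backbone template, translated so the CA sits on the target
    n = np.array([-_B_N_CA, 0.0, 0.0])
    ca = np.zeros(3)
    ang = math.radians(180.0 - _A_N_CA_C)
    c = _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    o = _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, 180.0)
    shift = ca_target - ca
    atoms = [
        AtomRecord("N", "N", n + shift),
        AtomRecord("CA", "C", ca + shift),
        AtomRecord("C", "C", c + shift),
        AtomRecord("O", "O", o + shift),
    ]
    return ResidueView(res_name, seq_id, "", atoms)


def make_toy_protease(spec: ToyProteaseSpec) -> tuple[StructureModel, CatalyticTriad]:
    """Two strand-built lobes with a His/Asp/Ser triad at exact Cα distances.

    Pre-noise, the triad Cα distances equal the spec targets to machine
    precision; Gaussian coordinate noise (``noise_sigma``) is added last.
    """
    d_ah, d_hs, d_as = spec.d_asp_his, spec.d_his_ser, spec.d_asp_ser
    # triangle in the z = 0 plane: Asp at origin, His on x-axis
    asp_ca = np.zeros(3)
    his_ca = np.array([d_ah, 0.0, 0.0])
    x = (d_ah**2 + d_as**2 - d_hs**2) / (2.0 * d_ah)
    y2 = d_as**2 - x**2
    if y2 < 0:
        raise ValueError("triad target distances violate the triangle inequality")
    ser_ca = np.array([x, math.sqrt(y2), 0.0])

    n = spec.n_residues
    lobe1 = make_ideal_sse("strand", n).residues
    lobe2 = make_ideal_sse("strand", n).residues
    rot = Rotation.from_euler("y", 180, degrees=True).as_matrix()

    def shift(residues, offset, start_id, rotate=False):
        out = []
        for i, r in enumerate(residues):
            atoms = [
                AtomRecord(a.name, a.element,
                           (rot @ a.coords if rotate else a.coords) + offset)
                for a in r.atoms
            ]
            out.append(ResidueView(r.res_name, start_id + i, "", atoms))
        return out

    centroid = np.mean([asp_ca, his_ca, ser_ca], axis=0)
    residues = []
    residues += shift(lobe1, centroid + np.array([-0.5 * n * 3.2, -4.0, 8.0]), 1)
    residues.append(ResidueView("HIS", n + 1, "", _triad_residue("HIS", n + 1, his_ca).atoms))
    residues.append(ResidueView("ASP", n + 2, "", _triad_residue("ASP", n + 2, asp_ca).atoms))
    residues.append(ResidueView("SER", n + 3, "", _triad_residue("SER", n + 3, ser_ca).atoms))
    residues += shift(lobe2, centroid + np.array([-0.5 * n * 3.2, 4.0, -8.0]),
                      n + 4, rotate=True)

    chain = ChainView("A", residues)
    model = StructureModel(f"TOY-{spec.seed}", "synthetic", [chain])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for _, _, atom in model.iter_atoms():
            atom.coords = atom.coords + rng.normal(0.0, spec.noise_sigma, 3)
    triad = CatalyticTriad(
        his=ResidueLocator("A", n + 1),
        asp=ResidueLocator("A", n + 2),
        ser=ResidueLocator("A", n + 3),
    )
    return model, triad


def apply_random_transform(
    model: StructureModel, seed: int, noise_sigma: float = 0.0
) -> tuple[StructureModel, RigidTransform]:
    """Apply a uniform random rotation (quaternion method), a translation in
    [−50, 50]³ and optional i.i.d. Gaussian noise; return the transform."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rotation = Rotation.from_quat(quat).as_matrix()
    translation = rng.uniform(-50.0, 50.0, 3)
    transform = RigidTransform(rotation, translation)
    moved = model.transformed(rotation, translation)
    if noise_sigma > 0:
        for _, _, atom in moved.iter_atoms():
            atom.coords = atom.coords + rng.normal(0.0, noise_sigma, 3)
    return moved, transform


def make_synthetic_alignment(spec: SyntheticAlignmentSpec) -> Alignment:
    """Alignment with uniform background (10% gaps) and controlled columns.

    Each conserved column carries its residue in ⌈occupancy × n_rows⌉
    seeded-random rows; the remaining rows draw from the other 19 residues,
    so the conserved residue is always the column's modal residue.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    grid = np.empty((spec.n_rows, spec.n_cols), dtype="<U1")
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            grid[i, j] = "-" if rng.random() < spec.gap_rate else rng.choice(alphabet)
    for col, residue, occ in spec.conserved:
        k = math.ceil(occ * spec.n_rows - 1e-9)
        rows = rng.choice(spec.n_rows, size=k, replace=False)
        others = np.array([a for a in AMINO_ACIDS if a != residue])
        for i in range(spec.n_rows):
            grid[i, col - 1] = residue if i in rows else rng.choice(others)
    rows = [
        SequenceRecord(f"seq{i + 1:02d}", "".join(grid[i]))
        for i in range(spec.n_rows)
    ]
    return Alignment(rows)
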
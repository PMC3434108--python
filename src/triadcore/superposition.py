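"""Rigid-body superposition and common-core detection.

``kabsch_fit`` solves the orthogonal Procrustes problem by SVD with the
standard sign correction, so the returned rotation is always proper
(det = +1, never a reflection).  ``iterative_core_superpose`` implements the
common-core ("structurally conserved region") procedure: start from a
sequence-derived residue correspondence, fit, drop all Cα pairs deviating by
more than a cutoff, and refit until the pair set is stable.  Because pruning
only removes pairs and the refit is optimal, the per-pair RMSD is
non-increasing and the iteration terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import ChainView


class SuperpositionError(ValueError):
    """Raised for degenerate inputs or a core that shrinks below 3 pairs."""


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation matrix R, translation t in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    """Final fit: transform, residue pairs kept, RMSD (Å), % of target matched."""

    transform: RigidTransform
    pairs: list[tuple[str, str]]
    rmsd: float
    fraction_matched: float
    n_iterations: int = 0
    rmsd_history: list[float] = field(default_factory=list)


def kabsch_fit(fixed: np.ndarray, moving: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (paired N×3 arrays).

    Returns the transform minimizing RMSD over all proper rotations and
    translations, plus the RMSD after applying it.

    Raises
    ------
    SuperpositionError
        If N < 3, shapes mismatch, or the point cloud is degenerate
        (collinear / rank < 2 after centering).
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise SuperpositionError("fixed and moving must be matching N×3 arrays")
    n = fixed.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {n}")

    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if (np.linalg.matrix_rank(x, tol=1e-9 * scale) < 2
            or np.linalg.matrix_rank(y, tol=1e-9 * scale) < 2):
        raise SuperpositionError("degenerate (collinear) point cloud")

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    transform = RigidTransform(rot, trans)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return transform, rmsd


def iterative_core_superpose(
    reference: ChainView,
    target: ChainView,
    pairing: list[tuple[str, str]],
    prune_cutoff: float = 2.0,
    max_iters: int = 50,
) -> SuperpositionResult:
    """Detect the common core by iterative Kabsch fitting and distance pruning.

    Parameters
    ----------
    pairing
        Initial residue correspondence as (reference residue id, target
        residue id) strings, e.g. from a global sequence alignment
        (see :func:`triadcore.sequence_analysis.alignment_residue_pairs`).
    prune_cutoff
        Post-fit Cα–Cα distance (Å) above which a pair is dropped each
        iteration.  All out-of-cutoff pairs are dropped at once.

    ``fraction_matched`` is reported relative to the *target* chain's residue
    count, in percent.
    """
    ref_ca = {r.residue_id: r.atom("CA") for r in reference.residues}
    tgt_ca = {r.residue_id: r.atom("CA") for r in target.residues}

    pairs = [
        (a, b)
        for a, b in pairing
        if ref_ca.get(a) is not None and tgt_ca.get(b) is not None
    ]
    if len(pairs) < 3:
        raise SuperpositionError(f"initial correspondence has {len(pairs)} Cα pairs (< 3)")
    if (len({a for a, _ in pairs}) != len(pairs)
            or len({b for _, b in pairs}) != len(pairs)):
        raise SuperpositionError("pairing is not one-to-one")

    seen: set[frozenset] = set()
    history: list[float] = []
    transform = RigidTransform.identity()
    rmsd = float("inf")
    for it in range(1, max_iters + 1):
        fixed = np.array([ref_ca[a].coords for a, _ in pairs])
        moving = np.array([tgt_ca[b].coords for _, b in pairs])
        transform, rmsd = kabsch_fit(fixed, moving)
        history.append(rmsd)
        dists = np.linalg.norm(transform.apply(moving) - fixed, axis=1)
        kept = [p for p, d in zip(pairs, dists) if d <= prune_cutoff]
        if len(kept) < 3:
            raise SuperpositionError(
                f"core shrank to {len(kept)} pairs at iteration {it} "
                f"(last good fit: {len(pairs)} pairs, rmsd {rmsd:.3f} Å)"
            )
        key = frozenset(kept)
        if kept == pairs or key in seen:  # fixed point / oscillation guard
            pairs = kept
            break
        seen.add(key)
        pairs = kept

    # Refit on the final pair set so transform/rmsd always describe `pairs`
    # (matters only if the loop stopped on the oscillation guard).
    fixed = np.array([ref_ca[a].coords for a, _ in pairs])
    moving = np.array([tgt_ca[b].coords for _, b in pairs])
    transform, rmsd = kabsch_fit(fixed, moving)
    fraction = 100.0 * len(pairs) / len(target.residues)
    return SuperpositionResult(
        transform=transform,
        pairs=pairs,
        rmsd=rmsd,
        fraction_matched=fraction,
        n_iterations=len(history),
        rmsd_history=history,
    )
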
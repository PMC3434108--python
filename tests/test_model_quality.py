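import math

import numpy as np
import pytest

from triadcore import (
    backbone_dihedrals,
    bond_geometry_rmsd,
    clashscore,
    make_ideal_sse,
    ramachandran_summary,
)
from triadcore.model_quality import (
    RamachandranSummary,
    dihedral_angle,
    load_rama_map,
    round_half_away,
)
from triadcore.structure_io import AtomRecord, ChainView, ResidueView, StructureModel
from triadcore.synthetic_data import apply_random_transform


def test_helix_dihedrals_recovered(ideal_helix):
    for d in backbone_dihedrals(ideal_helix)[1:-1]:
        assert d.phi == pytest.approx(-57.0, abs=1e-3)
        assert d.psi == pytest.approx(-47.0, abs=1e-3)
        assert abs(d.omega) == pytest.approx(180.0, abs=1e-3)


def test_terminal_dihedrals_undefined(ideal_helix):
    dihedrals = backbone_dihedrals(ideal_helix)
    assert dihedrals[0].phi is None and dihedrals[0].omega is None
    assert dihedrals[-1].psi is None


def test_cis_planar_dihedral_zero():
    # four coplanar points in a cis (U-shaped) arrangement
    assert dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)
    # and trans arrangement -> 180
    assert abs(dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])) == pytest.approx(180.0)


def test_chain_break_severs_dihedrals(ideal_strand):
    import copy

    broken = copy.deepcopy(ideal_strand)
    for res in broken.residues[4:]:
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([50.0, 0.0, 0.0])
    dihedrals = backbone_dihedrals(broken)
    assert dihedrals[3].psi is None  # link 4 -> 5 severed
    assert dihedrals[4].phi is None and dihedrals[4].omega is None


def test_dihedrals_invariant_under_rigid_transform(ideal_helix):
    model = StructureModel("H", "", [ideal_helix])
    moved, _ = apply_random_transform(model, seed=17)
    before = backbone_dihedrals(ideal_helix)
    after = backbone_dihedrals(moved.chains[0])
    for b, a in zip(before, after):
        if b.phi is not None:
            assert a.phi == pytest.approx(b.phi, abs=1e-6)
        if b.psi is not None:
            assert a.psi == pytest.approx(b.psi, abs=1e-6)


@pytest.mark.parametrize(
    "counts, expected",
    [
        # internally consistent published rows of the refinement table
        ({"most_favoured": 89, "additional_allowed": 21,
          "generously_allowed": 4, "disallowed": 3}, (76.1, 17.9, 3.4, 2.6)),
        ({"most_favoured": 62, "additional_allowed": 40,
          "generously_allowed": 1, "disallowed": 6}, (56.9, 36.7, 0.9, 5.5)),
        ({"most_favoured": 84, "additional_allowed": 33,
          "generously_allowed": 0, "disallowed": 0}, (71.8, 28.2, 0.0, 0.0)),
        ({"most_favoured": 86, "additional_allowed": 49,
          "generously_allowed": 0, "disallowed": 0}, (63.7, 36.3, 0.0, 0.0)),
    ],
)
def test_percentage_arithmetic_from_counts(counts, expected):
    summary = RamachandranSummary.from_counts(counts)
    assert tuple(summary.percentages.values()) == expected
    assert abs(sum(summary.percentages.values()) - 100.0) <= 0.2


def test_percentages_recompute_from_own_counts(ideal_helix):
    summary = ramachandran_summary(backbone_dihedrals(ideal_helix))
    again = RamachandranSummary.from_counts(summary.counts)
    assert again.percentages == summary.percentages


def test_alpha_core_fully_most_favoured(ideal_helix):
    summary = ramachandran_summary(backbone_dihedrals(ideal_helix))
    assert summary.percentages["most_favoured"] == 100.0
    assert summary.n_defined == 10  # 12 residues minus the two termini


def test_beta_core_most_favoured(ideal_strand):
    summary = ramachandran_summary(backbone_dihedrals(ideal_strand))
    assert summary.percentages["most_favoured"] == 100.0


def test_rama_map_well_formed():
    grid = load_rama_map()
    assert grid.shape == (36, 36)
    assert set(grid.ravel()) == {"M", "A", "G", "D"}


def test_round_half_away_from_zero():
    assert round_half_away(76.05, 1) == 76.1
    assert round_half_away(2.25, 1) == 2.3
    assert round_half_away(-2.25, 1) == -2.3
    assert round_half_away(71.84, 1) == 71.8


def _carbon_model(positions):
    residues = [
        ResidueView("ALA", i + 1, "", [AtomRecord("CA", "C", p)])
        for i, p in enumerate(positions)
    ]
    return StructureModel("C", "", [ChainView("A", residues)])


def test_clashscore_one_pair_in_100_atoms():
    # 100 isolated carbons on a sparse grid; exactly one pair overlaps by
    # 0.5 Å (> 0.4 threshold) and is far beyond covalent bonding range
    positions = [np.array([10.0 * i, 0.0, 0.0]) for i in range(99)]
    positions.append(positions[0] + np.array([2 * 1.70 - 0.5, 0.0, 0.0]))
    model = _carbon_model(positions)
    assert clashscore(model) == pytest.approx(10.0)


def test_clashscore_no_overlaps_zero(ideal_strand):
    assert clashscore(StructureModel("S", "", [ideal_strand])) == 0.0


def test_two_isolated_carbons_overlap_rule():
    d = 2 * 1.70 - 0.5
    model = _carbon_model([np.zeros(3), np.array([d, 0, 0])])
    assert clashscore(model) == pytest.approx(1000.0 / 2)
    nearly = _carbon_model([np.zeros(3), np.array([2 * 1.70 - 0.39, 0, 0])])
    assert clashscore(nearly) == 0.0


def test_clashscore_excludes_covalently_linked_atoms(ideal_helix):
    # bonded/1-3/1-4 backbone pairs are all well inside vdW overlap range
    # yet contribute no clashes
    assert clashscore(StructureModel("H", "", [ideal_helix])) == 0.0


def test_clashscore_invariances():
    positions = [np.array([10.0 * i, 0.0, 0.0]) for i in range(9)]
    positions.append(positions[0] + np.array([2 * 1.70 - 0.5, 0.0, 0.0]))
    model = _carbon_model(positions)
    base = clashscore(model)
    moved, _ = apply_random_transform(model, seed=23)
    assert clashscore(moved) == pytest.approx(base)
    # doubling with a far-away disjoint copy leaves the per-1000 score unchanged
    far = [p + np.array([0.0, 500.0, 0.0]) for p in positions]
    doubled = _carbon_model(positions + far)
    assert clashscore(doubled) == pytest.approx(base)


def test_bond_geometry_zero_on_ideal_fixture(helix_model):
    result = bond_geometry_rmsd(helix_model)
    assert result.length_rmsd == pytest.approx(0.0, abs=1e-12)
    assert result.angle_rmsd == pytest.approx(0.0, abs=1e-10)
    assert result.n_skipped_bonds == 0


def test_single_stretched_bond_closed_form(ideal_helix):
    import copy

    chain = copy.deepcopy(ideal_helix)
    last = chain.residues[-1]
    c, o = last.atom("C"), last.atom("O")
    direction = (o.coords - c.coords) / np.linalg.norm(o.coords - c.coords)
    o.coords = o.coords + 0.1 * direction  # stretch C=O, angles untouched
    result = bond_geometry_rmsd(StructureModel("H", "", [chain]))
    assert result.length_rmsd == pytest.approx(0.1 / math.sqrt(result.n_lengths))
    assert result.angle_rmsd == pytest.approx(0.0, abs=1e-9)


def test_perturbed_bonds_match_direct_recomputation(ideal_helix):
    # independent oracle: recompute the same backbone deviations directly
    import copy

    rng = np.random.default_rng(31)
    chain = copy.deepcopy(ideal_helix)
    for res in chain.residues:
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(0, 0.01, 3)
    result = bond_geometry_rmsd(StructureModel("H", "", [chain]))

    from triadcore.model_quality import STANDARD_BOND_LENGTHS

    devs = []
    res = chain.residues
    for i, r in enumerate(res):
        co = {a.name: a.coords for a in r.atoms}
        for pair in (("N", "CA"), ("CA", "C"), ("C", "O")):
            devs.append(np.linalg.norm(co[pair[0]] - co[pair[1]]) - STANDARD_BOND_LENGTHS[pair])
        if i + 1 < len(res):
            nxt = {a.name: a.coords for a in res[i + 1].atoms}
            devs.append(np.linalg.norm(co["C"] - nxt["N"]) - STANDARD_BOND_LENGTHS[("C", "N")])
    assert result.length_rmsd == pytest.approx(float(np.sqrt(np.mean(np.square(devs)))))
    assert result.length_rmsd == pytest.approx(0.012, abs=0.008)
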
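"""Contact enumeration, classification profiles and the cutoff scan."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ppaffinity.contacts import (
    ContactSet,
    compute_contacts,
    compute_contacts_brute_force,
    cutoff_scan,
    default_cutoff_grid,
    profile_contacts,
    residue_contributions,
)
from ppaffinity.structure import Structure
from ppaffinity.surface import compute_bsa
from ppaffinity.synthetic import (
    ToyComplexSpec,
    make_toy_complex,
    random_toy_complex,
)

from conftest import single_atom_residue, two_partner_structure


def _pair_structure(distance):
    a = single_atom_residue("A", 1, "K", (0.0, 0.0, 0.0))
    b = single_atom_residue("B", 1, "L", (distance, 0.0, 0.0))
    return two_partner_structure([a], [b])


def test_pair_below_cutoff_detected():
    assert len(compute_contacts(_pair_structure(4.0), 5.5)) == 1


def test_cutoff_boundary_is_strict():
    assert len(compute_contacts(_pair_structure(5.5), 5.5)) == 0


def test_contact_counts_once_per_residue_pair():
    # two atoms of the same residue both within cutoff -> still one pair
    a = single_atom_residue("A", 1, "K", (0.0, 0.0, 0.0))
    a.atoms.append(a.atoms[0].__class__(
        name="CB", element="C", coord=np.array([1.6, 0.0, 0.0])))
    b = single_atom_residue("B", 1, "L", (3.0, 0.0, 0.0))
    s = two_partner_structure([a], [b])
    cs = compute_contacts(s, 5.5)
    assert len(cs) == 1
    assert cs.pairs[(("A", 1, ""), ("B", 1, ""))] == pytest.approx(1.4)


@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force_oracle(seed):
    s = random_toy_complex(seed, max_residues_per_side=30)
    fast = compute_contacts(s, 5.5)
    slow = compute_contacts_brute_force(s, 5.5)
    assert set(fast.pairs) == set(slow.pairs)
    for key in fast.pairs:
        assert fast.pairs[key] == pytest.approx(slow.pairs[key], abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_pairs_monotone_in_cutoff(seed):
    s = random_toy_complex(seed + 50, max_residues_per_side=30)
    previous = set()
    for cutoff in (3.0, 4.5, 5.5, 7.0, 10.0):
        pairs = set(compute_contacts(s, cutoff).pairs)
        assert previous <= pairs
        previous = pairs


def test_rigid_transform_leaves_contacts_unchanged():
    s = random_toy_complex(99, max_residues_per_side=25)
    before = set(compute_contacts(s, 5.5).pairs)
    rot = Rotation.from_euler("xyz", [31.0, -57.0, 12.0], degrees=True)
    shift = np.array([13.0, -7.0, 5.0])
    for res in s.residues:
        for atom in res.atoms:
            new = rot.apply(atom.coord) + shift
            object.__setattr__(atom, "coord", new)
    assert set(compute_contacts(s, 5.5).pairs) == before


def test_empty_partner_rejected():
    s = _pair_structure(4.0)
    bad = Structure.__new__(Structure)
    bad.residues = s.partner_residues("A")
    bad.partner_of = {"A": "A", "B": "B"}
    bad.name = ""
    with pytest.raises(ValueError):
        compute_contacts(bad, 5.5)
    with pytest.raises(ValueError):
        compute_contacts(s, -1.0)


def _contact_set(structure, letter_pairs):
    by_pos = {}
    for i, (la, lb) in enumerate(letter_pairs):
        by_pos[(("A", i + 1, ""), ("B", i + 1, ""))] = 3.0
    return ContactSet(cutoff=5.5, pairs=by_pos)


def test_profile_counts_by_class():
    pairs = [("K", "L"), ("K", "S"), ("D", "E")]
    res_a = [single_atom_residue("A", i + 1, p[0], (i * 8.0, 0, 0))
             for i, p in enumerate(pairs)]
    res_b = [single_atom_residue("B", i + 1, p[1], (i * 8.0, 4, 0))
             for i, p in enumerate(pairs)]
    s = two_partner_structure(res_a, res_b)
    profile = profile_contacts(_contact_set(s, pairs), s)
    assert profile.ics_total == 3
    assert profile.polarity_counts["charged/apolar"] == 1
    assert profile.polarity_counts["charged/polar"] == 1
    assert profile.polarity_counts["charged/charged"] == 1


def test_empty_contact_set_gives_zero_profile(mixed_toy_complex):
    structure, _ = mixed_toy_complex
    profile = profile_contacts(ContactSet(cutoff=5.5, pairs={}), structure)
    assert profile.ics_total == 0
    assert all(v == 0 for v in profile.polarity_counts.values())


@pytest.mark.parametrize("scheme", ["polarity_counts", "hydropathy_counts"])
def test_class_counts_sum_to_total(mixed_toy_complex, scheme):
    structure, _ = mixed_toy_complex
    profile = profile_contacts(compute_contacts(structure), structure)
    assert sum(getattr(profile, scheme).values()) == profile.ics_total


def test_profile_matches_ground_truth(mixed_toy_complex):
    structure, truth = mixed_toy_complex
    profile = profile_contacts(compute_contacts(structure), structure)
    assert profile.polarity_counts == truth.polarity_counts
    assert profile.hydropathy_counts == truth.hydropathy_counts


def test_residue_holding_all_contacts_has_full_share():
    # one A residue contacts four B residues
    res_a = [single_atom_residue("A", 1, "K", (0.0, 0.0, 0.0))]
    res_b = [single_atom_residue("B", i + 1, "L",
                                 (3.5 * np.cos(t), 3.5 * np.sin(t), 0.0))
             for i, t in enumerate(np.linspace(0, 1.5, 4))]
    s = two_partner_structure(res_a, res_b)
    cs = compute_contacts(s, 5.5)
    assert len(cs) == 4
    surface = compute_bsa(s, n_points=240)
    contribs = residue_contributions(cs, surface, "A")
    lead = [c for c in contribs if c.residue_id == ("A", 1, "")][0]
    assert lead.ic_count == 4
    assert lead.ic_fraction == pytest.approx(100.0)


def test_contribution_fractions_sum_to_100(mixed_toy_complex):
    structure, _ = mixed_toy_complex
    cs = compute_contacts(structure)
    surface = compute_bsa(structure, n_points=240)
    for partner in ("A", "B"):
        contribs = residue_contributions(cs, surface, partner)
        assert sum(c.ic_fraction for c in contribs) == pytest.approx(100.0)
        assert sum(c.bsa_fraction for c in contribs) == pytest.approx(100.0)


def test_default_grid_follows_step_rule():
    grid = default_cutoff_grid()
    assert grid[0] == 3.0 and grid[-1] == 20.0
    assert len(grid) == 23
    fine = [c for c in grid if c <= 8.0]
    assert np.allclose(np.diff(fine), 0.5)
    coarse = [c for c in grid if c >= 8.0]
    assert np.allclose(np.diff(coarse), 1.0)


def _scan_set(slope=-0.2):
    structures = []
    for n_pairs in (3, 6, 9):
        spec = ToyComplexSpec(
            contact_pairs=["charged/apolar"] * n_pairs,
            spacing=25.0, contact_distance=1.6, seed=n_pairs)
        s, _ = make_toy_complex(spec, cutoff=3.0)
        structures.append((s, slope * n_pairs))
    return structures


def test_perfect_linear_relation_gives_r_minus_one():
    table = cutoff_scan(_scan_set(), cutoffs=[3.0, 5.5, 8.0, 20.0])
    assert np.allclose(table["r_pearson"], -1.0)
    assert np.allclose(table["s_spearman"], -1.0)


def test_degenerate_variance_reported_as_nan():
    structures = [(s, -5.0) for s, _ in _scan_set()]
    table = cutoff_scan(structures, cutoffs=[5.5])
    assert np.isnan(table["r_pearson"]).all()


def test_scan_requires_three_complexes():
    with pytest.raises(ValueError):
        cutoff_scan(_scan_set()[:2], cutoffs=[5.5])
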
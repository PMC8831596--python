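"""Holdout Q-factors and structural analytics: secondary structure, disorder,
pore profile, lateral portals, salt bridges."""

import math

import numpy as np
import pytest

from flexfold.nmr_restraints import DistanceRestraint
from flexfold.scoring import restraint_distances
from flexfold.structio import (
    Atom,
    Ensemble,
    Residue,
    Structure,
    SymmetryFrame,
    VDW_RADII,
    structure_from_ca,
)
from flexfold.synthetic import ideal_backbone_chain, restraints_from_bundle
from flexfold.validation import (
    assign_secondary_structure,
    disorder_fraction,
    holdout_split,
    lateral_portal_radius,
    place_amide_hydrogens,
    pore_profile,
    q_report,
    salt_bridge_distances,
)


def _dummy_restraints(n):
    return [DistanceRestraint((i + 1, "CA", 0), (i + 2, "CA", 0),
                              10.0, 8.0, 12.0, "PRE")
            for i in range(n)]


class TestHoldout:
    def test_ten_percent_of_560_is_56(self):
        working, free = holdout_split(_dummy_restraints(560), 0.1, seed=4)
        assert len(free) == 56
        assert len(working) == 504

    def test_same_seed_identical_split(self):
        rs = _dummy_restraints(40)
        a = holdout_split(rs, 0.25, seed=7)
        b = holdout_split(rs, 0.25, seed=7)
        assert [id(r) for r in a[1]] == [id(r) for r in b[1]]

    def test_disjoint_union(self, rng):
        for n, frac in ((17, 0.3), (101, 0.1), (8, 0.5)):
            rs = _dummy_restraints(n)
            working, free = holdout_split(rs, frac, seed=int(rng.integers(1e6)))
            assert len(working) + len(free) == n
            assert {id(r) for r in working}.isdisjoint({id(r) for r in free})

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            holdout_split(_dummy_restraints(10), 1.2)


class TestQReport:
    def test_truth_with_noiseless_restraints_is_zero(self, bundle, truth):
        rs = restraints_from_bundle(bundle)
        two_sided_pre = [r for r in rs if r.kind == "PRE" and r.two_sided]
        ens = Ensemble(models=[truth.structure])
        rep = q_report(ens, {"PRE": two_sided_pre,
                             "NOE": [r for r in rs if r.kind == "NOE"]})
        assert rep.q_pre < 1e-6
        assert rep.q_noe == 0.0  # satisfied bound-only NOEs contribute nothing

    def test_systematic_shift_matches_hand_arithmetic(self, truth):
        r = DistanceRestraint((10, "CA", 0), (40, "CA", 0),
                              0.0, 0.0, np.inf, "PRE", potential="sigmoid")
        d = restraint_distances(truth.structure, [r])[0]
        r_exact = DistanceRestraint((10, "CA", 0), (40, "CA", 0),
                                    float(d), float(d) - 1, float(d) + 1, "PRE",
                                    potential="sigmoid")
        shifted = truth.structure.copy()
        # move every copy of residue 40 CA by +2 Å along the A-chain pair axis
        for ch in shifted.chains:
            res = shifted.residue(ch, 40)
            a = shifted.residue(ch, 10).atoms["CA"].position
            b = res.atoms["CA"].position
            u = (b - a) / np.linalg.norm(b - a)
            res.atoms["CA"].position = b + 2.0 * u
        rep = q_report(Ensemble(models=[shifted]), {"PRE": [r_exact]})
        assert rep.q_pre == pytest.approx(2.0 / d, abs=5e-3)

    def test_free_set_only_counts_heldout(self, bundle, truth):
        rs = [r for r in restraints_from_bundle(bundle)
              if r.kind == "PRE" and r.two_sided]
        working, free = holdout_split(rs, 0.2, seed=1)
        rep = q_report(Ensemble(models=[truth.structure]), {"PRE": working}, free)
        assert rep.n_restraints["PRE_free"] == len(free)
        assert rep.q_pre_free < 1e-6


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_alpha(self):
        res = assign_secondary_structure(ideal_backbone_chain(16))
        labels = [res.labels["A"][i] for i in range(3, 14)]
        assert all(l == "H" for l in labels)

    def test_extended_chain_has_no_helix(self):
        res = assign_secondary_structure(
            ideal_backbone_chain(16, phi=-120, psi=120))
        assert all(l in ("C", "T") for l in res.labels["A"].values())
        assert not any(l in ("H", "G") for l in res.labels["A"].values())

    def test_three_ten_helix_is_g(self):
        res = assign_secondary_structure(
            ideal_backbone_chain(14, phi=-49, psi=-26))
        interior = [res.labels["A"][i] for i in range(4, 11)]
        assert all(l == "G" for l in interior)

    def test_invariant_under_rigid_motion(self):
        helix = ideal_backbone_chain(14)
        ref = assign_secondary_structure(helix)
        c, s = math.cos(1.1), math.sin(1.1)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = helix.transformed(R, np.array([13.0, -4.0, 7.0]))
        assert assign_secondary_structure(moved).labels == ref.labels

    def test_amide_h_geometry(self):
        helix = place_amide_hydrogens(ideal_backbone_chain(6))
        res = helix.residues["A"][2]
        d = np.linalg.norm(res.atoms["H"].position - res.atoms["N"].position)
        assert d == pytest.approx(1.01, abs=1e-6)


class TestDisorderFraction:
    def _assignment(self, labels):
        from flexfold.validation import SSAssignmentResult

        return SSAssignmentResult(labels={"A": dict(enumerate(labels, 1))})

    def test_all_helix_zero(self):
        assert disorder_fraction(self._assignment("H" * 10), (1, 10)) == 0.0

    def test_all_coil_one(self):
        assert disorder_fraction(self._assignment("C" * 10), (1, 10)) == 1.0

    def test_counting(self):
        assert disorder_fraction(self._assignment("HHGGTCCCHC"), (1, 10)) == \
            pytest.approx(0.5)  # 1 T + 4 C out of 10

    def test_ensemble_mean(self):
        a = self._assignment("H" * 10)
        b = self._assignment("C" * 10)
        assert disorder_fraction([a, b], (1, 10)) == pytest.approx(0.5)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            disorder_fraction(self._assignment("HH"), (5, 9))


def _ring_stack(ring_radius=5.0, vdw=1.7, n_rings=7, n_atoms=12, z_step=2.0):
    """Stack of atom rings around the z axis (a synthetic pore)."""
    residues = []
    num = 1
    for k in range(n_rings):
        z = k * z_step
        for j in range(n_atoms):
            ang = 2 * math.pi * j / n_atoms
            pos = np.array([ring_radius * math.cos(ang),
                            ring_radius * math.sin(ang), z])
            residues.append(Residue(num, "RNG", {
                "CA": Atom("CA", "C", pos, vdw)}))
            num += 1
    return Structure(chains=["A"], residues={"A": residues},
                     resolution_level="full-atom")


class TestPoreProfile:
    frame = SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    def test_ring_radius_minus_vdw(self):
        pore = _ring_stack(ring_radius=5.0, vdw=1.7)
        prof = pore_profile(pore, self.frame, z_range=(2.0, 10.0), step=1.0)
        ring_planes = prof.radii[::2]  # z = 2, 4, ... coincide with rings
        assert np.min(prof.radii) == pytest.approx(3.3, abs=0.05)
        assert np.all(ring_planes < 3.6)

    def test_clamped_when_no_atoms(self):
        pore = _ring_stack()
        prof = pore_profile(pore, self.frame, z_range=(100.0, 104.0),
                            step=2.0, clamp=15.0)
        assert np.all(prof.radii == 15.0)

    def test_radius_monotone_in_vdw(self):
        small = pore_profile(_ring_stack(vdw=1.5), self.frame,
                             z_range=(4.0, 8.0), step=2.0)
        large = pore_profile(_ring_stack(vdw=1.9), self.frame,
                             z_range=(4.0, 8.0), step=2.0)
        assert np.all(large.radii <= small.radii + 1e-6)

    def test_empty_z_range_rejected(self):
        with pytest.raises(ValueError):
            pore_profile(_ring_stack(), self.frame, z_range=(5.0, 5.0))


class TestLateralPortal:
    def _walled_pentamer(self, gap_radius):
        """Five wall slabs with gaps of a prescribed radius between them."""
        residues = {ch: [] for ch in "ABCDE"}
        num = 1
        for k, ch in enumerate("ABCDE"):
            base = 2 * math.pi * k / 5
            # each chain is an arc of atoms at radius 15, leaving a gap
            # centred between adjacent chains
            arc = 2 * math.pi / 5 - 2 * gap_radius / 15.0
            for j in range(24):
                for z in (-3.0, 0.0, 3.0):
                    ang = base + (j / 23.0 - 0.5) * arc
                    pos = np.array([15 * math.cos(ang), 15 * math.sin(ang), z])
                    residues[ch].append(Residue(num, "WAL", {
                        "CA": Atom("CA", "C", pos, 1.0)}))
                    num += 1
        return Structure(chains=list("ABCDE"), residues=residues,
                         resolution_level="full-atom")

    def test_drilled_gap_recovered(self):
        model = self._walled_pentamer(gap_radius=5.0)
        frame = SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r = lateral_portal_radius(model, ("A", "B"), girdle_z=-5.0,
                                  frame=frame)
        assert r == pytest.approx(4.0, abs=0.8)  # gap half-width minus vdw

    def test_occluded_interface_near_zero(self):
        model = self._walled_pentamer(gap_radius=0.3)
        frame = SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r = lateral_portal_radius(model, ("A", "B"), girdle_z=-5.0,
                                  frame=frame)
        assert r < 0.6

    def test_non_adjacent_chains_rejected(self):
        model = self._walled_pentamer(gap_radius=5.0)
        with pytest.raises(ValueError):
            lateral_portal_radius(model, ("A", "C"), girdle_z=-5.0)


class TestSaltBridges:
    def _arg_glu_pair(self, n_o_distance):
        arg = Residue(10, "ARG", {
            "CA": Atom("CA", "C", np.array([0.0, 0, 0])),
            "NH1": Atom("NH1", "N", np.array([2.0, 0, 0])),
            "NH2": Atom("NH2", "N", np.array([1.5, 1.5, 0])),
        })
        glu = Residue(20, "GLU", {
            "CA": Atom("CA", "C", np.array([8.0, 0, 0])),
            "OE1": Atom("OE1", "O", np.array([2.0 + n_o_distance, 0, 0])),
            "OE2": Atom("OE2", "O", np.array([2.0 + n_o_distance + 0.8, 0.5, 0])),
        })
        return Structure(chains=["A"], residues={"A": [arg, glu]},
                         resolution_level="full-atom")

    def test_constructed_distance_recovered(self):
        model = self._arg_glu_pair(2.8)
        (d,) = salt_bridge_distances(model, [(10, 20, "intra")])
        assert d == pytest.approx(2.8)

    def test_no_thresholding(self):
        model = self._arg_glu_pair(12.0)
        (d,) = salt_bridge_distances(model, [(10, 20, "intra")])
        assert d == pytest.approx(12.0)

    def test_missing_sidechain_flagged_none(self):
        model = structure_from_ca(np.array([[0.0, 0, 0], [8.0, 0, 0]]))
        (d,) = salt_bridge_distances(model, [(1, 2, "intra")])
        assert d is None
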
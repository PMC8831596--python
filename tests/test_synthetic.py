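"""Toy ground truth and forward models: determinism, geometry contracts and
zero-noise forward/inverse round trips."""

import math

import numpy as np
import pytest

from flexfold.esr_restraints import PENTAGON_RATIO, split_pentamer_modes
from flexfold.nmr_restraints import (
    compute_hetnoe,
    fit_relaxation_rate,
    rdc_from_ipap,
    temperature_coefficient,
)
from flexfold.sampler import ss_from_shifts
from flexfold.structio import ca_rmsd
from flexfold.synthetic import (
    AlignmentTensor,
    NoiseModel,
    SegmentPlan,
    build_toy_pentamer,
    forward_deer,
    forward_pre,
    forward_rdc,
    forward_relaxation,
    forward_shifts,
    forward_temp_and_noe,
    make_bundle,
    model_free_rates,
    restraints_from_bundle,
)


class TestBuildToyPentamer:
    def test_deterministic_and_exactly_c5(self, truth):
        again = build_toy_pentamer(seed=0)
        np.testing.assert_array_equal(again.subunit_coords, truth.subunit_coords)
        # exact C5: rotating chain A by 72° reproduces chain B to fp precision
        a = truth.structure.ca_coords(["A"])
        b = truth.structure.ca_coords(["B"])
        c, s = math.cos(2 * math.pi / 5), math.sin(2 * math.pi / 5)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        assert np.abs(a @ R.T - b).max() < 1e-9

    def test_helix_bonds_ideal(self, truth):
        x = truth.subunit_coords
        for i, num in enumerate(truth.residue_numbers[:-1]):
            if truth.ss.label(num) == "H" and truth.ss.label(num + 1) == "H":
                assert np.linalg.norm(x[i + 1] - x[i]) == pytest.approx(3.8,
                                                                        abs=0.01)

    def test_anchored_loop_touches_long_helix(self, truth):
        from scipy.spatial.distance import cdist

        x = truth.subunit_coords
        loop = [i for i, n in enumerate(truth.residue_numbers)
                if truth.ss.label(n) != "H"]
        ma = [i for i, n in enumerate(truth.residue_numbers)
              if truth.ss.label(n) == "H" and i > 30]
        assert cdist(x[loop], x[ma]).min() < 8.0

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError):
            build_toy_pentamer(SegmentPlan(segments=[("H", 10), ("L", 10),
                                                     ("H", 10)]))

    def test_order_parameters_follow_annotation(self, truth):
        for num in truth.residue_numbers:
            expected = 0.85 if truth.ss.label(num) == "H" else 0.30
            assert truth.order_parameters[num] == expected


class TestForwardPre:
    def test_distal_residues_unrestrained(self, truth, bundle):
        """Residues far from the label yield lower-bound-only restraints."""
        from flexfold.nmr_restraints import pre_table_to_restraints

        table = forward_pre(truth, 10, bundle.pre_params)
        site = truth.label_site(10)
        restraints = pre_table_to_restraints(table, (10, "LABEL", 0),
                                             bundle.pre_params)
        for (para, dia), r in zip(table, restraints):
            d = np.linalg.norm(
                truth.subunit_coords[truth.residue_numbers.index(para.residue)]
                - site)
            if d > 40.0:
                assert not np.isfinite(r.upper)  # no measurable broadening
            if d < 10.0:
                assert r.upper == bundle.pre_params.r_min_bound  # vanished

    def test_noiseless_round_trip_to_true_distances(self, bundle, truth):
        for r in restraints_from_bundle(bundle):
            if r.kind == "PRE" and r.has_target:
                key = ("PRE", r.site_a[0], r.site_b[0], r.site_b[2])
                assert abs(r.d0 - bundle.true_distances[key]) < 1e-6


class TestForwardDeer:
    def test_modes_at_pentagon_distances(self, truth):
        dist = forward_deer(truth, 52, width=2.0)
        modes = split_pentamer_modes(dist)
        d_adj = truth.structure and None  # readability
        adj = modes.adjacent[0]
        diag = modes.diagonal[0]
        assert diag / adj == pytest.approx(PENTAGON_RATIO, abs=0.03)

    def test_mode_positions_match_truth_table(self, bundle, truth):
        for res, dist in bundle.deer.items():
            modes = split_pentamer_modes(dist)
            assert modes.adjacent[0] == pytest.approx(
                bundle.true_distances[("DEER", res, 1)], abs=0.3)
            assert modes.diagonal[0] == pytest.approx(
                bundle.true_distances[("DEER", res, 2)], abs=0.5)

    def test_widths_recovered_within_ten_percent(self, truth):
        dist = forward_deer(truth, 52, width=2.5)
        modes = split_pentamer_modes(dist)
        assert modes.adjacent[1] == pytest.approx(2.5, rel=0.1)
        assert modes.diagonal[1] == pytest.approx(3.0, rel=0.1)  # 1.2x width


class TestForwardRelaxation:
    def test_rigid_residue_positive_hetnoe(self):
        _, _, noe = model_free_rates(1.0, 20e-12, 15e-9, 700.0)
        assert noe > 0.5

    def test_flexible_residue_negative_hetnoe(self):
        # fast sub-ns motion at the toy tumbling time drives the NOE negative
        _, _, noe = model_free_rates(0.2, 50e-12, 5e-9, 700.0)
        assert noe < 0.0

    def test_fit_recovers_generating_rates(self, truth):
        r1s, r2s, _ = forward_relaxation(truth)
        for series_list, idx in ((r1s, 0), (r2s, 1)):
            for series in series_list[:10]:
                num = series.residue
                expected = model_free_rates(
                    truth.order_parameters[num], truth.internal_times[num],
                    truth.tau_m, 700.0)[idx]
                fit = fit_relaxation_rate(series)
                assert fit.rate == pytest.approx(expected, rel=1e-6)

    def test_hetnoe_pairs_round_trip(self, truth):
        _, _, pairs = forward_relaxation(truth)
        for sat, unsat in pairs[:10]:
            num = sat.residue
            expected = model_free_rates(
                truth.order_parameters[num], truth.internal_times[num],
                truth.tau_m, 700.0)[2]
            assert compute_hetnoe(sat, unsat).noe == pytest.approx(expected,
                                                                   rel=1e-9)

    def test_loop_noes_below_helix_noes(self, truth):
        _, _, pairs = forward_relaxation(truth)
        noes = {s.residue: compute_hetnoe(s, u).noe for s, u in pairs}
        helix = [noes[n] for n in truth.residue_numbers
                 if truth.ss.label(n) == "H"]
        loop = [noes[n] for n in truth.residue_numbers
                if truth.ss.label(n) != "H"]
        assert np.mean(loop) < np.mean(helix)


class TestForwardRdc:
    def test_round_trip_to_generated_couplings(self, truth):
        records, quartets = forward_rdc(truth)
        for rec, quartet in zip(records, quartets):
            back = rdc_from_ipap(*quartet)
            assert back.d_hz == pytest.approx(rec.d_hz, abs=1e-9)

    def test_magic_angle_zero(self):
        tensor = AlignmentTensor(da_hz=10.0, rhombicity=0.0)
        magic = math.acos(1.0 / math.sqrt(3.0))
        v = np.array([math.sin(magic), 0.0, math.cos(magic)])
        assert tensor.rdc(v) == pytest.approx(0.0, abs=1e-9)

    def test_parallel_vector_gives_twice_da(self):
        tensor = AlignmentTensor(da_hz=10.0, rhombicity=0.3)
        assert tensor.rdc(np.array([0.0, 0.0, 1.0])) == pytest.approx(20.0)


class TestForwardTempAndNoe:
    def test_hbond_map_recovered_exactly(self, truth):
        series, _ = forward_temp_and_noe(truth)
        for num, pts in series.items():
            res = temperature_coefficient(pts)
            assert res.hbond_flag == truth.hbond_map[num]

    def test_helix_i_i3_contacts_present(self, truth):
        _, peaks = forward_temp_and_noe(truth)
        pairs = {(i, j) for i, j, _ in peaks}
        helix_runs = [n for n in truth.residue_numbers
                      if all(truth.ss.label(n + d) == "H" for d in range(4))]
        found = sum(1 for n in helix_runs if (n, n + 3) in pairs)
        assert found >= len(helix_runs) * 0.9

    def test_no_contact_beyond_cutoff(self, truth):
        _, peaks = forward_temp_and_noe(truth)
        x = truth.subunit_coords
        idx = {n: i for i, n in enumerate(truth.residue_numbers)}
        for i, j, _ in peaks:
            assert np.linalg.norm(x[idx[i]] - x[idx[j]]) < 5.5


class TestShiftAnnotationRoundTrip:
    def test_helices_recovered_from_shifts(self, truth):
        ann = ss_from_shifts(forward_shifts(truth))
        agree = sum(
            1 for n in truth.residue_numbers
            if (ann.labels[n] == "H") == (truth.ss.label(n) == "H"))
        assert agree >= 0.9 * len(truth.residue_numbers)


class TestMakeBundle:
    def test_byte_identical_for_same_seed(self, tmp_path):
        import json

        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_bundle(3, outdir=d1)
        make_bundle(3, outdir=d2)
        m1 = json.loads((d1 / "manifest.json").read_text())
        m2 = json.loads((d2 / "manifest.json").read_text())
        assert m1["files"] == m2["files"]
        assert len(m1["files"]) >= 8

    def test_manifest_checksums_verify(self, tmp_path):
        import hashlib
        import json

        out = tmp_path / "bundle"
        make_bundle(2, outdir=out)
        manifest = json.loads((out / "manifest.json").read_text())
        for name, digest in manifest["files"].items():
            assert hashlib.sha256(
                (out / name).read_bytes()).hexdigest() == digest

    def test_noise_seeds_recorded_and_effective(self):
        clean = make_bundle(1)
        noisy = make_bundle(1, noise=NoiseModel(intensity_cv=0.05, seed=1))
        p_clean = clean.pre_tables[10][5][0].intensity
        p_noisy = noisy.pre_tables[10][5][0].intensity
        assert p_clean != p_noisy
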
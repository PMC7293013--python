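import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from looprefine.ensemble_io import Ensemble, WeightSet
from looprefine.errors import StructureError, ValidationError
from looprefine.forward_models import (DEFAULT_KARPLUS, AlignmentTensor,
                                       KarplusCoefficients,
                                       assemble_bme_inputs,
                                       coupling_observable_rows,
                                       fit_alignment_tensor, karplus_coupling,
                                       load_karplus_table,
                                       noe_effective_distance,
                                       noe_observable_rows,
                                       rdc_observable_rows)
from looprefine.observables import Measurement, bind_selectors


class TestNoeEffectiveDistance:
    def test_single_frame_identity(self):
        assert noe_effective_distance([3.0], WeightSet.uniform(1)) == \
            pytest.approx(3.0)

    def test_two_frame_closed_form(self):
        r = noe_effective_distance([2.0, 4.0], WeightSet.uniform(2))
        expected = (0.5 * 2.0 ** -6 + 0.5 * 4.0 ** -6) ** (-1.0 / 6.0)
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(2.239, abs=2e-3)

    def test_degenerate_weights_pick_one_frame(self):
        assert noe_effective_distance([2.0, 4.0], WeightSet([1.0, 0.0])) == \
            pytest.approx(2.0)

    def test_bounds_and_below_linear_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = rng.uniform(2.0, 8.0, 6)
            w = WeightSet.from_unnormalized(rng.uniform(0.1, 1.0, 6))
            eff = noe_effective_distance(r, w)
            assert r.min() - 1e-12 <= eff <= r.max() + 1e-12
            assert eff <= float(w.weights @ r) + 1e-12

    def test_monotone_in_distances(self):
        w = WeightSet.uniform(3)
        base = noe_effective_distance([3.0, 4.0, 5.0], w)
        shorter = noe_effective_distance([2.5, 4.0, 5.0], w)
        assert shorter <= base

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValidationError):
            noe_effective_distance([2.0, 0.0], WeightSet.uniform(2))


class TestKarplus:
    @pytest.mark.parametrize("theta,expected_terms", [
        (0.0, lambda c: c.A + c.B + c.C),
        (90.0, lambda c: c.C),
        (180.0, lambda c: c.A - c.B + c.C),
    ])
    def test_closed_form_angles(self, theta, expected_terms):
        c = KarplusCoefficients(9.67, -2.03, 0.5, 0.0, "test")
        assert karplus_coupling(theta, c) == pytest.approx(expected_terms(c),
                                                           abs=1e-12)

    def test_phase_offset_shifts_angle(self):
        c = KarplusCoefficients(8.0, -1.0, 0.3, 30.0, "test")
        assert karplus_coupling(60.0, c) == pytest.approx(
            karplus_coupling(90.0, KarplusCoefficients(8.0, -1.0, 0.3)),
            abs=1e-12)

    def test_table_round_trip(self, tmp_path):
        path = tmp_path / "karplus.tsv"
        path.write_text("coupling_type\tA\tB\tC\tphase_deg\n"
                        "sugar_HH\t9.67\t-2.03\t0.0\t0.0\n")
        table = load_karplus_table(path)
        assert table["sugar_HH"].A == 9.67


class TestObservableRows:
    def test_noe_rows_are_rminus6(self, default_bundle, noisy_measurements):
        ensemble, _ = default_bundle
        noe = [m for m in noisy_measurements
               if m.observable_class == "noe_distance"][:5]
        mat = noe_observable_rows(ensemble, noe)
        assert mat.transform == "r_minus_6"
        idx = bind_selectors(noe, ensemble)
        i = idx[noe[0].selectors[0]]
        j = idx[noe[0].selectors[1]]
        d0 = np.linalg.norm(ensemble.coords[0, i] - ensemble.coords[0, j])
        assert mat.values[0, 0] == pytest.approx(d0 ** -6)

    def test_back_transform_matches_effective_distance(self, default_bundle,
                                                       noisy_measurements):
        ensemble, _ = default_bundle
        noe = [m for m in noisy_measurements
               if m.observable_class == "noe_distance"][:5]
        mat = noe_observable_rows(ensemble, noe)
        w = WeightSet.uniform(ensemble.n_frames)
        avg = mat.averages(w.weights)
        back = avg ** (-1.0 / 6.0)
        direct = [noe_effective_distance(
            mat.values[k] ** (-1.0 / 6.0), w) for k in range(len(noe))]
        np.testing.assert_allclose(back, direct, rtol=1e-12)

    def test_identical_frames_give_identical_coupling_columns(
            self, default_bundle, noisy_measurements):
        ensemble, _ = default_bundle
        coup = [m for m in noisy_measurements
                if m.observable_class == "scalar_coupling"]
        double = Ensemble(ensemble.atom_names, ensemble.res_names,
                          ensemble.res_ids, ensemble.chain_ids,
                          np.stack([ensemble.coords[0], ensemble.coords[0]]))
        mat = coupling_observable_rows(double, coup)
        np.testing.assert_allclose(mat.values[:, 0], mat.values[:, 1])

    def test_planar_cis_quadruplet_gives_a_plus_b_plus_c(self):
        atoms = [("C3'", (1.0, 1.0, 0.0)), ("O3'", (1.0, 0.0, 0.0)),
                 ("P", (2.0, 0.0, 0.0)), ("O5'", (2.0, 1.0, 0.0))]
        names = np.array([a for a, _ in atoms], dtype="U6")
        ens = Ensemble(names, np.full(4, "U", dtype="U4"),
                       np.ones(4, dtype=int), np.full(4, "A", dtype="U2"),
                       np.array([[xyz for _, xyz in atoms]], dtype=float))
        m = Measurement("j", "scalar_coupling",
                        ((1, "C3'"), (1, "O3'"), (1, "P"), (1, "O5'")),
                        5.0, 0.5, coupling_type="backbone_HCOP")
        mat = coupling_observable_rows(ens, [m])
        c = DEFAULT_KARPLUS["backbone_HCOP"]
        np.testing.assert_allclose(mat.values, [[c.A + c.B + c.C]],
                                   atol=1e-10)

    def test_empty_subsets_give_zero_rows(self, default_bundle):
        ensemble, _ = default_bundle
        assert coupling_observable_rows(ensemble, []).n_measurements == 0
        assert noe_observable_rows(ensemble, []).n_measurements == 0

    def test_rigid_motion_leaves_rows_unchanged(self, default_bundle,
                                                noisy_measurements):
        ensemble, _ = default_bundle
        rot = Rotation.random(random_state=5).as_matrix()
        moved = Ensemble(ensemble.atom_names, ensemble.res_names,
                         ensemble.res_ids, ensemble.chain_ids,
                         ensemble.coords[:3] @ rot.T + np.array([5., -3., 2.]))
        sub = Ensemble(ensemble.atom_names, ensemble.res_names,
                       ensemble.res_ids, ensemble.chain_ids,
                       ensemble.coords[:3])
        for rows_of in (noe_observable_rows, coupling_observable_rows):
            ms = [m for m in noisy_measurements if m.observable_class in
                  ("noe_distance", "scalar_coupling")]
            a = rows_of(sub, ms)
            b = rows_of(moved, ms)
            np.testing.assert_allclose(a.values, b.values, atol=1e-8)


def _rdc_measurements(values, sigma=1.0):
    bonds = [(2, "C1'", "H1'"), (3, "C4'", "C3'"), (4, "P", "O5'"),
             (5, "O4'", "C1'"), (10, "C5'", "C4'"), (11, "C2", "N3"),
             (12, "C6", "H6"), (13, "O3'", "C3'")]
    return [Measurement(f"rdc{k}", "rdc", ((r, a1), (r, a2)), float(v), sigma)
            for k, ((r, a1, a2), v) in enumerate(zip(bonds, values))]


class TestAlignmentTensor:
    def test_round_trip_recovers_tensor(self, default_bundle):
        ensemble, _ = default_bundle
        w = WeightSet.uniform(ensemble.n_frames)
        truth = AlignmentTensor.from_params([2.0, -3.0, 0.8, -0.5, 0.3])
        probe = _rdc_measurements(np.zeros(8))
        mat = rdc_observable_rows(ensemble, truth, probe)
        synthetic = _rdc_measurements(mat.averages(w.weights))
        fitted = fit_alignment_tensor(ensemble, w, synthetic)
        np.testing.assert_allclose(fitted.params, truth.params, atol=1e-8)
        refit_rows = rdc_observable_rows(ensemble, fitted, synthetic)
        chi2 = np.mean((refit_rows.averages(w.weights)
                        - np.array([m.value for m in synthetic])) ** 2)
        assert chi2 < 1e-16

    def test_zero_rdcs_give_zero_tensor(self, default_bundle):
        ensemble, _ = default_bundle
        w = WeightSet.uniform(ensemble.n_frames)
        fitted = fit_alignment_tensor(ensemble, w, _rdc_measurements(np.zeros(8)))
        np.testing.assert_allclose(fitted.params, np.zeros(5), atol=1e-12)

    def test_underdetermined_rejected(self, default_bundle):
        ensemble, _ = default_bundle
        w = WeightSet.uniform(ensemble.n_frames)
        with pytest.raises(ValidationError, match="underdetermined"):
            fit_alignment_tensor(ensemble, w, _rdc_measurements(np.zeros(8))[:4])

    def test_parallel_bonds_unidentifiable(self):
        # two atoms per residue, all bonds along z
        n_res = 6
        names, resids, coords = [], [], []
        for r in range(1, n_res + 1):
            names += ["C1'", "H1'"]
            resids += [r, r]
            coords += [[3.0 * r, 0.0, 0.0], [3.0 * r, 0.0, 1.1]]
        ens = Ensemble(np.array(names, dtype="U6"),
                       np.full(2 * n_res, "U", dtype="U4"),
                       np.array(resids), np.full(2 * n_res, "A", dtype="U2"),
                       np.array([coords], dtype=float))
        ms = [Measurement(f"r{k}", "rdc", ((k + 1, "C1'"), (k + 1, "H1'")),
                          1.0, 1.0) for k in range(n_res)]
        with pytest.raises(ValidationError, match="unidentifiable"):
            fit_alignment_tensor(ens, WeightSet.uniform(1), ms)

    def test_zero_tensor_predicts_zero(self, default_bundle):
        ensemble, _ = default_bundle
        mat = rdc_observable_rows(ensemble,
                                  AlignmentTensor(np.zeros((3, 3))),
                                  _rdc_measurements(np.zeros(8)))
        np.testing.assert_allclose(mat.values, 0.0)

    def test_axial_tensor_bond_along_z(self):
        s = 0.4
        tensor = AlignmentTensor(np.diag([-s / 2, -s / 2, s]))
        ens = Ensemble(np.array(["C1'", "H1'"], dtype="U6"),
                       np.array(["U", "U"], dtype="U4"), np.array([1, 1]),
                       np.array(["A", "A"], dtype="U2"),
                       np.array([[[0.0, 0.0, 0.0], [0.0, 0.0, 1.1]]]))
        m = Measurement("r", "rdc", ((1, "C1'"), (1, "H1'")), 0.0, 1.0)
        mat = rdc_observable_rows(ens, tensor, [m])
        assert mat.values[0, 0] == pytest.approx(s, abs=1e-12)

    def test_rotational_covariance(self, default_bundle):
        ensemble, _ = default_bundle
        sub = Ensemble(ensemble.atom_names, ensemble.res_names,
                       ensemble.res_ids, ensemble.chain_ids,
                       ensemble.coords[:2])
        tensor = AlignmentTensor.from_params([1.0, -0.5, 0.2, 0.4, -0.3])
        ms = _rdc_measurements(np.zeros(8))
        base = rdc_observable_rows(sub, tensor, ms)
        rot = Rotation.random(random_state=11).as_matrix()
        rotated = Ensemble(sub.atom_names, sub.res_names, sub.res_ids,
                           sub.chain_ids, sub.coords @ rot.T)
        co_tensor = AlignmentTensor(rot @ tensor.matrix @ rot.T)
        together = rdc_observable_rows(rotated, co_tensor, ms)
        np.testing.assert_allclose(together.values, base.values, atol=1e-10)

    def test_fit_optimality_against_random_tensors(self, default_bundle,
                                                   noisy_measurements):
        ensemble, _ = default_bundle
        w = WeightSet.uniform(ensemble.n_frames)
        rdcs = [m for m in noisy_measurements if m.observable_class == "rdc"]
        fitted = fit_alignment_tensor(ensemble, w, rdcs)
        y = np.array([m.value for m in rdcs])
        sig = np.array([m.sigma for m in rdcs])

        def chi2_of(t):
            rows = rdc_observable_rows(ensemble, t, rdcs)
            return np.sum(((rows.averages(w.weights) - y) / sig) ** 2)

        best = chi2_of(fitted)
        rng = np.random.default_rng(0)
        for _ in range(25):
            trial = AlignmentTensor.from_params(
                fitted.params + rng.normal(0.0, 0.3, 5))
            assert chi2_of(trial) >= best - 1e-9


class TestAssembly:
    def test_assembled_matrix_spaces_and_slices(self, default_bundle,
                                                noisy_measurements):
        ensemble, _ = default_bundle
        prior = WeightSet.uniform(ensemble.n_frames)
        inputs = assemble_bme_inputs(ensemble, noisy_measurements, prior)
        noe = inputs["slices"]["noe_distance"]
        assert (inputs["f_exp"][noe] > 0).all()
        noe_ms = [m for m in noisy_measurements
                  if m.observable_class == "noe_distance"]
        # targets transformed to r^-6 space
        assert inputs["f_exp"][noe][0] == pytest.approx(
            noe_ms[0].value ** -6)
        assert inputs["matrix"].shape[0] == len(noisy_measurements)
        assert inputs["tensor"] is not None
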
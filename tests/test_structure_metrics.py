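import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import hexagon_residue, make_conformation
from oracles import dihedral_reference, ermsd_reference

from looprefine.ensemble_io import WeightSet
from looprefine.errors import StructureError, ValidationError
from looprefine.structure_metrics import (assign_states, backbone_torsions,
                                          block_standard_error, dihedral,
                                          ermsd, ermsd_trajectory,
                                          population, ring_center,
                                          weighted_fes_2d)


def three_base_conformation(seed=0, names=("U", "A", "C")):
    rng = np.random.default_rng(seed)
    atoms = []
    for k in range(3):
        center = rng.normal(0.0, 4.0, 3) + [7.0 * k, 0, 0]
        normal = rng.normal(0.0, 1.0, 3)
        atoms += hexagon_residue(k + 1, center, normal=normal)
    return make_conformation(atoms, res_names={i + 1: n
                                               for i, n in enumerate(names)})


def rigid_copy(conf, seed=1):
    import copy

    rng = np.random.default_rng(seed)
    r = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
    t = rng.normal(0.0, 10.0, 3)
    out = copy.deepcopy(conf)
    out.coords = conf.coords @ r.T + t
    return out


class TestRingCenter:
    def test_hexagon_centroid_at_origin(self):
        conf = make_conformation(hexagon_residue(1, (0, 0, 0)))
        np.testing.assert_allclose(ring_center(conf, 1), [0, 0, 0],
                                   atol=1e-12)

    def test_translated_hexagon(self):
        conf = make_conformation(hexagon_residue(1, (1.0, -2.0, 3.0)))
        np.testing.assert_allclose(ring_center(conf, 1), [1, -2, 3],
                                   atol=1e-12)

    def test_missing_atom_named(self):
        atoms = [a for a in hexagon_residue(1, (0, 0, 0)) if a[1] != "C5"]
        conf = make_conformation(atoms)
        with pytest.raises(StructureError, match="C5"):
            ring_center(conf, 1)


class TestErmsd:
    def test_identity_is_zero(self):
        conf = three_base_conformation()
        assert ermsd(conf, conf) == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_invariance(self, seed):
        conf = three_base_conformation()
        moved = rigid_copy(conf, seed=seed)
        assert ermsd(moved, conf) < 1e-10

    @pytest.mark.parametrize("seed_a,seed_b", [(0, 5), (1, 6), (2, 9)])
    def test_matches_independent_gvector_oracle(self, seed_a, seed_b):
        a = three_base_conformation(seed=seed_a)
        b = three_base_conformation(seed=seed_b)
        assert ermsd(a, b) == pytest.approx(ermsd_reference(a, b), abs=1e-10)

    def test_symmetry_and_nonnegativity(self):
        a = three_base_conformation(seed=0)
        b = three_base_conformation(seed=7)
        assert ermsd(a, b) == pytest.approx(ermsd(b, a), abs=1e-12)
        assert ermsd(a, b) >= 0

    def test_base_count_mismatch(self):
        a = three_base_conformation()
        atoms = hexagon_residue(1, (0, 0, 0)) + hexagon_residue(2, (7, 0, 0))
        b = make_conformation(atoms)
        with pytest.raises(StructureError, match="mismatch"):
            ermsd(a, b)

    def test_trajectory_matches_per_frame(self, default_bundle):
        ensemble, truth = default_bundle
        vals = ermsd_trajectory(
            type(ensemble)(ensemble.atom_names, ensemble.res_names,
                           ensemble.res_ids, ensemble.chain_ids,
                           ensemble.coords[:4]), truth.template_a)
        for j in range(4):
            assert vals[j] == pytest.approx(
                ermsd(ensemble.frame(j), truth.template_a), abs=1e-12)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]) == \
            pytest.approx(180.0, abs=1e-10)

    @settings(derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 100_000))
    def test_matches_vector_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0.0, 3.0, (4, 3))
        # reject near-degenerate geometries the oracle cannot resolve
        if (np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[1])) < 1e-2
                or np.linalg.norm(np.cross(pts[2] - pts[1],
                                           pts[3] - pts[2])) < 1e-2):
            return
        ours = dihedral(*pts)
        ref = dihedral_reference(*pts)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_staggered_plus_60(self):
        # hand-built staggered quadruplet
        p0 = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), -1.0])
        quad = [p0, [0, 0, 0], [0, 0, 1.5], [1, 0, 2.5]]
        assert dihedral(*quad) == pytest.approx(
            dihedral_reference(*quad), abs=1e-8)
        assert abs(abs(dihedral(*quad)) - 60.0) < 1e-6

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0.0, 2.0, (4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-dihedral(*pts), abs=1e-8)


class TestBackboneTorsions:
    def test_terminal_residues_flagged_undefined(self, default_bundle):
        _, truth = default_bundle
        table = backbone_torsions(truth.template_a)
        assert np.isnan(table.loc[1, "alpha"])     # no O3' on residue 0
        assert np.isnan(table.loc[14, "epsilon"])  # no P on residue 15
        assert np.isfinite(table.loc[8, "zeta"])

    def test_torsions_rigid_motion_invariant(self, default_bundle):
        _, truth = default_bundle
        conf = truth.template_a
        moved = rigid_copy(conf, seed=4)
        a = backbone_torsions(conf)
        b = backbone_torsions(moved)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8,
                                   equal_nan=True)


class TestStates:
    def test_threshold_assignment_boundary_is_b(self):
        labels = assign_states(np.array([0.3, 0.7, 1.2]), 0.7)
        assert list(labels.labels) == ["A", "B", "B"]

    def test_all_zero_all_a_and_zero_threshold_all_b(self):
        assert set(assign_states(np.zeros(5), 0.7).labels) == {"A"}
        assert set(assign_states(np.zeros(5), 0.0).labels) == {"B"}

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            assign_states(np.array([-0.1, 0.5]))

    def test_population_sums_to_one(self):
        labels = assign_states(np.array([0.1, 0.9, 0.2, 1.5]))
        w = WeightSet.from_unnormalized(np.array([1.0, 2.0, 3.0, 4.0]))
        pa = population(labels, w, "A")
        pb = population(labels, w, "B")
        assert pa + pb == pytest.approx(1.0, abs=1e-15)
        assert pa == pytest.approx(0.4)

    def test_degenerate_weights(self):
        labels = assign_states(np.array([0.1, 1.5]))
        w = WeightSet(np.array([0.9, 0.1]))
        assert population(labels, w) == pytest.approx(0.9)


class TestFes:
    def test_single_occupied_bin(self):
        w = WeightSet.uniform(4)
        fes = weighted_fes_2d(np.zeros(4), np.zeros(4), w,
                              bins=[np.linspace(-1, 1, 4),
                                    np.linspace(-1, 1, 4)])
        assert fes.mask.sum() == 8
        filled = fes.values[~fes.mask]
        np.testing.assert_allclose(filled, [0.0])

    def test_two_bin_free_energy_difference(self):
        w = WeightSet(np.array([0.8, 0.2]))
        fes = weighted_fes_2d(np.array([-0.5, 0.5]), np.array([0.0, 0.0]), w,
                              bins=[np.array([-1.0, 0.0, 1.0]),
                                    np.array([-1.0, 1.0])])
        vals = fes.values[~fes.mask]
        assert np.max(vals) - np.min(vals) == pytest.approx(np.log(4),
                                                            abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 50))
        w = WeightSet.uniform(50)
        perm = rng.permutation(50)
        bins = [np.linspace(-3, 3, 7), np.linspace(-3, 3, 7)]
        a = weighted_fes_2d(x, y, w, bins=bins)
        b = weighted_fes_2d(x[perm], y[perm], w, bins=bins)
        np.testing.assert_allclose(a.values[~a.mask], b.values[~b.mask],
                                   atol=1e-12)
        assert (a.mask == b.mask).all()


class TestBlockStandardError:
    def test_constant_quantity_gives_zero(self):
        w = WeightSet.uniform(16)
        assert block_standard_error(np.full(16, 3.3), w) == pytest.approx(0.0)

    def test_zero_weight_block_rejected(self):
        w = WeightSet.from_unnormalized(
            np.concatenate([np.zeros(4), np.ones(12)]))
        with pytest.raises(ValidationError, match="zero total weight"):
            block_standard_error(np.arange(16.0), w, n_blocks=4)

    def test_iid_normal_tracks_sem(self):
        # Monte-Carlo check: the 4-block SE estimates sigma/sqrt(n) within
        # a factor two on average over many seeds
        n = 64
        w = WeightSet.uniform(n)
        ratios = []
        for seed in range(1000):
            x = np.random.default_rng(seed).normal(0.0, 1.0, n)
            se = block_standard_error(x, w, n_blocks=4)
            ratios.append(se / (1.0 / np.sqrt(n)))
        mean_ratio = np.mean(ratios)
        assert 0.5 < mean_ratio < 2.0
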
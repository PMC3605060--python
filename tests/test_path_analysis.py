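import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knotfold.chain_core import Conformation, Trajectory
from knotfold.knot_topology import ClosureSpec
from knotfold.path_analysis import (DensityProjection, MechanismConfig,
                                    PathRecord, classify_mechanism,
                                    density_projection, order_matrix,
                                    overlap_at_first_knot, path_record,
                                    path_similarity, sigma_distribution)


def record_from_order(order, contacts=None):
    """PathRecord whose contacts form in the given order (a permutation)."""
    order = np.asarray(order, dtype=float)
    contacts = contacts or tuple((0, i + 3) for i in range(len(order)))
    return PathRecord(trajectory_id="t", contacts=contacts,
                      formation_frames=order,
                      order_matrix=order_matrix(order))


class TestOrderMatrix:
    def test_strictly_increasing_frames(self):
        m = order_matrix([0, 1, 2])
        np.testing.assert_array_equal(
            m, [[1, 1, 1], [0, 1, 1], [0, 0, 1]])

    def test_all_ties_give_all_ones(self):
        np.testing.assert_array_equal(order_matrix([5, 5, 5]), np.ones((3, 3)))

    def test_permutation_case(self):
        m = order_matrix([2, 0, 1])
        expected = np.array([[1, 0, 0], [1, 1, 1], [1, 0, 1]])
        np.testing.assert_array_equal(m, expected)

    def test_never_formed_rank_last_and_tie(self):
        m = order_matrix([1, 2, None, None])
        assert m[0, 2] == 1 and m[2, 0] == 0  # formed precedes never-formed
        assert m[2, 3] == 1 and m[3, 2] == 1  # tie among never-formed

    def test_too_few_defined_rejected(self):
        with pytest.raises(ValueError):
            order_matrix([1, None, None])


class TestPathSimilarity:
    def test_identical_is_one(self):
        a = record_from_order([0, 1, 2, 3])
        assert path_similarity(a, a) == 1.0

    def test_reversed_strict_order_is_zero(self):
        a = record_from_order([0, 1, 2, 3])
        b = record_from_order([3, 2, 1, 0])
        assert path_similarity(a, b) == 0.0

    def test_single_transposition_hand_count(self):
        a = record_from_order([0, 1, 2, 3])
        b = record_from_order([1, 0, 2, 3])
        # exactly the (0,1)/(1,0) off-diagonal entries differ: 2/12
        assert path_similarity(a, b) == pytest.approx(5.0 / 6.0)

    def test_symmetry(self, rng):
        a = record_from_order(rng.permutation(6))
        b = record_from_order(rng.permutation(6))
        assert path_similarity(a, b) == path_similarity(b, a)

    def test_contact_set_mismatch_rejected(self):
        a = record_from_order([0, 1, 2])
        b = record_from_order([0, 1, 2],
                              contacts=((1, 5), (2, 6), (3, 7)))
        with pytest.raises(ValueError):
            path_similarity(a, b)

    @given(st.integers(min_value=0, max_value=2 ** 30))
    @settings(max_examples=40, deadline=None)
    def test_range_and_timing_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 50, size=7).astype(float)
        other = rng.integers(0, 50, size=7).astype(float)
        a, b = record_from_order(frames), record_from_order(other)
        sigma = path_similarity(a, b)
        assert 0.0 <= sigma <= 1.0
        # strictly increasing reparameterisation: order preserved
        warped = record_from_order(np.exp(frames / 10.0) + 3.0)
        assert path_similarity(warped, b) == pytest.approx(sigma)

    @given(st.integers(min_value=0, max_value=2 ** 30))
    @settings(max_examples=25, deadline=None)
    def test_triangle_inequality_on_strict_orders(self, seed):
        rng = np.random.default_rng(seed)
        a = record_from_order(rng.permutation(6))
        b = record_from_order(rng.permutation(6))
        c = record_from_order(rng.permutation(6))
        dab = 1 - path_similarity(a, b)
        dbc = 1 - path_similarity(b, c)
        dac = 1 - path_similarity(a, c)
        assert dac <= dab + dbc + 1e-12


class TestSigmaDistribution:
    def test_two_identical_paths_mass_at_one(self):
        a = record_from_order([0, 1, 2, 3])
        b = record_from_order([0, 1, 2, 3])
        sigmas, hist, edges = sigma_distribution([a, b], bins=10)
        assert sigmas.tolist() == [1.0]
        assert hist.sum() == pytest.approx(1.0)
        assert hist[-1] == pytest.approx(1.0)

    def test_three_paths_pairwise_values(self):
        paths = [record_from_order(o)
                 for o in ([0, 1, 2, 3], [1, 0, 2, 3], [3, 2, 1, 0])]
        sigmas, hist, _ = sigma_distribution(paths)
        expected = sorted([path_similarity(paths[i], paths[j])
                           for i, j in itertools.combinations(range(3), 2)])
        assert sorted(sigmas.tolist()) == pytest.approx(expected)
        assert len(sigmas) == 3

    def test_single_path_rejected(self):
        with pytest.raises(ValueError):
            sigma_distribution([record_from_order([0, 1, 2])])

    def test_random_permutation_mean_matches_monte_carlo_oracle(self):
        # mean sigma over random permutation pairs of 10 contacts
        rng = np.random.default_rng(7)
        paths = [record_from_order(rng.permutation(10)) for _ in range(20)]
        sigmas, _, _ = sigma_distribution(paths)
        oracle_rng = np.random.default_rng(8)
        oracle = []
        for _ in range(4000):
            p1 = oracle_rng.permutation(10)
            p2 = oracle_rng.permutation(10)
            m1 = order_matrix(p1.astype(float))
            m2 = order_matrix(p2.astype(float))
            off = ~np.eye(10, dtype=bool)
            oracle.append(1 - np.abs(m1.astype(int) - m2.astype(int))[off].sum()
                          / 90.0)
        se = np.std(oracle) / np.sqrt(len(sigmas))
        assert sigmas.mean() == pytest.approx(np.mean(oracle), abs=3 * se)


class TestOverlapAtFirstKnot:
    def test_knotting_at_final_native_frame(self, toy_native, fast_closure):
        n = toy_native.n_beads
        rod = Conformation(np.column_stack([3.8 * np.arange(n),
                                            np.zeros(n), np.zeros(n)]))
        traj = Trajectory([Conformation(rod.coords, frame_index=0),
                           Conformation(toy_native.reference.coords,
                                        frame_index=1)])
        ov = overlap_at_first_knot(traj, toy_native, fast_closure, seed=0)
        assert ov == pytest.approx(1.0)

    def test_never_knotting_returns_none(self, toy_native, fast_closure):
        n = toy_native.n_beads
        rod = Conformation(np.column_stack([3.8 * np.arange(n),
                                            np.zeros(n), np.zeros(n)]))
        traj = Trajectory([Conformation(rod.coords + k, frame_index=k)
                           for k in range(3)])
        assert overlap_at_first_knot(traj, toy_native, fast_closure,
                                     seed=0) is None


class TestDensityProjection:
    def test_repeated_frozen_frame_single_bin(self, toy_native):
        frame = toy_native.reference
        traj = Trajectory([Conformation(frame.coords, frame_index=k)
                           for k in range(7)])
        proj = density_projection([traj], toy_native, bins=10)
        counts = np.expm1(proj.log_counts)
        assert counts.sum() == pytest.approx(7.0)
        assert (counts > 0).sum() == 1

    def test_native_trajectory_mass_at_origin(self, toy_native):
        traj = Trajectory([Conformation(toy_native.reference.coords,
                                        frame_index=k) for k in range(3)])
        proj = density_projection([traj], toy_native, bins=5)
        ix, iy = np.unravel_index(np.argmax(proj.log_counts),
                                  proj.log_counts.shape)
        assert proj.x_edges[ix] < 0.5
        assert proj.y_edges[iy] < 0.5

    def test_region_forms_before_global(self, toy_native, rng):
        # two-stage fixture: the sheet region reaches native early while the
        # rest is still far -> y-marginal collapses before x does
        ref = toy_native.reference.coords
        regs = toy_native.annotated_regions
        region = [i for nm in ("sheet_a", "sheet_b")
                  for i in range(regs[nm][0], regs[nm][1] + 1)]
        other = np.array([i for i in range(len(ref)) if i not in region])
        frames = []
        scram = ref + rng.normal(0, 8.0, ref.shape)
        for k, lam_body in enumerate(np.linspace(0.0, 1.0, 8)):
            coords = scram.copy()
            coords[region] = ref[region]  # region native from the start
            coords[other] = scram[other] + lam_body * (ref[other] - scram[other])
            frames.append(Conformation(coords, frame_index=k))
        traj = Trajectory(frames)
        from knotfold.chain_core import kabsch_rmsd
        y = [kabsch_rmsd(f, toy_native.reference, subset=region)
             for f in frames]
        x = [kabsch_rmsd(f, toy_native.reference) for f in frames]
        assert y[0] < 2.0          # region formed from frame 0
        assert x[0] > 5.0          # global still unfolded then
        assert x[-1] < 1.0

    def test_empty_paths_rejected(self, toy_native):
        with pytest.raises(ValueError):
            density_projection([], toy_native)


class TestClassifyMechanism:
    # full closed-loop fixture tests live in test_synthetic_data /
    # test_acceptance; here: the unresolved contract
    def test_no_knotting_event_unresolved(self, toy_native, fast_closure):
        n = toy_native.n_beads
        rod = Conformation(np.column_stack([3.8 * np.arange(n),
                                            np.zeros(n), np.zeros(n)]))
        traj = Trajectory([Conformation(rod.coords + 0.1 * k, frame_index=k)
                           for k in range(12)])
        call = classify_mechanism(traj, toy_native, fast_closure, seed=1)
        assert call.label == "unresolved"
        assert call.first_knot_frame is None
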
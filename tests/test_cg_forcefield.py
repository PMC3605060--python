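import numpy as np
import pytest

from knotfold.chain_core import Conformation
from knotfold.cg_forcefield import (ForceFieldParams, build_forcefield,
                                    energy, energy_and_force, force,
                                    load_quasichemical_matrix)
from knotfold.contact_maps import ContactMapParams, build_native_structure

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def seq48(toy_native):
    rng = np.random.default_rng(3)
    return "".join(rng.choice(list(AA), toy_native.n_beads))


def small_native(n=10, seed=0):
    rng = np.random.default_rng(seed)
    coords = np.cumsum(
        3.8 * _unit_rows(rng.normal(size=(n, 3))), axis=0)
    return build_native_structure(Conformation(coords))


def _unit_rows(v):
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def straight_native(n):
    coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    return build_native_structure(Conformation(coords))


class TestBuildForcefield:
    def test_native_only_zeroes_nonnative_terms(self, toy_native, seq48, rng):
        ff = build_forcefield(toy_native, seq48, mode="native_only")
        x = toy_native.reference.coords + rng.normal(0, 1.0, (48, 3))
        e = energy(x, ff)
        assert e.quasichemical == 0.0
        assert e.electrostatic == 0.0

    def test_charge_sign_pattern(self):
        # KEKEK: alternating +1/-1 charges; like pairs repel, unlike attract
        native = straight_native(5)  # no native contacts on a rod
        ff = build_forcefield(native, "KEKEK", mode="with_nonnative")
        pairs = {tuple(p): q for p, q in zip(ff.nonnative_pairs,
                                             ff.charge_product)}
        assert pairs[(0, 4)] == 1.0   # K..K repulsive product
        assert pairs[(0, 3)] == -1.0  # K..E attractive product
        assert pairs[(1, 4)] == -1.0

    def test_native_well_minimum_at_reference(self, toy_native):
        ff = build_forcefield(toy_native)
        e_ref = energy(toy_native.reference, ff).native
        # stretch a single native pair by +1 A, everything else fixed:
        # evaluate the pair term directly on constructed two-bead geometry
        sigma = ff.native_sigma[0]
        eps = ff.params.native_eps

        def well(r):
            s = sigma / r
            return eps * (5 * s ** 12 - 6 * s ** 10)

        assert well(sigma) == pytest.approx(-eps)
        assert well(sigma) < well(sigma + 1.0)
        assert e_ref < 0.0

    def test_unknown_amino_acid_rejected(self, toy_native):
        with pytest.raises(ValueError, match="amino-acid"):
            build_forcefield(toy_native, "X" * toy_native.n_beads)

    def test_sequence_length_mismatch(self, toy_native):
        with pytest.raises(ValueError):
            build_forcefield(toy_native, "ACD")

    def test_quasichemical_matrix_symmetric(self):
        m = load_quasichemical_matrix()
        assert m.shape == (20, 20)
        np.testing.assert_allclose(m.values, m.values.T)


class TestEnergy:
    def test_breakdown_total_consistent(self, toy_native, seq48, rng):
        ff = build_forcefield(toy_native, seq48, mode="with_nonnative")
        x = toy_native.reference.coords + rng.normal(0, 0.5, (48, 3))
        e = energy(x, ff)
        parts = (e.bonded + e.native + e.quasichemical + e.electrostatic
                 + e.excluded_volume)
        assert e.total == pytest.approx(parts, rel=1e-9)

    def test_isolated_charge_pair_closed_form(self):
        # two +1 beads at r = debye length; neutralise all other couplings
        native = straight_native(6)
        p = ForceFieldParams(ev_eps=0.0, qc_scale=0.0)
        ff = build_forcefield(native, "KAAAAK", mode="with_nonnative",
                              params=p)
        lam = p.debye_length
        idx = np.where((ff.nonnative_pairs == [0, 5]).all(axis=1))[0][0]
        assert ff.charge_product[idx] == 1.0
        # place beads 0 and 5 at exactly lambda_D apart, far from the rest
        from knotfold.cg_forcefield import _pair_terms
        x = native.reference.coords.copy() + 500.0
        x[0] = [0.0, 0.0, 0.0]
        x[5] = [lam, 0.0, 0.0]
        el = _pair_terms(x, ff)["electrostatic"]
        v_pair = el[3][idx]
        assert v_pair == pytest.approx(
            p.coulomb_prefactor * np.exp(-1.0) / lam, rel=1e-12)
        # and decays to zero at large separation
        x[5] = [80 * lam, 0.0, 0.0]
        el = _pair_terms(x, ff)["electrostatic"]
        assert abs(el[3][idx]) < 1e-30

    def test_clash_capped_not_infinite(self, toy_native):
        ff = build_forcefield(toy_native)
        squeezed = toy_native.reference.coords * 0.05
        e = energy(squeezed, ff)
        assert np.isfinite(e.total)

    def test_native_only_equals_nonnative_with_zeroed_couplings(
            self, toy_native, seq48, rng):
        p = ForceFieldParams(qc_scale=0.0, coulomb_prefactor=0.0)
        ff_n = build_forcefield(toy_native, seq48, "native_only", params=p)
        ff_nn = build_forcefield(toy_native, seq48, "with_nonnative", params=p)
        x = toy_native.reference.coords + rng.normal(0, 1.0, (48, 3))
        assert energy(x, ff_n).total == pytest.approx(
            energy(x, ff_nn).total, rel=1e-12)


class TestForce:
    @pytest.mark.parametrize("mode", ["native_only", "with_nonnative"])
    def test_finite_difference_oracle(self, mode, rng):
        native = small_native(10)
        seq = "".join(np.random.default_rng(8).choice(list(AA), 10))
        ff = build_forcefield(native, seq, mode=mode)
        x = native.reference.coords + rng.normal(0, 0.4, (10, 3))
        f = force(x, ff)
        h = 1e-6
        for _ in range(25):
            i, d = rng.integers(10), rng.integers(3)
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            fd = -(energy(xp, ff).total - energy(xm, ff).total) / (2 * h)
            assert f[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_translation_invariance(self, toy_native, rng):
        ff = build_forcefield(toy_native)
        x = toy_native.reference.coords + rng.normal(0, 0.5, (48, 3))
        f1 = force(x, ff)
        f2 = force(x + np.array([11.0, -4.0, 2.5]), ff)
        np.testing.assert_allclose(f1, f2, atol=1e-9)
        # net force and torque vanish
        np.testing.assert_allclose(f1.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(x - x.mean(0), f1).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-8)

    def test_near_zero_nonbonded_force_at_reference(self, toy_native):
        ff = build_forcefield(toy_native)
        from knotfold.cg_forcefield import _pair_terms
        terms = _pair_terms(toy_native.reference.coords, ff)
        _, _, r, _, dv = terms["native"]
        # every native well sits at its minimum in the reference structure
        np.testing.assert_allclose(dv, 0.0, atol=1e-10)

    def test_second_order_energy_consistency(self, toy_native, rng):
        # <F, dx> matches -dE to second order for small random displacements
        ff = build_forcefield(toy_native)
        x = toy_native.reference.coords + rng.normal(0, 0.3, (48, 3))
        f = force(x, ff)
        for scale in (1e-4, 1e-5):
            dx = rng.normal(0, scale, (48, 3))
            de = energy(x + dx, ff).total - energy(x, ff).total
            # residual is the Hessian quadratic form: O(|dx|^2)
            assert de == pytest.approx(-(f * dx).sum(),
                                       abs=3e4 * scale ** 2)

    def test_kernel_matches_numpy_reference(self, toy_native, seq48, rng):
        from knotfold import _kernels
        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba unavailable")
        ff = build_forcefield(toy_native, seq48, mode="with_nonnative")
        x = toy_native.reference.coords + rng.normal(0, 1.2, (48, 3))
        e_k, f_k = energy_and_force(x, ff)
        f_n = force(x, ff, use_kernel=False)
        e_n = energy(x, ff, use_kernel=False)
        np.testing.assert_allclose(f_k, f_n, atol=1e-10)
        for name in ("bonded", "native", "quasichemical", "electrostatic",
                     "excluded_volume"):
            assert getattr(e_k, name) == pytest.approx(
                getattr(e_n, name), abs=1e-9)
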
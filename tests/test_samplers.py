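import numpy as np
import pytest
from scipy import stats

from knotfold.chain_core import Conformation
from knotfold.cg_forcefield import (ForceFieldParams, build_forcefield,
                                    energy)
from knotfold.contact_maps import (build_native_structure,
                                   collective_coordinate, native_overlap)
from knotfold.knot_topology import ClosureSpec, classify_conformation
from knotfold.samplers import (MoveSet, RatchetState, SamplerError,
                               bias_potential, denature, run_mc, run_rmd,
                               update_zm)


def dimer_ff(k=50.0, r0=3.8, n=3):
    """Chain with only harmonic bonds (all other couplings off)."""
    coords = np.column_stack([r0 * np.arange(n), np.zeros(n), np.zeros(n)])
    native = build_native_structure(Conformation(coords))
    params = ForceFieldParams(k_bond=k, k_angle=0.0, k_dihedral_1=0.0,
                              k_dihedral_3=0.0, native_eps=0.0, ev_eps=0.0,
                              qc_scale=0.0, coulomb_prefactor=0.0)
    return native, build_forcefield(native, params=params)


class TestBiasPotential:
    def test_below_reference_is_zero(self):
        s = RatchetState(k_R=3.0, z_m=5.0)
        assert bias_potential(4.0, s) == 0.0

    def test_at_reference_is_zero(self):
        s = RatchetState(k_R=3.0, z_m=5.0)
        assert bias_potential(5.0, s) == 0.0

    def test_harmonic_above_reference(self):
        s = RatchetState(k_R=3.0, z_m=5.0)
        assert bias_potential(7.0, s) == pytest.approx(6.0)  # (3/2)*4

    def test_continuity_at_reference(self):
        s = RatchetState(k_R=3.0, z_m=5.0)
        eps = 1e-9
        assert bias_potential(5.0 + eps, s) < 1e-15


class TestUpdateZm:
    def test_downward_always_accepted(self):
        s = RatchetState(z_m=5.0)
        assert update_zm(4.0, s, u=0.999999) == 4.0

    def test_zero_beta_always_accepts_backtracking(self):
        s = RatchetState(beta_tilde=0.0, z_m=5.0)
        assert update_zm(7.0, s, u=0.9999) == 7.0

    def test_infinite_beta_rejects_backtracking(self):
        s = RatchetState(beta_tilde=1e12, z_m=5.0)
        assert update_zm(7.0, s, u=0.001) == 5.0

    def test_quadratic_variant(self):
        s = RatchetState(k_R=2.0, beta_tilde=1.0, z_m=5.0,
                         quadratic_backtrack=True)
        # arg = (k_R/2)(dz)^2 = 1; accept iff exp(-1) >= u
        assert update_zm(6.0, s, u=np.exp(-1.0) - 1e-9) == 6.0
        s.z_m = 5.0
        assert update_zm(6.0, s, u=np.exp(-1.0) + 1e-9) == 5.0


class TestRunRmd:
    def test_zero_ratchet_bitwise_equals_unbiased(self, rich_native, toy_ff):
        t_unbiased = run_rmd(rich_native.reference, rich_native, toy_ff, None,
                             n_steps=300, dt=1e-3, seed=5, save_every=50)
        t_zero = run_rmd(rich_native.reference, rich_native, toy_ff,
                         RatchetState(k_R=0.0), n_steps=300, dt=1e-3, seed=5,
                         save_every=50)
        np.testing.assert_array_equal(t_unbiased.coords_array(),
                                      t_zero.coords_array())

    def test_zero_bias_force_whenever_z_at_or_below_zm(self, rich_native,
                                                       toy_ff):
        traj = run_rmd(rich_native.reference, rich_native, toy_ff,
                       RatchetState(k_R=50.0, beta_tilde=30.0),
                       n_steps=10000, dt=2e-3, seed=3, save_every=1000,
                       debug=True)
        dbg = traj.meta["debug"]
        # bias recorded BEFORE the z_m update of the same step
        z, zm, bias = dbg["z"], dbg["z_m"], dbg["bias_force_norm"]
        prev_zm = np.concatenate([[np.nan], zm[:-1]])
        at_or_below = np.isnan(prev_zm) | (z <= prev_zm)
        assert (bias[at_or_below] == 0.0).all()

    def test_monotone_zm_without_backtracking(self, rich_native, toy_ff):
        traj = run_rmd(rich_native.reference, rich_native, toy_ff,
                       RatchetState(k_R=50.0, beta_tilde=1e12),
                       n_steps=5000, dt=2e-3, seed=4, save_every=100,
                       debug=True)
        zm = traj.meta["debug"]["z_m"]
        assert (np.diff(zm) <= 1e-12).all()

    def test_hard_ratchet_keeps_cc_near_running_minimum(self, rich_native,
                                                        toy_ff):
        traj = run_rmd(rich_native.reference, rich_native, toy_ff,
                       RatchetState(k_R=2000.0, beta_tilde=1e12),
                       n_steps=10000, dt=2e-3, seed=6, save_every=100,
                       debug=True)
        z = traj.meta["debug"]["z"]
        zm = traj.meta["debug"]["z_m"]
        # z may exceed the running minimum only by the thermal scale of the
        # stiff ratchet: quantile check against the k_R -> inf oracle z == z_m
        excess = z - zm
        assert np.quantile(excess, 0.95) < np.sqrt(2.0 / 2000.0) * 10

    def test_fixed_seed_reproducible(self, rich_native, toy_ff):
        t1 = run_rmd(rich_native.reference, rich_native, toy_ff,
                     RatchetState(), n_steps=200, dt=1e-3, seed=11)
        t2 = run_rmd(rich_native.reference, rich_native, toy_ff,
                     RatchetState(), n_steps=200, dt=1e-3, seed=11)
        np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())

    def test_blowup_detected(self, rich_native, toy_ff):
        with pytest.raises(SamplerError, match="blow-up"):
            run_rmd(rich_native.reference, rich_native, toy_ff, None,
                    n_steps=5000, dt=1.0, seed=0)

    def test_unbiased_displacement_statistics(self):
        # free chain (no forces at all): displacement per step is pure noise
        native, ff = dimer_ff(k=0.0, n=5)
        dt, n_steps = 1e-3, 4000
        traj = run_rmd(native.reference, native, ff, RatchetState(k_R=0.0),
                       n_steps=n_steps, dt=dt, seed=9, save_every=1)
        disp = np.diff(traj.coords_array(), axis=0).ravel()
        sigma = np.sqrt(2.0 * dt)
        assert disp.mean() == pytest.approx(0.0, abs=4 * sigma / np.sqrt(disp.size))
        assert disp.std() == pytest.approx(sigma, rel=0.05)


class TestRunMc:
    def test_infinite_temperature_accepts_everything(self):
        native, ff = dimer_ff(k=0.0, n=5)
        traj = run_mc(native.reference, ff, MoveSet(cartesian_step=0.3,
                                                    p_crankshaft=0.0),
                      n_moves=2000, temperature=1e12, seed=1, tune=False)
        assert traj.meta["acceptance_rate"] == pytest.approx(1.0)

    def test_harmonic_dimer_variance(self):
        # stiff bond: radial Jacobian correction is negligible
        k, temperature = 50.0, 1.0
        native, ff = dimer_ff(k=k)
        traj = run_mc(native.reference, ff,
                      MoveSet(cartesian_step=0.3, p_crankshaft=0.0),
                      n_moves=100000, temperature=temperature, seed=2,
                      n_saved=2000, tune=False)
        lengths = np.array([f.bond_lengths()[0] for f in traj.frames[200:]])
        var = lengths.var(ddof=1)
        expected = temperature / (2.0 * k)  # E = k (r - r0)^2
        n_eff = len(lengths) / 8.0  # generous autocorrelation allowance
        se = expected * np.sqrt(2.0 / n_eff)
        assert abs(var - expected) < 3 * se

    def test_detailed_balance_boltzmann_bond_distribution(self):
        k, temperature = 50.0, 1.0
        native, ff = dimer_ff(k=k)
        traj = run_mc(native.reference, ff,
                      MoveSet(cartesian_step=0.3, p_crankshaft=0.0),
                      n_moves=100000, temperature=temperature, seed=3,
                      n_saved=1000, tune=False)
        lengths = np.array([f.bond_lengths()[0] for f in traj.frames[100::4]])
        r0 = 3.8

        # exact radial Boltzmann CDF p(r) ~ r^2 exp(-k (r-r0)^2 / T)
        grid = np.linspace(r0 - 1.5, r0 + 1.5, 4001)
        pdf = grid ** 2 * np.exp(-k * (grid - r0) ** 2 / temperature)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]

        def cdf_func(r):
            return np.interp(r, grid, cdf)

        res = stats.ks_1samp(lengths, cdf_func)
        assert res.pvalue > 0.01

    def test_freely_jointed_end_to_end(self):
        # pivot-only sampling of a 30-bead chain with rigid-ish bonds and no
        # other couplings: <R^2> = (N-1) b^2
        n, b = 30, 3.8
        native, ff = dimer_ff(k=400.0, n=n)
        moves = MoveSet(pivot_enabled=True, p_crankshaft=0.05,
                        cartesian_step=0.05, pivot_angle=np.pi)
        traj = run_mc(native.reference, ff, moves, n_moves=60000,
                      temperature=1.0, seed=4, n_saved=3000, tune=False)
        r2 = np.array([((f.coords[-1] - f.coords[0]) ** 2).sum()
                       for f in traj.frames[300:]])
        expected = (n - 1) * b ** 2
        assert r2.mean() == pytest.approx(expected, rel=0.05)

    def test_acceptance_autotuning(self, rich_native, toy_ff):
        moves = MoveSet(crankshaft_angle=3.0, cartesian_step=2.5,
                        target_acceptance=0.5)
        traj = run_mc(rich_native.reference, toy_ff, moves, n_moves=20000,
                      temperature=1.0, seed=5, burn_in=10000, n_saved=50)
        assert traj.meta["acceptance_rate"] == pytest.approx(0.5, abs=0.05)

    def test_ratcheted_mc_records_cc(self, rich_native, toy_ff):
        bias = RatchetState(k_R=20.0, beta_tilde=50.0)
        traj = run_mc(rich_native.reference, toy_ff, MoveSet(), n_moves=500,
                      seed=6, bias=bias, native=rich_native, n_saved=10)
        assert np.isfinite(traj.cc_value).all()


class TestDenature:
    def test_output_unknotted_and_unfolded(self, rich_native, toy_ff,
                                           fast_closure):
        conf = denature(rich_native, toy_ff, seed=42)
        assert native_overlap(conf, rich_native) < 0.3
        verdict = classify_conformation(conf, fast_closure, seed=0,
                                        do_scan=False)
        assert verdict.global_state == "unknot"

    def test_zero_high_steps_rejected(self, rich_native, toy_ff):
        with pytest.raises(SamplerError):
            denature(rich_native, toy_ff, n_high_steps=0)

    def test_distinct_seeds_distinct_outputs(self, rich_native, toy_ff):
        from knotfold.chain_core import kabsch_rmsd
        confs = [denature(rich_native, toy_ff, seed=s) for s in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert kabsch_rmsd(confs[i], confs[j]) > 0.5
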
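"""Pivot moves, Metropolis energetics, constraints, and sub-ensembles."""

import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from wlcbrush.chain import ChainParams, bending_energy, init_conformation
from wlcbrush.field import FieldGrid
from wlcbrush.oracles import bond_correlation_closed_form, joint_angle_cdf
from wlcbrush.sampler import (AzoConfig, BrushConfig, check_constraints,
                              delta_energy, field_energy, metropolis_accept,
                              pivot_move, propose, re_kink, sample_ensemble,
                              sample_free_chain, stream_seeds, switch_isomer)

from conftest import random_conformation


class TestPivotMove:
    def test_identity_rotation(self, straight):
        prop = pivot_move(straight, 3, [0, 0, 1.0], 0.0)
        assert np.allclose(prop.orientations, straight.orientations)
        assert np.allclose(prop.positions, straight.positions)

    def test_rodrigues_quarter_turn(self):
        # r=(1,0,0) about n=z by pi/2 -> (0,1,0)
        p = ChainParams(N=1.0, Nm=2)
        conf = init_conformation(p)
        conf.orientations[:] = [1.0, 0, 0]
        prop = pivot_move(conf, 1, [0, 0, 1.0], math.pi / 2)
        assert np.allclose(prop.orientations, [[0, 1.0, 0]] * 2, atol=1e-12)

    def test_inverse_rotation_round_trip(self, params, rng):
        conf = random_conformation(params, rng)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        fwd = pivot_move(conf, 5, axis, 0.811)
        back = pivot_move(fwd, 5, axis, -0.811)
        assert np.max(np.abs(back.positions - conf.positions)) < 1e-12

    def test_head_untouched_and_input_not_mutated(self, params, rng):
        conf = random_conformation(params, rng)
        snapshot = conf.orientations.copy()
        prop = pivot_move(conf, 8, [0, 0, 1.0], 1.0)
        assert np.array_equal(conf.orientations, snapshot)
        assert np.array_equal(prop.orientations[:7], conf.orientations[:7])
        assert np.array_equal(prop.graft_point, conf.graft_point)

    def test_non_unit_axis_rejected(self, straight):
        with pytest.raises(ValueError):
            pivot_move(straight, 1, [0, 0, 2.0], 0.3)


class TestPropose:
    def test_deterministic_given_stream(self, params, straight):
        a, ma = propose(straight, params, np.random.default_rng(42))
        b, mb = propose(straight, params, np.random.default_rng(42))
        assert np.array_equal(a.orientations, b.orientations)
        assert ma["pivot_index"] == mb["pivot_index"]

    def test_zero_cap_is_identity(self, params, straight, rng):
        prop, _ = propose(straight, params, rng, max_angle=0.0)
        assert np.allclose(prop.orientations, straight.orientations)

    def test_axis_isotropy(self, params, straight):
        rng = np.random.default_rng(7)
        axes = [propose(straight, params, rng)[1]["axis"]
                for _ in range(10_000)]
        mean = np.mean(axes, axis=0)
        assert np.linalg.norm(mean) < 0.05


class TestEnergies:
    def test_constant_field_energy(self, params, zero_field, straight):
        fg = FieldGrid(zero_field.z_edges, zero_field.orientation,
                       np.full_like(zero_field.omega, 1.7))
        assert field_energy(straight, fg, params) == pytest.approx(
            params.N * 1.7)

    def test_linear_field_single_bond_lookup(self, ogrid):
        p = ChainParams(N=1.0, Nm=2)
        conf = init_conformation(p)
        nz = 50
        fg = FieldGrid.zeros(nz, 2.0, ogrid)
        zc = fg.z_centers
        fg.omega[:] = zc[:, None]          # omega(z, u) = z
        # midpoints at z = 0.25 and 0.75
        assert field_energy(conf, fg, p) == pytest.approx(
            (0.25 + 0.75) * p.N / p.Nm, rel=1e-12)

    def test_delta_energy_matches_recomputation(self, params, zero_field,
                                                rng):
        zero_field.omega[:] = rng.random(zero_field.omega.shape)
        conf = init_conformation(params)
        prop, _ = propose(conf, params, rng, max_angle=0.5)
        dE = delta_energy(conf, prop, zero_field, params)
        recomputed = (bending_energy(prop, params)
                      - bending_energy(conf, params)
                      + field_energy(prop, zero_field, params)
                      - field_energy(conf, zero_field, params))
        assert dE == pytest.approx(recomputed, abs=1e-10)

    def test_uniform_field_cancels(self, params, zero_field, rng):
        fg = FieldGrid(zero_field.z_edges, zero_field.orientation,
                       np.full_like(zero_field.omega, 3.0))
        conf = init_conformation(params)
        prop = pivot_move(conf, params.Nm, [1.0, 0, 0], 0.4)
        assert delta_energy(conf, prop, fg, params) == pytest.approx(
            delta_energy(conf, prop, None, params), abs=1e-10)
        assert delta_energy(conf, conf, fg, params) == 0.0


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, rng) for _ in range(100))

    def test_infinite_never_accepted(self, rng):
        assert not any(metropolis_accept(np.inf, rng) for _ in range(100))

    def test_nan_raises(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), rng)

    def test_ln2_acceptance_rate(self):
        rng = np.random.default_rng(3)
        n = 100_000
        hits = sum(metropolis_accept(math.log(2.0), rng) for _ in range(n))
        # P = 1/2; 3 sigma of a binomial proportion
        assert abs(hits / n - 0.5) < 3 * 0.5 / math.sqrt(n)


class TestConstraints:
    def test_wall_violation(self, params, straight):
        brush = BrushConfig(sigma_eff=1.0)
        bent = pivot_move(straight, 1, [1.0, 0, 0], math.pi * 0.75)
        assert check_constraints(bent, brush) == "wall"
        assert check_constraints(straight, brush) == "ok"

    def test_compression_violation(self, params, straight):
        H = 0.5 * params.contour_length
        brush = BrushConfig(sigma_eff=1.0, compression_H=H)
        assert check_constraints(straight, brush) == "compression"
        tilted = pivot_move(straight, 1, [1.0, 0, 0], 1.2)
        if np.all(tilted.positions[1:, 2] < H):
            assert check_constraints(tilted, brush) == "ok"

    def test_graft_node_exempt(self, params, straight):
        # graft sits exactly at z = 0 and must not trip the wall test
        assert straight.positions[0, 2] == 0.0
        assert check_constraints(straight,
                                 BrushConfig(sigma_eff=1.0)) == "ok"


class TestAzo:
    def test_trans_is_plain_geometry(self, params, straight):
        brush = BrushConfig(sigma_eff=1.0, azo=AzoConfig(f=0.5))
        assert brush.azo.kink_angle == pytest.approx(0.0)
        assert brush.active_azo_index(params.Nm) == -1
        assert check_constraints(straight, brush) == "ok"

    def test_cis_kink_imposed_and_preserved(self, params, straight):
        brush = BrushConfig(sigma_eff=1.0, azo=AzoConfig(f=0.5, state="cis"))
        j = brush.azo.bond_index(params.Nm)
        kinked = re_kink(straight, brush)
        cosang = float(kinked.orientations[j - 1] @ kinked.orientations[j])
        assert cosang == pytest.approx(math.cos(2 * math.pi / 3), abs=1e-12)
        # a cone pivot (axis = preceding bond) preserves the kink exactly
        prop = pivot_move(kinked, j + 1, kinked.orientations[j - 1], 1.3)
        cos2 = float(prop.orientations[j - 1] @ prop.orientations[j])
        assert cos2 == pytest.approx(cosang, abs=1e-9)
        assert check_constraints(kinked, brush) == "ok"

    def test_cone_move_zero_azimuth_is_identity(self, params, straight):
        brush = BrushConfig(sigma_eff=1.0, azo=AzoConfig(f=0.5, state="cis"))
        kinked = re_kink(straight, brush)
        j = brush.azo.bond_index(params.Nm)
        same = pivot_move(kinked, j + 1, kinked.orientations[j - 1], 0.0)
        assert np.allclose(same.positions, kinked.positions)

    def test_azo_pivot_preserves_kink(self, params, straight, rng):
        from wlcbrush.sampler import azo_pivot
        brush = BrushConfig(sigma_eff=1.0, azo=AzoConfig(f=0.5, state="cis"))
        kinked = re_kink(straight, brush)
        j = brush.azo.bond_index(params.Nm)
        target = float(kinked.orientations[j - 1] @ kinked.orientations[j])
        for _ in range(20):
            kinked = azo_pivot(kinked, brush, rng)
            cosang = float(kinked.orientations[j - 1]
                           @ kinked.orientations[j])
            assert cosang == pytest.approx(target, abs=1e-9)
        with pytest.raises(ValueError):
            azo_pivot(straight, BrushConfig(sigma_eff=1.0), rng)

    def test_isomer_switch_round_trip(self, params, straight):
        brush = BrushConfig(sigma_eff=1.0, azo=AzoConfig(f=0.5, state="cis"))
        kinked = re_kink(straight, brush)
        back, b2 = switch_isomer(kinked, brush)
        assert b2.azo.state == "trans"
        assert check_constraints(back, b2) == "ok"


class TestRejectionEqualsInfiniteEnergy:
    def test_identical_chains_for_identical_seeds(self, params, zero_field):
        """Wall handling by rejection must equal an infinite-energy
        Metropolis rule, step by step for a shared variate stream."""
        brush = BrushConfig(sigma_eff=1.0)

        def run(mode, seed, n_steps=300):
            rng = np.random.default_rng(seed)
            conf = init_conformation(params)
            for _ in range(n_steps):
                prop, meta = propose(conf, params, rng, max_angle=1.0)
                violated = check_constraints(prop, brush) != "ok"
                dE = delta_energy(conf, prop, None, params)
                if mode == "reject":
                    ok = (not violated) and (
                        dE <= 0 or meta["accept_uniform"] < math.exp(-dE))
                else:
                    dE_eff = math.inf if violated else dE
                    ok = dE_eff <= 0 or (
                        math.isfinite(dE_eff)
                        and meta["accept_uniform"] < math.exp(-dE_eff))
                if ok:
                    conf = prop
            return conf

        a = run("reject", 11)
        b = run("infinite", 11)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.positions[0], np.zeros(3))  # graft exact


class TestEnsembles:
    def test_bit_reproducible(self, params, zero_field):
        brush = BrushConfig(sigma_eff=1.0)
        out = []
        for _ in range(2):
            dens, stats, _ = sample_ensemble(
                zero_field, params, brush, 400,
                seeds=stream_seeds(5, 0, 2), burn_in=10, stride=1.0)
            out.append((dens.rho.copy(), stats.counts.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])

    def test_errors_on_bad_inputs(self, params, zero_field):
        brush = BrushConfig(sigma_eff=1.0)
        with pytest.raises(ValueError):
            sample_ensemble(zero_field, params, brush, 10, seeds=[])
        with pytest.raises(ValueError):
            sample_ensemble(zero_field, params, brush, 1,
                            seeds=stream_seeds(0, 0, 4))

    def test_stream_split_statistically_equivalent(self, params, zero_field):
        """Pooled histograms from K=1 and K=4 sub-ensembles describe the
        same stationary distribution (chi-square on end-z counts)."""
        brush = BrushConfig(sigma_eff=1.0)
        _, s1, _ = sample_ensemble(zero_field, params, brush, 4000,
                                   seeds=stream_seeds(100, 0, 1),
                                   burn_in=50, stride=2.0)
        _, s4, _ = sample_ensemble(zero_field, params, brush, 4000,
                                   seeds=stream_seeds(200, 0, 4),
                                   burn_in=50, stride=2.0)
        h1, h4 = s1.endz, s4.endz
        keep = (h1 + h4) >= 10
        table = np.vstack([h1[keep], h4[keep]])
        _, p, _, _ = sp_stats.chi2_contingency(table)
        assert p > 0.01

    def test_ergodicity_burn_in_insensitivity(self, params, zero_field):
        """Free-end z profile from a straight start is stable when the
        burn-in is doubled (L1 difference of normalized histograms small)."""
        brush = BrushConfig(sigma_eff=1.0)
        dists = []
        for burn in (50, 100):
            _, st, _ = sample_ensemble(zero_field, params, brush, 6000,
                                       seeds=stream_seeds(3, burn, 3),
                                       burn_in=burn, stride=2.0)
            d = st.endz / st.endz.sum()
            dists.append(d)
        assert np.abs(dists[0] - dists[1]).sum() < 0.1


class TestFreeChainStatistics:
    def test_detailed_balance_joint_angle_ks(self):
        """Stationary single-joint angle density ~ exp(2 eps cos) sin."""
        p = ChainParams(N=5.0, Nm=20)
        ens = sample_free_chain(p, 20_000, stream_seeds(21, 0, 1),
                                burn_in=100, stride=8.0)
        pval = sp_stats.kstest(
            ens.joint_series(),
            lambda c: joint_angle_cdf(c, p.epsilon)).pvalue
        assert pval > 0.01

    def test_tangent_correlation_geometric_decay(self):
        """<u_i.u_{i+j}> ~ t^j recovers the closed-form t within 2%."""
        p = ChainParams(N=30.0, Nm=100)
        ens = sample_free_chain(p, 40_000, stream_seeds(8, 0, 4),
                                burn_in=100, stride=2.0)
        lags = np.array([1, 2, 3])
        vals = np.array([ens.bond_correlation(lag=j)[0] for j in lags])
        slope = np.polyfit(lags, np.log(vals), 1)[0]
        t_fit = math.exp(slope)
        t_ref = bond_correlation_closed_form(p.epsilon)
        assert abs(t_fit - t_ref) / t_ref < 0.02


class TestDiagnostics:
    def test_end_autocorrelation_time_reasonable(self, params, zero_field):
        brush = BrushConfig(sigma_eff=1.0)
        _, st, _ = sample_ensemble(zero_field, params, brush, 3000,
                                   seeds=stream_seeds(17, 0, 2),
                                   burn_in=50, stride=3.0)
        tau = st.end_autocorrelation_time()
        assert 0.4 < tau < 50.0
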
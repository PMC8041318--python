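"""Unit and property tests for the hTS coupled-equilibrium kinetics module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from folatekin import mechanism as mech
from folatekin.errors import FitError, InputError, ParameterDomainError

from conftest import random_condition, random_params


class TestRateLaw:
    def test_zero_inhibitor_is_michaelis_menten(self, mixed_params):
        p = mixed_params
        for s in (1.0, 10.0, 100.0):
            v = mech.rate_law(mech.AssayCondition(s=s), p)
            km = p.km_app(mech.DEFAULT_DUMP_UM)
            assert v == pytest.approx(p.Vmax * s / (km + s), rel=1e-12)

    def test_competitive_limit_vmax_independent_of_inhibitor(self):
        # with no non-productive ternary path (K6 -> inf), saturating
        # substrate restores Vmax at any inhibitor level: common intercepts
        p = mech.MechanismParams.from_apparent(km_app=20.0, vmax=1.0, ki=90.0)
        assert math.isinf(p.ki_prime())
        for i in (0.0, 50.0, 200.0):
            v = mech.rate_law(mech.AssayCondition(s=1e9, i=i), p)
            assert v == pytest.approx(p.Vmax, rel=1e-6)

    def test_monotone_decreasing_in_inhibitor(self, rng):
        for _ in range(50):
            p = random_params(rng)
            c = random_condition(rng)
            v_levels = [
                mech.rate_law(mech.AssayCondition(s=c.s, d=c.d, i=i), p)
                for i in (0.0, c.i, 2 * c.i)
            ]
            assert v_levels[0] >= v_levels[1] >= v_levels[2]
            assert all(v >= 0 for v in v_levels)

    def test_monotone_increasing_in_substrate(self, rng):
        for _ in range(50):
            p = random_params(rng)
            c = random_condition(rng)
            v_levels = [
                mech.rate_law(mech.AssayCondition(s=s, d=c.d, i=c.i), p)
                for s in (0.5 * c.s, c.s, 2 * c.s)
            ]
            assert v_levels[0] <= v_levels[1] <= v_levels[2]

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ParameterDomainError):
            mech.MechanismParams(K1=0, K2=1, K3=1, K4=1, K5=1, K6=1, Vmax=1)
        with pytest.raises(ParameterDomainError):
            mech.MechanismParams(K1=1, K2=1, K3=-2, K4=1, K5=1, K6=1, Vmax=1)


class TestSpeciesBalanceOracle:
    def test_no_inhibitor_no_inhibited_species(self, mixed_params):
        state, _ = mech.species_balance_oracle(
            mech.AssayCondition(s=10.0, i=0.0), mixed_params, total_enzyme=0.5
        )
        assert state.IiI == state.AAi == state.iAA == state.iAAs == 0.0

    def test_tracer_limit_matches_rate_law(self, mixed_params):
        p = mixed_params
        cond = mech.AssayCondition(s=10.0, i=40.0)
        e0 = 1e-6 * min(p.K1, p.K3, p.K4, p.K5)
        _, v_oracle = mech.species_balance_oracle(cond, p, total_enzyme=e0)
        v_closed = mech.rate_law(cond, p)
        assert v_oracle == pytest.approx(v_closed, rel=1e-3)

    def test_fractions_sum_to_one_random_draws(self, rng):
        for _ in range(100):
            p = random_params(rng)
            c = random_condition(rng)
            e0 = float(10.0 ** rng.uniform(-4, 0))
            state, v = mech.species_balance_oracle(c, p, total_enzyme=e0)
            assert state.total == pytest.approx(1.0, abs=1e-9)
            assert 0 <= state.AAs <= 1
            assert v >= 0

    def test_enzyme_depletion_lowers_rate_per_enzyme(self, mixed_params):
        # outside the tracer limit, ligand sequestration reduces the
        # fractional AAs occupancy relative to the closed form
        cond = mech.AssayCondition(s=10.0, i=40.0)
        _, v_tracer = mech.species_balance_oracle(
            cond, mixed_params, total_enzyme=1e-8
        )
        _, v_depleted = mech.species_balance_oracle(
            cond, mixed_params, total_enzyme=8.0
        )
        assert v_depleted < v_tracer


class TestSimulateRates:
    def test_zero_noise_on_the_rate_law(self, mixed_params):
        design = mech.fig_lr_design()
        ds = mech.simulate_rates(mixed_params, design, noise_cv=0.0, seed=1)
        for cond, v in zip(design, ds.data["rate"]):
            assert v == pytest.approx(mech.rate_law(cond, mixed_params))

    def test_standard_design_shape(self, mixed_params):
        ds = mech.simulate_rates(mixed_params, mech.fig_lr_design(), 0.05, seed=7)
        assert len(ds) == 20  # 4 inhibitor levels x 5 substrate levels
        assert sorted(ds.data["inhibitor_uM"].unique()) == [0.0, 25.0, 50.0, 100.0]
        assert ds.dump_uM == 140.0

    def test_seed_determinism(self, mixed_params):
        design = mech.fig_lr_design()
        a = mech.simulate_rates(mixed_params, design, 0.05, seed=11)
        b = mech.simulate_rates(mixed_params, design, 0.05, seed=11)
        assert a.data.equals(b.data)

    def test_empty_design_rejected(self, mixed_params):
        with pytest.raises(InputError):
            mech.simulate_rates(mixed_params, [], 0.0, seed=1)


class TestDoubleReciprocalFit:
    def test_competitive_common_intercepts(self, competitive_params):
        ds = mech.simulate_rates(
            competitive_params, mech.fig_lr_design(), 0.0, seed=1
        )
        fits = mech.double_reciprocal_fit(ds)
        intercepts = [f.intercept for f in fits.primary.values()]
        ref = intercepts[0]
        assert all(abs(b - ref) / ref < 1e-9 for b in intercepts)

    def test_mixed_intercepts_increase_with_inhibitor(self, mixed_params):
        ds = mech.simulate_rates(mixed_params, mech.fig_lr_design(), 0.0, seed=1)
        fits = mech.double_reciprocal_fit(ds)
        assert fits.intercept_line.slope > 0

    def test_record_order_invariance(self, mixed_params, rng):
        ds = mech.simulate_rates(mixed_params, mech.fig_lr_design(), 0.05, seed=5)
        shuffled = mech.RateDataset(
            ds.data.sample(frac=1.0, random_state=3).reset_index(drop=True),
            provenance=ds.provenance,
        )
        f1 = mech.double_reciprocal_fit(ds)
        f2 = mech.double_reciprocal_fit(shuffled)
        for lvl in f1.primary:
            assert f1.primary[lvl].slope == pytest.approx(f2.primary[lvl].slope)
            assert f1.primary[lvl].intercept == pytest.approx(
                f2.primary[lvl].intercept
            )

    def test_too_few_substrate_levels(self, mixed_params):
        design = mech.grid_design((5.0, 10.0), (0.0, 25.0))
        ds = mech.simulate_rates(mixed_params, design, 0.0, seed=1)
        with pytest.raises(FitError):
            mech.double_reciprocal_fit(ds)

    def test_zero_rate_records_excluded_with_warning(self, mixed_params):
        ds = mech.simulate_rates(mixed_params, mech.fig_lr_design(), 0.0, seed=1)
        df = ds.data.copy()
        df.loc[0, "rate"] = 0.0
        with pytest.warns(UserWarning, match="non-positive rate"):
            fits = mech.double_reciprocal_fit(mech.RateDataset(df))
        assert len(fits.primary) == 4


class TestClassifyAndExtract:
    def test_noise_free_competitive_recovery(self, competitive_params):
        ds = mech.simulate_rates(
            competitive_params, mech.fig_lr_design(), 0.0, seed=1
        )
        summary = mech.classify_and_extract(mech.double_reciprocal_fit(ds))
        assert summary.mode == "competitive"
        assert summary.Ki_app == pytest.approx(90.0, rel=1e-6)
        assert summary.Kiprime_app is None

    def test_noise_free_mixed_recovery(self, mixed_params):
        ds = mech.simulate_rates(mixed_params, mech.fig_lr_design(), 0.0, seed=1)
        summary = mech.classify_and_extract(mech.double_reciprocal_fit(ds))
        assert summary.mode == "mixed"
        assert summary.Ki_app == pytest.approx(40.0, rel=1e-6)
        assert summary.Kiprime_app == pytest.approx(44.0, rel=1e-6)

    def test_two_level_design_low_confidence(self, mixed_params):
        design = mech.grid_design(
            mech.DEFAULT_SUBSTRATE_LEVELS, (0.0, 40.0)
        )
        ds = mech.simulate_rates(mixed_params, design, 0.0, seed=1)
        summary = mech.classify_and_extract(mech.double_reciprocal_fit(ds))
        assert summary.mode == "mixed"  # i=40 at Ki'=44 shifts intercept ~90%
        assert summary.low_confidence

    def test_no_inhibition_detected(self, rng):
        # rates independent of inhibitor level: slope replot has slope ~ 0
        p = mech.MechanismParams.from_apparent(km_app=20.0, vmax=1.0, ki=1e12)
        ds = mech.simulate_rates(p, mech.fig_lr_design(), 0.0, seed=2)
        summary = mech.classify_and_extract(mech.double_reciprocal_fit(ds))
        assert summary.mode == "none"

    def test_stochastic_ki_recovery_median_within_10pct(self, mixed_params):
        recovered = []
        rng = np.random.default_rng(123)
        for _ in range(60):
            ds = mech.simulate_rates(
                mixed_params, mech.fig_lr_design(), noise_cv=0.05, seed=rng
            )
            s = mech.classify_and_extract(mech.double_reciprocal_fit(ds))
            if s.Ki_app is not None:
                recovered.append(s.Ki_app)
        assert abs(np.median(recovered) - 40.0) / 40.0 < 0.10


class TestInferMicroConstants:
    def test_peptide_path_k2(self):
        summary = mech.InhibitionSummary(mode="competitive", Ki_app=90.0)
        micro = mech.infer_micro_constants(summary, d_over_K1=15.0)
        assert micro.K2_est == pytest.approx(6.0)

    @pytest.mark.parametrize(
        "ki_app, k2_ref, inv34_expected, hmean_expected",
        [
            (38.0, 6.0, 0.01520468, 131.538),  # correction term 1/90
            (73.0, 95.0 / 15.0, 0.00317231, 630.456),  # correction term 1/95
        ],
    )
    def test_conjugate_path_reproduces_composite_terms(
        self, ki_app, k2_ref, inv34_expected, hmean_expected
    ):
        summary = mech.InhibitionSummary(mode="mixed", Ki_app=ki_app,
                                         Kiprime_app=44.0)
        micro = mech.infer_micro_constants(summary, K2_ref=k2_ref)
        assert micro.inv34 == pytest.approx(inv34_expected, rel=1e-4)
        assert micro.hmean34 == pytest.approx(hmean_expected, rel=1e-4)
        assert micro.hmean34 == pytest.approx(2.0 / micro.inv34)

    def test_interface_only_flagged_not_raised(self):
        summary = mech.InhibitionSummary(mode="competitive", Ki_app=90.0)
        micro = mech.infer_micro_constants(summary, K2_ref=6.0)
        assert micro.interface_only
        assert micro.hmean34 is None

    def test_missing_k2_ref_peptide_vs_conjugate(self):
        summary = mech.InhibitionSummary(mode="mixed", Ki_app=38.0,
                                         Kiprime_app=44.0)
        with pytest.raises(InputError):
            mech.infer_micro_constants(summary, K2_ref=-1.0)

    @given(
        k2=st.floats(1.0, 50.0),
        k3=st.floats(10.0, 1000.0),
        k4=st.floats(10.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composite_relation_roundtrip(self, k2, k3, k4):
        # build Ki_app from the composite relation and invert it again
        d_over_k1 = 15.0
        inv34_true = 1.0 / k3 + 1.0 / k4
        ki_app = 1.0 / (inv34_true + 1.0 / (d_over_k1 * k2))
        summary = mech.InhibitionSummary(mode="mixed", Ki_app=ki_app,
                                         Kiprime_app=44.0)
        micro = mech.infer_micro_constants(summary, K2_ref=k2)
        assert micro.inv34 == pytest.approx(inv34_true, rel=1e-9)


class TestFromApparent:
    @given(
        ki=st.floats(5.0, 500.0),
        kip=st.floats(5.0, 500.0),
        share=st.floats(0.0, 0.95),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exact_apparent_reconstruction(self, ki, kip, share):
        p = mech.MechanismParams.from_apparent(
            km_app=20.0, vmax=1.0, ki=ki, ki_prime=kip, interface_share=share
        )
        assert p.ki_app(mech.DEFAULT_DUMP_UM) == pytest.approx(ki, rel=1e-10)
        assert p.ki_prime() == pytest.approx(kip, rel=1e-10)
        assert p.km_app(mech.DEFAULT_DUMP_UM) == pytest.approx(20.0, rel=1e-10)
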
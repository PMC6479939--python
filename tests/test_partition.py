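"""Three-source partition arithmetic, fractionation profiles, regressions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paddyflux as pf
from paddyflux.isotopes import IsotopeMeasurement, Pool, Stage, Treatment
from paddyflux.partition import CarbonPools, round_half_away


class TestMassBalanceChain:
    def test_fertilizer_carbon_worked_example(self):
        # 10.24 g manure at 23.05% C -> 2.36 g C
        raw = pf.fertilizer_carbon(10.24, 0.2305)
        assert round_half_away(raw, 2) == 2.36
        assert pf.fertilizer_carbon(0.0, 0.9) == 0.0
        assert pf.fertilizer_carbon(100.0, 0.5) == 50.0

    def test_soil_carbon(self):
        # 20 kg topsoil at 1.78% total C (hand arithmetic)
        assert pf.soil_carbon(20000.0, 0.0178) == pytest.approx(356.0)
        assert pf.soil_carbon(0.0, 0.0178) == 0.0
        assert pf.soil_carbon(40000.0, 0.0178) == pytest.approx(712.0)

    def test_carbon_ratio(self):
        assert round_half_away(pf.carbon_ratio(2.36, 359.67), 2) == 0.66
        assert pf.carbon_ratio(0.0, 100.0) == 0.0
        assert pf.carbon_ratio(5.0, 5.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            pf.carbon_ratio(1.0, 0.0)

    def test_partition_sources_worked_chain(self):
        shares = pf.partition_sources(49.06, 0.66)
        assert shares.fertilizer_max == 0.34
        assert shares.soil_min == 50.60
        assert shares.photosynthesis == 49.06

    def test_partition_sources_edges(self):
        assert pf.partition_sources(100.0, 0.66) == pf.SourceShares(100.0, 0.0, 0.0)
        s = pf.partition_sources(49.06, 0.0)
        assert s.fertilizer_max == 0.0
        assert s.soil_min == pytest.approx(50.94)
        with pytest.raises(ValueError):
            pf.partition_sources(101.0, 0.5)

    def test_no_rounding_mode_is_exact(self):
        s = pf.partition_sources(49.06, 0.6561570328356549, digits=None)
        total = s.photosynthesis + s.fertilizer_max + s.soil_min
        assert total == pytest.approx(100.0, abs=1e-12)
        assert s.fertilizer_max == pytest.approx(50.94 * 0.6561570328356549 / 100)

    def test_full_chain_report(self):
        report = pf.three_source_partition(CarbonPools(), 49.06)
        assert report.fertilizer_c_g == 2.36
        assert report.carbon_ratio_percent == 0.66
        assert report.shares.fertilizer_max == 0.34
        assert report.shares.soil_min == 50.60

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=0.0, max_value=5.0),
    )
    def test_shares_sum_to_100(self, p_photo, ratio):
        s = pf.partition_sources(p_photo, ratio)
        assert s.photosynthesis + s.fertilizer_max + s.soil_min == pytest.approx(
            100.0, abs=0.02
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.0, max_value=99.0),
        st.floats(min_value=0.0, max_value=4.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_fertilizer_bound_monotone(self, p_photo, ratio, bump):
        base = pf.partition_sources(p_photo, ratio, digits=None)
        more_ratio = pf.partition_sources(p_photo, ratio + bump, digits=None)
        more_photo = pf.partition_sources(
            min(p_photo + bump, 100.0), ratio, digits=None
        )
        assert more_ratio.fertilizer_max >= base.fertilizer_max
        assert more_photo.fertilizer_max <= base.fertilizer_max


class TestPhotosynthesisShare:
    def test_end_member_cases(self):
        assert pf.photosynthesis_share(0.0, 0.0, 500.0, 0.0) == 0.0
        assert pf.photosynthesis_share(500.0, 0.0, 500.0, 0.0) == 100.0
        assert pf.photosynthesis_share(250.0, 0.0, 500.0, 0.0) == 50.0

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert pf.photosynthesis_share(600.0, 0.0, 500.0, 0.0) == 100.0

    def test_zero_source_excess_rejected(self):
        with pytest.raises(ValueError):
            pf.photosynthesis_share(10.0, 0.0, 5.0, 5.0)


def _profile_measurements(shares, total_excess=0.01, masses=None, ctl_delta=-25.0):
    """Construct labelled/control pairs whose 13C excess realises *shares*."""
    masses = masses or {
        Pool.CO2: 1.2,
        Pool.PLANT: 20.0,
        Pool.SOIL: 350.0,
        Pool.CH4: 0.05,
    }
    lab, ctl = [], []
    for pool, share in shares.items():
        mass = masses[pool]
        ap_ctl = pf.atom_percent_from_delta(ctl_delta)
        ap_lab = ap_ctl + share / 100.0 * total_excess / mass * 100.0
        x = ap_lab / 100.0
        delta_lab = pf.delta_from_ratio(x / (1 - x))
        common = dict(stage=Stage.TILLERING, day=27, replicate=1, pool=pool)
        lab.append(
            IsotopeMeasurement(
                treatment=Treatment.OY,
                delta_permil=delta_lab,
                pool_c_mass_g=mass,
                **common,
            )
        )
        ctl.append(
            IsotopeMeasurement(
                treatment=Treatment.ON,
                delta_permil=ctl_delta,
                pool_c_mass_g=mass,
                **common,
            )
        )
    return lab, ctl


class TestFractionationProfile:
    def test_single_pool_takes_all(self):
        planted = {Pool.CO2: 0.0, Pool.PLANT: 100.0, Pool.SOIL: 0.0, Pool.CH4: 0.0}
        prof = pf.fractionation_profile(*_profile_measurements(planted))
        assert prof.shares[Pool.PLANT] == pytest.approx(100.0, abs=1e-9)
        assert prof.shares[Pool.SOIL] == pytest.approx(0.0, abs=1e-9)

    def test_equal_excess_quarters(self):
        planted = {p: 25.0 for p in Pool}
        prof = pf.fractionation_profile(*_profile_measurements(planted))
        for p in Pool:
            assert prof.shares[p] == pytest.approx(25.0, abs=1e-9)

    def test_planted_shares_recovered(self):
        planted = {Pool.CO2: 30.0, Pool.PLANT: 60.0, Pool.SOIL: 2.0, Pool.CH4: 8.0}
        prof = pf.fractionation_profile(*_profile_measurements(planted))
        for pool, share in planted.items():
            assert prof.shares[pool] == pytest.approx(share, abs=1e-9)

    def test_invariant_to_common_mass_rescale(self):
        planted = {Pool.CO2: 30.0, Pool.PLANT: 60.0, Pool.SOIL: 2.0, Pool.CH4: 8.0}
        base_masses = {Pool.CO2: 1.2, Pool.PLANT: 20.0, Pool.SOIL: 350.0, Pool.CH4: 0.05}
        prof1 = pf.fractionation_profile(
            *_profile_measurements(planted, masses=base_masses)
        )
        scaled = {p: 3.0 * m for p, m in base_masses.items()}
        prof2 = pf.fractionation_profile(
            *_profile_measurements(planted, total_excess=0.03, masses=scaled)
        )
        for p in Pool:
            assert prof1.shares[p] == pytest.approx(prof2.shares[p], abs=1e-6)

    def test_missing_pool_rejected(self):
        lab, ctl = _profile_measurements({p: 25.0 for p in Pool})
        with pytest.raises(ValueError, match="missing pools"):
            pf.fractionation_profile(lab[:-1], ctl)


class TestFitLine:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = pf.fit_line(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.n == 5

    def test_permuted_response_has_null_slope(self, rng):
        x = rng.normal(0, 1, 50)
        y = 3 * x + rng.normal(0, 1, 50)
        fit = pf.fit_line(x, rng.permutation(y))
        assert abs(fit.slope) <= 3 * fit.slope_se + 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 2, 12)
            y = rng.normal(0, 5, 12)
            fit = pf.fit_line(x, y)
            # textbook normal equations, computed from raw sums
            n = len(x)
            sxx = np.sum(x * x) - np.sum(x) ** 2 / n
            sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
            slope = sxy / sxx
            intercept = (np.sum(y) - slope * np.sum(x)) / n
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_line([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pf.fit_line([1, 1, 1], [1, 2, 3])


class TestContributionCoefficient:
    @pytest.mark.parametrize("slope, k", [(6.00, 0.17), (0.08, 12.50), (1.0, 1.0)])
    def test_reciprocal_slopes(self, slope, k):
        assert pf.contribution_coefficient(slope) == k

    def test_accepts_regression_fit(self):
        x = np.arange(6.0)
        fit = pf.fit_line(x, 6.0 * x + 120.47)
        assert pf.contribution_coefficient(fit) == 0.17

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            pf.contribution_coefficient(0.0)

    def test_recovery_within_delta_method_se(self, rng):
        # y = a x + noise: 1/slope-hat should cover 1/a at ~2 SE
        a, n = 2.0, 20
        inside = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.uniform(0, 10, n)
            y = a * x + rng.normal(0, 2.0, n)
            fit = pf.fit_line(x, y)
            k_hat = pf.contribution_coefficient(fit, digits=None)
            se_k = fit.slope_se / fit.slope**2  # delta method
            if abs(k_hat - 1 / a) <= 2 * se_k:
                inside += 1
        assert inside / n_sim >= 0.9


def test_round_half_away_from_zero():
    assert round_half_away(0.335, 2) == 0.34
    assert round_half_away(-0.335, 2) == -0.34
    assert round_half_away(0.125, 2) == 0.13  # not banker's rounding
    assert round_half_away(2.36032, 2) == 2.36
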
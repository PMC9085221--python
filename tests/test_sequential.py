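"""Information-size arithmetic and sequential boundaries against oracles.

The two-look futility oracle integrates the bivariate normal law of the
Brownian-scale statistic exactly (scipy multivariate normal CDF), fully
independent of the package's recursive grid integration.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.stats import multivariate_normal

from decigene import (
    DesignError,
    LocusDesignConfig,
    alpha_spending,
    beta_spending,
    boundaries_for_schedule,
    build_design,
    comparator_proportion,
    design_boundaries,
    diversity_adjusted_is,
    evaluate_crossing,
    fixed_information_size,
    futility_boundaries,
    monitoring_boundaries,
    schedule_fractions,
)
from decigene.sequential import Z_CAP, _look_threshold


class TestComparatorProportion:
    def test_null_or_is_identity(self):
        assert comparator_proportion(0.27, 1.0) == pytest.approx(0.27)

    @pytest.mark.parametrize(
        "maf, or_, expected",
        [(0.38, 1.5, 0.57 / 1.19), (0.04, 1.5, 0.06 / 1.02)],
    )
    def test_hand_arithmetic(self, maf, or_, expected):
        assert comparator_proportion(maf, or_) == pytest.approx(expected, abs=1e-10)

    def test_odds_ratio_recovered(self):
        p_t = comparator_proportion(0.2, 2.5)
        implied = (p_t / (1 - p_t)) / (0.2 / 0.8)
        assert implied == pytest.approx(2.5, rel=1e-12)


class TestInformationSize:
    def test_published_calculator_value(self):
        # two-proportion normal-approximation size, p_c=0.38 vs p_t=0.4790
        p_t = comparator_proportion(0.38, 1.5)
        assert fixed_information_size(0.05, 0.8, 0.38, p_t) == 389

    def test_sample_size_diverges_as_effect_vanishes(self):
        sizes = [
            fixed_information_size(0.05, 0.8, 0.3, comparator_proportion(0.3, or_))
            for or_ in (2.0, 1.7, 1.5, 1.3, 1.15, 1.05)
        ]
        assert sizes == sorted(sizes)
        assert sizes[-1] > 50 * sizes[0] / 10  # steep growth near the null

    def test_equal_proportions_rejected(self):
        with pytest.raises(DesignError):
            fixed_information_size(0.05, 0.8, 0.3, 0.3)

    @pytest.mark.parametrize("d2, factor", [(0.0, 1), (0.8, 5)])
    def test_diversity_adjustment_exact(self, d2, factor):
        assert diversity_adjusted_is(389, d2) == 389 * factor

    def test_ris_monotone_in_d2(self):
        rises = [diversity_adjusted_is(400, d2) for d2 in (0.0, 0.2, 0.5, 0.8, 0.9)]
        assert rises == sorted(rises)

    def test_ris_grows_as_maf_falls_below_030(self):
        sizes = [
            fixed_information_size(0.05, 0.8, maf, comparator_proportion(maf, 1.5))
            for maf in (0.30, 0.25, 0.20, 0.15, 0.10, 0.05)
        ]
        assert sizes == sorted(sizes)

    def test_build_design_resolves_config(self):
        cfg = LocusDesignConfig(locus_id="rs1", maf=0.38)
        d = build_design(cfg)
        assert d.n_fixed == 389
        assert d.ris == 1945
        assert d.p_t == pytest.approx(0.57 / 1.19)

    def test_estimate_mode_requires_d2(self):
        cfg = LocusDesignConfig(locus_id="rs1", maf=0.38, heterogeneity_mode="estimate")
        with pytest.raises(DesignError):
            build_design(cfg)
        assert build_design(cfg, estimated_d2=0.5).ris == diversity_adjusted_is(389, 0.5)


class TestSpending:
    def test_boundary_conditions(self):
        assert alpha_spending(1.0, 0.05) == pytest.approx(0.05)
        assert alpha_spending(1e-9, 0.05) < 1e-12

    def test_half_information_value(self):
        # 2 * (1 - Phi(1.95996 / sqrt(0.5)))
        assert alpha_spending(0.5, 0.05) == pytest.approx(0.00556, abs=5e-5)

    def test_monotone_in_t(self):
        ts = np.linspace(0.05, 1.0, 30)
        vals = [alpha_spending(t, 0.05) for t in ts]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_beta_spending_exhausts_budget(self):
        assert beta_spending(1.0, 0.2) == pytest.approx(0.2)
        assert beta_spending(0.3, 0.2) < beta_spending(0.7, 0.2)


class TestMonitoringBoundaries:
    def test_single_look_reduces_to_fixed_sample(self):
        b = monitoring_boundaries([1.0], 0.05)
        assert b.monitor_upper[0] == pytest.approx(1.9600, abs=1e-3)
        assert b.spent_alpha[0] == pytest.approx(0.05, abs=1e-4)

    def test_two_equal_looks_match_published_tables(self):
        b = monitoring_boundaries([0.5, 1.0], 0.05)
        assert b.monitor_upper[0] == pytest.approx(2.963, abs=2e-3)
        assert b.monitor_upper[1] == pytest.approx(1.969, abs=2e-3)

    def test_five_equal_looks_match_published_tables(self):
        b = monitoring_boundaries([0.2, 0.4, 0.6, 0.8, 1.0], 0.05)
        published = [4.8769, 3.3569, 2.6803, 2.2898, 2.0310]
        assert list(b.monitor_upper) == pytest.approx(published, abs=2e-3)

    def test_spending_account_balances(self):
        b = monitoring_boundaries([0.25, 0.5, 0.75, 1.0], 0.05)
        assert b.spent_alpha[-1] == pytest.approx(0.05, abs=1e-4)
        assert list(b.spent_alpha) == sorted(b.spent_alpha)

    @given(
        st.lists(
            st.floats(0.1, 1.0), min_size=1, max_size=6, unique=True
        ).map(sorted)
    )
    def test_thresholds_non_increasing_on_separated_grids(self, fractions):
        # consecutive looks closer than 0.08 in information can locally raise
        # the Z threshold (the Brownian-scale boundary always rises while
        # sqrt(t) barely grows); monotonicity is a well-separated-look property
        sep = [fractions[0]]
        for t in fractions[1:]:
            if t - sep[-1] >= 0.08:
                sep.append(t)
        fractions = sep
        if fractions[-1] < 1.0 and 1.0 - fractions[-1] < 0.08:
            fractions[-1] = 1.0
        elif fractions[-1] < 1.0:
            fractions = fractions + [1.0]
        b = monitoring_boundaries(fractions, 0.05)
        uppers = list(b.monitor_upper)
        assert all(b2 <= a + 1e-6 for a, b2 in zip(uppers, uppers[1:]))
        assert all(u > 0 for u in uppers)
        assert b.monitor_lower == tuple(-u for u in uppers)

    def test_non_increasing_fractions_rejected(self):
        with pytest.raises(DesignError):
            monitoring_boundaries([0.5, 0.5, 1.0])
        with pytest.raises(DesignError):
            monitoring_boundaries([0.8, 0.4])
        with pytest.raises(DesignError):
            monitoring_boundaries([])


def futility_two_look_oracle(alpha=0.05, power=0.8):
    """Exact two-look inner-wedge values via the bivariate normal CDF."""
    beta = 1.0 - power
    theta = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    # cumulative type-II spend at t = 0.5: halved-budget OF shape, doubled
    b1 = 4.0 * stats.norm.sf(stats.norm.ppf(1 - beta / 4) / math.sqrt(0.5))
    l1 = theta * 0.5 + math.sqrt(0.5) * stats.norm.ppf(b1)
    mean = [theta * 0.5, theta]
    cov = [[0.5, 0.5], [0.5, 1.0]]

    def spent2(l2):
        # P(S1 > l1, S2 <= l2) = P(S2 <= l2) - P(S1 <= l1, S2 <= l2)
        return stats.norm.cdf(l2 - theta) - multivariate_normal.cdf(
            [l1, l2], mean=mean, cov=cov
        )

    l2 = optimize.brentq(lambda l: spent2(l) - (beta - b1), -5, 5, xtol=1e-10)
    return l1 / math.sqrt(0.5), l2


class TestFutilityBoundaries:
    def test_two_looks_match_exact_bivariate_oracle(self):
        f = futility_boundaries([0.5, 1.0], 0.05, 0.8)
        z1, z2 = futility_two_look_oracle()
        assert f.futility_upper[0] == pytest.approx(z1, abs=2e-3)
        assert f.futility_upper[1] == pytest.approx(z2, abs=2e-3)
        assert f.futility_lower[0] == pytest.approx(-z1, abs=2e-3)
        assert f.spent_beta[-1] == pytest.approx(0.2, abs=1e-4)

    def test_wedge_closes_onto_monitoring_boundary(self):
        d = design_boundaries([0.5, 1.0], 0.05, 0.8)
        assert abs(d.futility_upper[-1] - d.monitor_upper[-1]) < 0.05

    def test_higher_power_lowers_the_wedge_at_interim_looks(self):
        # at the final look closure pins the wedge near z_{1-alpha/2} for any
        # power, so the declaring-futility-gets-harder effect is interim-only
        lo = futility_boundaries([0.5, 0.7, 0.85, 1.0], 0.05, 0.80)
        hi = futility_boundaries([0.5, 0.7, 0.85, 1.0], 0.05, 0.95)
        compared = 0
        for a, b in zip(lo.futility_upper[:-1], hi.futility_upper[:-1]):
            if not (math.isnan(a) or math.isnan(b)):
                assert b < a
                compared += 1
        assert compared >= 2

    def test_very_small_fraction_has_undefined_wedge(self):
        f = futility_boundaries([0.05, 0.5, 1.0], 0.05, 0.8)
        assert math.isnan(f.futility_upper[0])
        assert not math.isnan(f.futility_upper[-1])

    def test_wedge_inside_monitoring_band(self):
        d = design_boundaries([0.3, 0.5, 0.7, 1.0], 0.05, 0.8)
        for mon, fut in zip(d.monitor_upper, d.futility_upper):
            if not math.isnan(fut):
                assert 0 < fut < mon


class TestCrossingEvaluation:
    @pytest.fixture
    def design(self):
        return build_design(LocusDesignConfig(locus_id="rs1", maf=0.3, fixed_d2=0.0))

    def test_flat_zero_curve_past_ris_is_ris_complete(self, design):
        subjects = [design.ris // 2, design.ris + 10]
        b = boundaries_for_schedule(subjects, design)
        rep = evaluate_crossing([0.0, 0.0], subjects, design, b)
        assert rep.significance_look is None
        assert rep.ris_reached

    def test_huge_first_look_crosses_immediately(self, design):
        subjects = [100, 200, design.ris]
        b = boundaries_for_schedule(subjects, design)
        rep = evaluate_crossing([5.0, 0.0, 0.0], subjects, design, b)
        assert rep.significance_look == 0
        assert rep.significance_direction == 1

    def test_exact_threshold_counts_as_crossed(self, design):
        subjects = [design.ris]
        b = boundaries_for_schedule(subjects, design)
        z = b.monitor_upper[0]
        rep = evaluate_crossing([-z], subjects, design, b)
        assert rep.significance_look == 0
        assert rep.significance_direction == -1

    def test_looks_beyond_ris_are_not_retested(self, design):
        # a late excursion after full information must not create a crossing
        subjects = [design.ris // 4, design.ris, design.ris * 2]
        b = boundaries_for_schedule(subjects, design)
        rep = evaluate_crossing([0.1, 0.2, 4.0], subjects, design, b)
        assert rep.significance_look is None
        assert rep.ris_reached

    def test_randomised_series_against_naive_scan_oracle(self, design):
        rng = np.random.default_rng(3)
        for _ in range(25):
            k = int(rng.integers(2, 12))
            subjects = np.cumsum(rng.integers(50, 400, size=k)).tolist()
            zs = rng.normal(0, 2, size=k).tolist()
            b = boundaries_for_schedule(subjects, design)
            rep = evaluate_crossing(zs, subjects, design, b)
            # independent scan: same contract, re-derived look by look
            fractions = [min(1.0, n / design.ris) for n in subjects]
            sig = fut = None
            for i, (z, t) in enumerate(zip(zs, fractions)):
                mon, f_thr = _look_threshold(b, t)
                if sig is None and abs(z) >= mon:
                    sig = i
                if fut is None and not math.isnan(f_thr) and abs(z) <= f_thr:
                    fut = i
                if t >= 1.0:
                    break
            assert rep.significance_look == sig
            assert rep.futility_look == fut

    def test_schedule_fraction_contract(self):
        assert schedule_fractions([100, 500, 2000, 3000], 2000) == [0.05, 0.25, 1.0, 1.0]
        with pytest.raises(DesignError):
            schedule_fractions([500, 100], 2000)
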
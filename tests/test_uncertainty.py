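"""Monte Carlo PSA and one-way (tornado) sensitivity analysis."""

import math

import numpy as np
import pytest

from ctximpact import (
    ConfigurationError,
    ConversionInputs,
    ParameterDistribution,
    ValidationError,
    one_way_sensitivity,
    run_psa,
    sample_parameter,
)
from ctximpact.pilot import run_pilot_psa
from ctximpact.uncertainty import nearest_rank_percentile


RNG = lambda: np.random.default_rng(123)


class TestSampleParameter:
    def test_fixed_always_returns_central(self):
        dist = ParameterDistribution("x", "fixed", 2.63)
        draws = sample_parameter(dist, RNG(), size=1000)
        assert (draws == 2.63).all()

    def test_beta_mean_matches_central(self):
        """Method-of-moments beta centred at 0.24 with the 0-0.40 range:
        10,000 draws average to the base case within 0.01 and stay in [0,1]."""
        dist = ParameterDistribution("d", "beta", 0.24, value_range=(0.0, 0.40))
        draws = sample_parameter(dist, RNG(), size=10_000)
        assert abs(draws.mean() - 0.24) < 0.01
        assert (draws >= 0).all() and (draws <= 1).all()

    def test_relative_range_maps_to_196_sd(self):
        """A +/-20% relative spread means ~95% of normal draws inside the range."""
        dist = ParameterDistribution("r", "normal", 8.43, domain=(1.0, math.inf))
        draws = sample_parameter(dist, RNG(), size=20_000)
        inside = ((draws > 8.43 * 0.8) & (draws < 8.43 * 1.2)).mean()
        assert 0.94 < inside < 0.96
        assert ((draws > 8.43 * 0.6) & (draws < 8.43 * 1.4)).mean() > 0.99

    def test_normal_truncated_to_domain(self):
        dist = ParameterDistribution("r", "normal", 1.05, relative=0.5, domain=(1.0, math.inf))
        draws = sample_parameter(dist, RNG(), size=5_000)
        assert (draws >= 1.0).all()

    def test_beta_degenerate_endpoint(self):
        dist = ParameterDistribution("d", "beta", 0.0)
        assert sample_parameter(dist, RNG()) == 0.0

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            ParameterDistribution("d", "beta", 1.3)

    def test_central_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            ParameterDistribution("x", "normal", 5.0, value_range=(1.0, 2.0))


def _model(a, b):
    return a / b


class TestRunPsa:
    DISTS = [
        ParameterDistribution("a", "normal", 100.0, domain=(1e-9, math.inf)),
        ParameterDistribution("b", "normal", 4.0, domain=(1e-9, math.inf)),
    ]

    def test_all_fixed_collapses_to_point(self):
        dists = [ParameterDistribution("a", "fixed", 100.0),
                 ParameterDistribution("b", "fixed", 4.0)]
        res = run_psa(_model, dists, n_iter=200, seed=1)
        assert res.lower == res.upper == res.point_estimate == 25.0

    def test_seed_reproducibility_bit_identical(self):
        r1 = run_psa(_model, self.DISTS, n_iter=2_000, seed=42, retain_draws=True)
        r2 = run_psa(_model, self.DISTS, n_iter=2_000, seed=42, retain_draws=True)
        assert r1.lower == r2.lower and r1.upper == r2.upper
        assert (r1.draws == r2.draws).all()

    def test_point_inside_interval_and_draw_count(self):
        res = run_psa(_model, self.DISTS, n_iter=2_000, seed=7, retain_draws=True)
        assert res.lower <= res.point_estimate <= res.upper
        assert res.lower <= res.median <= res.upper
        assert res.draws.size == res.n_draws == 2_000

    def test_widening_a_range_never_narrows_the_interval(self):
        """Nested spreads, same seed: the wider parameterization produces a
        credible interval containing the narrower one."""
        widths = [0.05, 0.10, 0.20, 0.40]
        intervals = []
        for w in widths:
            dists = [
                ParameterDistribution("a", "normal", 100.0, relative=w, domain=(1e-9, math.inf)),
                ParameterDistribution("b", "fixed", 4.0),
            ]
            res = run_psa(_model, dists, n_iter=4_000, seed=99)
            intervals.append(res.interval)
        for narrow, wide in zip(intervals, intervals[1:]):
            assert wide[0] <= narrow[0] and wide[1] >= narrow[1]

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            run_psa(_model, self.DISTS, n_iter=50, seed=1)

    def test_duplicate_parameter_names_rejected(self):
        with pytest.raises(ConfigurationError):
            run_psa(_model, [self.DISTS[0], self.DISTS[0]], n_iter=200, seed=1)

    def test_single_beta_interval_matches_oversampled_oracle(self):
        """10,000-draw interval of a one-parameter beta model agrees with a
        200,000-draw brute-force oracle within Monte Carlo error."""
        dist = ParameterDistribution("d", "beta", 0.24, value_range=(0.0, 0.40))
        res = run_psa(lambda d: d, [dist], n_iter=10_000, seed=5)
        oracle = np.sort(sample_parameter(dist, np.random.default_rng(987_654), size=200_000))
        assert res.lower == pytest.approx(oracle[int(0.025 * 200_000) - 1], abs=0.01)
        assert res.upper == pytest.approx(oracle[int(0.975 * 200_000) - 1], abs=0.01)


def test_nearest_rank_agrees_with_bruteforce_definition():
    rng = np.random.default_rng(3)
    draws = np.sort(rng.normal(size=997))
    for q in (0.025, 0.5, 0.975, 0.001, 0.999):
        rank = max(1, math.ceil(q * draws.size))  # independent brute-force rank
        assert nearest_rank_percentile(draws, q) == draws[rank - 1]
    assert nearest_rank_percentile(draws, 1.0) == draws[-1]


class TestOneWaySensitivity:
    BASE = ConversionInputs(1000, 0.2, 2.0, 2.0)

    def test_hand_computed_swings_and_ordering(self):
        """Varying d over (0.1, 0.3) swings the output by 50; varying r over
        (1.6, 2.4) swings it by 83.33 — so the revisit rate ranks first."""
        rows = one_way_sensitivity(
            self.BASE,
            {"destruction_rate": (0.1, 0.3), "revisit_rate": (1.6, 2.4)},
        )
        assert [r.parameter for r in rows] == ["revisit_rate", "destruction_rate"]
        r_row, d_row = rows
        assert (r_row.output_low, r_row.output_high) == (pytest.approx(250.0), pytest.approx(500 / 3))
        assert (d_row.output_low, d_row.output_high) == (pytest.approx(225.0), pytest.approx(175.0))
        assert r_row.swing == pytest.approx(250 / 3)
        assert d_row.swing == pytest.approx(50.0)

    def test_zero_width_range_gives_zero_swing(self):
        rows = one_way_sensitivity(self.BASE, {"ctx_per_visit": (2.0, 2.0)})
        assert rows[0].swing == 0.0

    def test_symmetric_relative_ranges_make_denominator_swings_equal(self):
        """c-bar and r enter the model identically (as 1/x), so +/-20% ranges
        give them identical swings."""
        rows = one_way_sensitivity(
            self.BASE,
            {"ctx_per_visit": (1.6, 2.4), "revisit_rate": (1.6, 2.4)},
        )
        assert rows[0].swing == pytest.approx(rows[1].swing)

    def test_base_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            one_way_sensitivity(self.BASE, {"destruction_rate": (0.5, 0.9)})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            one_way_sensitivity(self.BASE, {"wibble": (0.0, 1.0)})


def test_pilot_psa_interval_covers_emr_truth():
    """The pilot Monte Carlo interval around the 24%-wastage base case covers
    the EMR-recorded 3,071 unique patients."""
    res = run_pilot_psa(n_iter=4_000, seed=11)
    assert res.contains(3_071)
    assert res.lower <= res.point_estimate <= res.upper
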
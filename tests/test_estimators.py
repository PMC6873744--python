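import numpy as np
import pytest

import telomr as t
from telomr.estimators import _weighted_median_point


def _instr(snp="rs1", bx=0.05, sx=0.01, by=0.002, sy=0.002):
    return t.HarmonizedInstrument(
        snp_id=snp, beta_exposure=bx, se_exposure=sx,
        beta_outcome=by, se_outcome=sy, action="unchanged",
    )


def _panel(rows, convention="per_sd_increase"):
    return t.InstrumentPanel(
        instruments=tuple(
            _instr(f"rs{i}", *row) for i, row in enumerate(rows)
        ),
        sign_convention=convention,
    )


class TestWaldRatio:
    def test_table_values(self, study_panel_increase):
        instr = next(
            i for i in study_panel_increase.instruments if i.snp_id == "rs10936599"
        )
        est = t.wald_ratio(instr)
        assert est.beta == pytest.approx(-7.83e-3)

    def test_delta_method_arithmetic(self):
        est = t.wald_ratio(_instr(bx=0.5, sx=0.01, by=0.1, sy=0.02))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_null_effect(self):
        est = t.wald_ratio(_instr(by=0.0))
        assert est.beta == 0.0 and est.p_value == 1.0

    def test_zero_exposure_beta_errors(self):
        instr = t.HarmonizedInstrument(
            snp_id="rs0", beta_exposure=1e-300, se_exposure=0.01,
            beta_outcome=0.0, se_outcome=0.002, action="unchanged",
        )
        object.__setattr__(instr, "beta_exposure", 0.0)
        with pytest.raises(t.DataError):
            t.wald_ratio(instr)

    def test_second_order_se_larger(self):
        instr = _instr(bx=0.05, sx=0.02, by=0.01, sy=0.002)
        assert (
            t.wald_ratio(instr, second_order=True).se > t.wald_ratio(instr).se
        )


class TestIVW:
    def test_reproduces_published_estimate(self, study_panel):
        est = t.ivw(study_panel)
        assert round(est.odds_ratio, 2) == 1.03
        assert round(est.or_ci_low, 2) == 1.01
        assert round(est.or_ci_high, 2) == 1.05
        assert est.n_snps == 10

    def test_single_instrument_reduces_to_wald(self):
        instr = _instr()
        panel = t.InstrumentPanel(instruments=(instr,))
        assert t.ivw(panel).beta == t.wald_ratio(instr).beta

    def test_equal_weights_give_mean_of_ratios(self):
        # identical bX and seY => equal weights
        rows = [(0.1, 0.01, 0.004, 0.002), (0.1, 0.01, 0.002, 0.002),
                (0.1, 0.01, -0.003, 0.002)]
        panel = _panel(rows)
        ratios = panel.beta_outcome / panel.beta_exposure
        assert t.ivw(panel).beta == pytest.approx(np.mean(ratios))

    def test_point_estimate_identical_across_variance_models(self, random_panel):
        fixed = t.ivw(random_panel, variance_model="fixed")
        re = t.ivw(random_panel, variance_model="multiplicative_re")
        assert fixed.beta == re.beta
        assert re.se >= fixed.se

    def test_underdispersion_floored(self):
        # homogeneous ratios: Q ~ 0, RE se must equal (not undercut) fixed se
        rows = [(0.1, 0.01, 0.005, 0.002), (0.2, 0.01, 0.010, 0.002),
                (0.05, 0.01, 0.0025, 0.002)]
        panel = _panel(rows)
        assert t.ivw(panel).se == t.ivw(panel, variance_model="fixed").se


class TestMaximumLikelihood:
    def test_reproduces_published_estimate(self, study_panel):
        est = t.maximum_likelihood(study_panel)
        assert round(est.odds_ratio, 2) == 1.03

    def test_matches_fixed_ivw_when_exposure_noise_vanishes(self, random_panel):
        shrunk = t.InstrumentPanel(
            instruments=tuple(
                t.HarmonizedInstrument(
                    snp_id=i.snp_id, beta_exposure=i.beta_exposure,
                    se_exposure=1e-8, beta_outcome=i.beta_outcome,
                    se_outcome=i.se_outcome, action="unchanged",
                )
                for i in random_panel.instruments
            )
        )
        ml = t.maximum_likelihood(shrunk)
        fixed = t.ivw(shrunk, variance_model="fixed")
        assert ml.beta == pytest.approx(fixed.beta, abs=1e-4)

    def test_needs_two_instruments(self):
        with pytest.raises(t.DataError):
            t.maximum_likelihood(t.InstrumentPanel(instruments=(_instr(),)))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        # three points exactly on bY = 0.01 + 0.3 bX
        rows = [(bx, 0.01, 0.01 + 0.3 * bx, 0.002) for bx in (0.05, 0.10, 0.20)]
        fit = t.egger(_panel(rows))
        assert fit.intercept == pytest.approx(0.01, abs=1e-12)
        assert fit.slope.beta == pytest.approx(0.3, abs=1e-10)

    def test_null_outcome_gives_null_fit(self):
        rows = [(bx, 0.01, 0.0, 0.002) for bx in (0.05, 0.10, 0.20)]
        fit = t.egger(_panel(rows))
        assert fit.intercept == 0.0 and fit.slope.beta == 0.0
        assert fit.slope.p_value == 1.0

    def test_needs_three_instruments(self):
        with pytest.raises(t.DataError):
            t.egger(_panel([(0.1, 0.01, 0.01, 0.002)] * 1 + [(0.2, 0.01, 0.01, 0.002)]))


def brute_force_weighted_median(ratios, weights):
    """Independent re-implementation of the percentile rule, pure Python."""
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    r = [ratios[i] for i in order]
    w = [weights[i] for i in order]
    total = sum(w)
    positions = []
    running = 0.0
    for wi in w:
        positions.append((running + wi / 2) / total)
        running += wi
    if 0.5 <= positions[0]:
        return r[0]
    for a in range(len(positions) - 1):
        if positions[a] <= 0.5 <= positions[a + 1]:
            frac = (0.5 - positions[a]) / (positions[a + 1] - positions[a])
            return r[a] + frac * (r[a + 1] - r[a])
    return r[-1]


class TestWeightedMedian:
    def test_hand_interpolated_example(self):
        # ratios (1, 2, 10), weights (1, 1, 2) -> 2 + (0.5-0.375)/0.375*8 = 14/3
        value = _weighted_median_point(np.array([1.0, 2.0, 10.0]),
                                       np.array([1.0, 1.0, 2.0]))
        assert value == pytest.approx(14 / 3)
        assert value == pytest.approx(
            brute_force_weighted_median([1.0, 2.0, 10.0], [1.0, 1.0, 2.0])
        )

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_agrees_with_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(200):
            ratios = rng.normal(0, 1, n)
            weights = rng.uniform(0.1, 5, n)
            assert _weighted_median_point(ratios, weights) == pytest.approx(
                brute_force_weighted_median(list(ratios), list(weights)), rel=1e-12
            )

    def test_equal_weights_equal_plain_median(self):
        rng = np.random.default_rng(1)
        for n in (3, 4, 5, 9, 10):
            ratios = rng.normal(0, 1, n)
            assert _weighted_median_point(ratios, np.ones(n)) == pytest.approx(
                np.median(ratios)
            )

    def test_degenerate_panel_recovers_common_ratio(self):
        rows = [(0.1, 0.01, 0.02, 0.002), (0.2, 0.01, 0.04, 0.002),
                (0.05, 0.01, 0.01, 0.002)]
        est = t.weighted_median(_panel(rows), n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)
        assert est.se < 0.05

    def test_needs_three_instruments(self):
        with pytest.raises(t.DataError):
            t.weighted_median(_panel([(0.1, 0.01, 0.01, 0.002)] * 2))


class TestWeightedMode:
    def test_point_mass_recovered(self):
        rows = [(0.1, 0.01, 0.03, 0.002), (0.2, 0.01, 0.06, 0.002),
                (0.05, 0.01, 0.015, 0.002)]
        est = t.weighted_mode(_panel(rows), n_boot=50, seed=2)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_heavy_cluster_wins(self):
        # total weight 10 at ratio 0.0, weight ~1 at ratio 0.5
        rows = [(0.1, 0.001, 0.0, 0.002)] * 0 + [
            (0.10, 0.001, 0.0, 0.002),
            (0.11, 0.001, 0.0, 0.002),
            (0.12, 0.001, 0.0, 0.002),
            (0.09, 0.001, 0.0, 0.002),
            (0.03, 0.001, 0.015, 0.002),
        ]
        est = t.weighted_mode(_panel(rows), n_boot=10, seed=3)
        ratios = np.array([0.0, 0.0, 0.0, 0.0, 0.5])
        sd = np.std(ratios, ddof=1)
        from scipy.stats import median_abs_deviation

        h = 0.9 * min(sd, median_abs_deviation(ratios, scale="normal")) * 5 ** (-0.2)
        assert abs(est.beta - 0.0) <= max(h, 1e-3)

    def test_kde_argmax_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        rows = [(bx, 0.01, by, 0.002)
                for bx, by in zip(rng.uniform(0.05, 0.2, 6), rng.normal(0.002, 0.002, 6))]
        panel = _panel(rows)
        est = t.weighted_mode(panel, n_boot=10, seed=0, grid_points=512)
        # oracle: explicit loop KDE on a 20x finer grid
        ratios = panel.beta_outcome / panel.beta_exposure
        weights = (panel.beta_exposure / panel.se_outcome) ** 2
        weights = weights / weights.sum()
        from scipy.stats import median_abs_deviation

        sd = np.std(ratios, ddof=1)
        h = 0.9 * min(sd, median_abs_deviation(ratios, scale="normal")) * 6 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512 * 20)
        dens = np.zeros_like(grid)
        for r, w in zip(ratios, weights):
            dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
        spacing = (grid[-1] - grid[0]) / (512 - 1)
        assert abs(est.beta - grid[np.argmax(dens)]) <= spacing

    def test_needs_three_instruments(self):
        with pytest.raises(t.DataError):
            t.weighted_mode(_panel([(0.1, 0.01, 0.01, 0.002)] * 2))


class TestEquivariance:
    """Sign and scale equivariance across all five estimators."""

    @staticmethod
    def _negated(panel):
        return t.InstrumentPanel(
            instruments=tuple(
                t.HarmonizedInstrument(
                    snp_id=i.snp_id, beta_exposure=i.beta_exposure,
                    se_exposure=i.se_exposure, beta_outcome=-i.beta_outcome,
                    se_outcome=i.se_outcome, action="unchanged",
                )
                for i in panel.instruments
            )
        )

    @staticmethod
    def _scaled(panel, k):
        return t.InstrumentPanel(
            instruments=tuple(
                t.HarmonizedInstrument(
                    snp_id=i.snp_id, beta_exposure=k * i.beta_exposure,
                    se_exposure=k * i.se_exposure, beta_outcome=i.beta_outcome,
                    se_outcome=i.se_outcome, action="unchanged",
                )
                for i in panel.instruments
            )
        )

    @pytest.mark.parametrize(
        "estimator,kwargs,tol",
        [
            (t.ivw, {}, 1e-14),
            (t.maximum_likelihood, {}, 1e-7),
            (lambda p, **k: t.egger(p).slope, {}, 1e-12),
            (t.weighted_median, {"n_boot": 10, "seed": 0}, 1e-12),
            (t.weighted_mode, {"n_boot": 10, "seed": 0}, 1e-9),
        ],
        ids=["ivw", "ml", "egger", "median", "mode"],
    )
    def test_sign_equivariance(self, random_panel, estimator, kwargs, tol):
        base = estimator(random_panel, **kwargs).beta
        negated = estimator(self._negated(random_panel), **kwargs).beta
        assert negated == pytest.approx(-base, abs=tol)

    @pytest.mark.parametrize(
        "estimator,kwargs,tol",
        [
            (t.ivw, {}, 1e-12),
            (t.maximum_likelihood, {}, 1e-6),
            (lambda p, **k: t.egger(p).slope, {}, 1e-10),
            (t.weighted_median, {"n_boot": 10, "seed": 0}, 1e-10),
            (t.weighted_mode, {"n_boot": 10, "seed": 0}, 1e-7),
        ],
        ids=["ivw", "ml", "egger", "median", "mode"],
    )
    def test_scale_equivariance(self, random_panel, estimator, kwargs, tol):
        k = 2.5
        base = estimator(random_panel, **kwargs).beta
        scaled = estimator(self._scaled(random_panel, k), **kwargs).beta
        assert scaled == pytest.approx(base / k, rel=tol, abs=tol)


class TestReporting:
    def test_per_sd_decrease_negates_and_inverts(self, study_panel, study_panel_increase):
        dec = t.ivw(study_panel)
        inc = t.ivw(study_panel_increase)
        assert dec.beta == pytest.approx(-inc.beta)
        assert dec.odds_ratio == pytest.approx(1 / inc.odds_ratio)
        assert dec.or_ci_low == pytest.approx(1 / inc.or_ci_high)

    def test_estimate_invariants(self, study_panel):
        for est in t.all_estimates(study_panel, n_boot=50, seed=4):
            assert est.ci_low <= est.beta <= est.ci_high
            assert 0 < est.p_value <= 1
            assert est.odds_ratio == pytest.approx(np.exp(est.beta))
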
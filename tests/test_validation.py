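import numpy as np
import pytest

from cathquant import fixtures
from cathquant.method_model import MethodConfig, MrmMethod
from cathquant.quant import fit_calibration
from cathquant.synthetic_data import (
    BatchDesign,
    SampleSlot,
    SimulationParams,
    default_params,
    simulate_batch,
)
from cathquant.validation import (
    ReplicateTable,
    ValidationError,
    assign_loq,
    bias_pct,
    carryover_check,
    dilution_integrity,
    estimate_lod,
    interference_screen,
    matrix_effects,
    precision,
    run_bias_precision_study,
    stability_assess,
    summarize_bias_precision,
    summarize_stability,
)

LEVELS = (1.0, 5.0, 10.0, 20.0, 50.0, 150.0, 500.0, 1000.0)


class TestBias:
    def test_zero_bias(self):
        assert bias_pct([30.0, 30.0], 30.0) == 0.0

    def test_rounded_grand_mean_example(self):
        # a grand average of 25.7 ng/mL at a 30 ng/mL nominal
        assert bias_pct([25.7], 30.0) == pytest.approx(-14.33, abs=0.005)

    def test_scale_invariance(self):
        vals = np.array([28.0, 31.5, 30.2])
        assert bias_pct(vals, 30.0) == pytest.approx(bias_pct(vals * 10, 300.0))

    def test_errors(self):
        with pytest.raises(ValidationError):
            bias_pct([], 30.0)
        with pytest.raises(ValidationError):
            bias_pct([30.0], 0.0)


def anova_components_oracle(data):
    """Brute-force one-way variance components for a balanced table."""
    k, n = data.shape
    grand = data.mean()
    ssw = sum((data[i] - data[i].mean()) ** 2 for i in range(k)).sum()
    ssb = n * sum((data[i].mean() - grand) ** 2 for i in range(k))
    msw = ssw / (k * (n - 1))
    msb = ssb / (k - 1)
    sigma_b2 = max(0.0, (msb - msw) / n)
    within = 100 * np.sqrt(msw) / grand
    between = 100 * np.sqrt(msw + sigma_b2) / grand
    return within, between


class TestPrecision:
    def test_single_run_cv(self):
        table = ReplicateTable("a", 100.0, np.array([[98.0, 100.0, 102.0], [98, 100, 102]]))
        res = precision(table)
        assert res.per_run["cv_pct"].iloc[0] == pytest.approx(2.0)

    def test_identical_values_zero_cv(self):
        table = ReplicateTable("a", 30.0, np.full((5, 3), 30.0))
        res = precision(table)
        assert res.within_run_cv_pct == 0.0
        assert res.between_run_cv_pct == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_anova_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = 100 + rng.normal(0, 5, (3, 2))
        res = precision(ReplicateTable("a", 100.0, data))
        within, between = anova_components_oracle(data)
        assert res.within_run_cv_pct == pytest.approx(within, abs=1e-10)
        assert res.between_run_cv_pct == pytest.approx(between, abs=1e-10)

    def test_between_never_below_within_in_anova_mode(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            data = 100 + rng.normal(0, 8, (5, 3))
            res = precision(ReplicateTable("a", 100.0, data))
            assert res.between_run_cv_pct >= res.within_run_cv_pct - 1e-12

    def test_literal_mode(self):
        data = np.array([[99.0, 101.0], [109.0, 111.0], [89.0, 91.0]])
        res = precision(ReplicateTable("a", 100.0, data), mode="literal")
        run_means = data.mean(axis=1)
        expected = 100 * np.std(run_means, ddof=1) / data.mean()
        assert res.between_run_cv_pct == pytest.approx(expected)

    def test_recovers_configured_cvs(self):
        # 5 x 3 design, within 8 %, between 5 %: over 200 trials the mean
        # recovered within-run CV is ~8 % and between-run ~sqrt(8^2 + 5^2) %
        rng = np.random.default_rng(99)
        mu, sw, sb = 400.0, 0.08, 0.05
        withins, betweens = [], []
        for _ in range(200):
            runs = mu * (1 + rng.normal(0, sb, 5))
            data = runs[:, None] * (1 + rng.normal(0, sw, (5, 3)))
            res = precision(ReplicateTable("a", mu, data))
            withins.append(res.within_run_cv_pct)
            betweens.append(res.between_run_cv_pct)
        assert np.mean(withins) == pytest.approx(8.0, abs=0.5)
        assert np.mean(betweens) == pytest.approx(np.hypot(8.0, 5.0), abs=0.7)

    def test_too_small_design_rejected(self):
        with pytest.raises(ValidationError):
            precision(ReplicateTable("a", 1.0, np.array([[1.0, 2.0]])))


class TestLod:
    def test_all_passing_returns_lowest(self):
        series = {0.05: [50.0], 0.1: [100.0], 0.2: [200.0]}
        assert estimate_lod(series) == 0.05

    def test_crossing_between_grid_points(self):
        # analytic S/N = rf x c / (noise x sigma sqrt(2 pi)) crossing 3
        # between 0.2 and 0.3 must yield the first grid point above it
        rf, noise, sigma = 700.0, 700.0, 0.03
        height = lambda c: rf * c / (sigma * np.sqrt(2 * np.pi))
        series = {c: [height(c) / noise] for c in (0.05, 0.1, 0.2, 0.3, 0.5, 1.0)}
        crossing = 3 * noise * sigma * np.sqrt(2 * np.pi) / rf
        assert 0.2 < crossing < 0.3
        assert estimate_lod(series) == 0.3

    def test_monotonicity_enforced(self):
        # a fluke pass below a failing level must not win
        series = {0.05: [4.0], 0.1: [2.0], 0.2: [5.0], 0.3: [9.0]}
        assert estimate_lod(series) == 0.2

    def test_all_failing_raises(self):
        with pytest.raises(ValidationError):
            estimate_lod({0.05: [1.0], 0.1: [2.0]})


class TestLoq:
    def test_default_assignment(self):
        assert assign_loq(MethodConfig()) == 1.0

    def test_alternate_levels(self):
        cfg = MethodConfig(calibration_levels=(5.0, 10.0, 50.0, 100.0, 500.0))
        assert assign_loq(cfg) == 5.0

    def test_warning_when_loq_not_above_lod(self):
        with pytest.warns(UserWarning, match="LOD"):
            assign_loq(MethodConfig(), lod=2.0)


class TestMatrixEffects:
    def test_identical_sets(self):
        me, cv, ok = matrix_effects([100, 100, 100], [100, 100, 100])
        assert me == 100.0 and ok

    def test_suppression(self):
        a = np.array([100.0, 110.0, 90.0, 105.0, 95.0])
        me, cv, ok = matrix_effects(a, 0.8 * a)
        assert me == pytest.approx(80.0)
        assert ok

    def test_excessive_deviation_fails(self):
        a = np.full(5, 100.0)
        me, cv, ok = matrix_effects(a, 0.6 * a)
        assert not ok

    def test_errors(self):
        with pytest.raises(ValidationError):
            matrix_effects([1.0], [1.0])
        with pytest.raises(ValidationError):
            matrix_effects([0.0, 0.0], [1.0, 1.0])


class TestStability:
    @pytest.mark.parametrize(
        "factor,loss,stable", [(1.0, 0.0, True), (0.82, -18.0, True), (0.75, -25.0, False)]
    )
    def test_loss_and_verdict(self, factor, loss, stable):
        d0 = np.array([1000.0, 1020.0, 980.0])
        got_loss, _, got_stable = stability_assess(d0, factor * d0)
        assert got_loss == pytest.approx(loss, abs=1e-9)
        assert got_stable is stable


class TestDilutionIntegrity:
    def test_passing_and_failing_controls(self):
        # 1:5 dilution of a 1000 ng/mL control
        bias, ok = dilution_integrity(193.2, 1000.0, 5.0)
        assert bias == pytest.approx(-3.4)
        assert ok
        bias, ok = dilution_integrity(146.8, 1000.0, 5.0)
        assert bias == pytest.approx(-26.6)
        assert not ok

    def test_exact_recovery(self):
        bias, ok = dilution_integrity(200.0, 1000.0, 5.0)
        assert bias == 0.0 and ok

    def test_boundary_inclusive(self):
        bias, ok = dilution_integrity(240.0, 1000.0, 5.0)
        assert bias == pytest.approx(20.0) and ok


def _single_analyte_method(method, analyte):
    return MrmMethod(
        [method.quantifier_for(analyte), method.internal_standard], method.config
    )


@pytest.fixture(scope="module")
def setup(method):
    sub = _single_analyte_method(method, "Mephedrone")
    params = default_params(method, seed=21)
    fit = fit_calibration([(c, 0.1173 * c) for c in LEVELS], analyte="Mephedrone")
    return sub, params, fit


class TestCarryoverAndInterference:

    def _blank_after_top(self, sub, params, fraction):
        p = SimulationParams(**{**params.__dict__, "carryover_fraction": fraction})
        slots = [
            SampleSlot("TOP", "calibrator", {"Mephedrone": 1000.0}, injection_order=0),
            SampleSlot("BL", "blank", injection_order=1),
        ]
        chroms = simulate_batch(BatchDesign(slots, seed=3), sub, p, channels="quantifier")
        return [c for c in chroms["BL"] if c.analyte == "Mephedrone"]

    def test_no_carryover_passes(self, setup):
        sub, params, fit = setup
        blanks = self._blank_after_top(sub, params, 0.0)
        verdict = carryover_check(
            {"Mephedrone": blanks}, {"Mephedrone": 0.1}, {"Mephedrone": fit}, sub, 20000.0
        )
        assert verdict["Mephedrone"] is True

    def test_gross_carryover_fails(self, setup):
        sub, params, fit = setup
        blanks = self._blank_after_top(sub, params, 0.01)  # ~10 ng/mL apparent
        verdict = carryover_check(
            {"Mephedrone": blanks}, {"Mephedrone": 0.1}, {"Mephedrone": fit}, sub, 20000.0
        )
        assert verdict["Mephedrone"] is False

    def test_missing_lod_raises(self, setup):
        sub, params, fit = setup
        blanks = self._blank_after_top(sub, params, 0.0)
        with pytest.raises(ValidationError, match="LOD"):
            carryover_check({"Mephedrone": blanks}, {}, {"Mephedrone": fit}, sub, 20000.0)

    def test_interference_clean_and_spiked_panels(self, setup):
        sub, params, fit = setup
        clean = self._blank_after_top(sub, params, 0.0)
        spiked = self._blank_after_top(sub, params, 0.01)
        table = interference_screen(
            {"drug_free": clean, "drug_panel": spiked},
            {"Mephedrone": 0.1},
            {"Mephedrone": fit},
            sub,
            20000.0,
        )
        assert not table.loc[table.panel == "drug_free", "flagged"].any()
        assert table.loc[table.panel == "drug_panel", "flagged"].all()


class TestFixtureSummaries:
    def test_stability_fixture_all_within_limit(self):
        table = summarize_stability(fixtures.load_stability())
        assert len(table) == 26
        assert table["all_stable"].all()

    def test_bias_precision_fixture_shape(self):
        table = fixtures.load_bias_precision()
        assert len(table) == 78  # 26 analytes x 3 QC levels
        summary = summarize_bias_precision(table)
        assert set(summary.max_within_cv_by_level) == {30.0, 400.0, 800.0}


def test_simulated_qc_study_smoke(method):
    # two analytes through the full chromatogram path
    params = default_params(method, seed=5)
    table = run_bias_precision_study(
        method, params, analytes=["Mephedrone", "Butylone"]
    )
    assert len(table) == 6
    assert table["passed"].all()
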
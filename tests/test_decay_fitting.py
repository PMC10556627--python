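import math
import shutil
import subprocess

import numpy as np
import pytest

from chipdecay.decay_fitting import (
    DecayFit,
    DecaySeries,
    asymp_model_eval,
    decay_f_test,
    filter_fits,
    fit_decay,
    grid_search_rss,
    initialize_fit,
    residence_time,
    wald_pvalue,
)
from chipdecay.io_formats import ValidationError

T7 = np.array([0.0, 2.0, 4.0, 7.5, 15.0, 30.0, 60.0])


def make_series(y0, yf, koff, t=T7, noise=0.0, seed=0, peak_id="p"):
    y = asymp_model_eval(y0, yf, math.log(koff), t)
    if noise:
        y = np.maximum(y + np.random.default_rng(seed).normal(0, noise, len(t)), 0.0)
    return DecaySeries(peak_id, t, y)


class TestModelEval:
    def test_value_at_origin(self):
        assert asymp_model_eval(42.0, 3.0, -1.7, 0.0) == pytest.approx(42.0)

    def test_degenerate_flat_model(self):
        t = np.array([0.0, 5.0, 100.0])
        np.testing.assert_allclose(asymp_model_eval(7.0, 7.0, 0.3, t), 7.0)

    def test_closed_form_point(self):
        # 10 + 90*exp(-1)
        val = asymp_model_eval(100.0, 10.0, math.log(0.2), 5.0)
        assert val == pytest.approx(10.0 + 90.0 * math.exp(-1.0), rel=1e-12)


class TestSeriesValidation:
    def test_too_few_observations(self):
        with pytest.raises(ValidationError, match=">= 4"):
            DecaySeries("p", [0, 1, 2], [3, 2, 1])

    def test_too_few_distinct_times(self):
        with pytest.raises(ValidationError, match="distinct"):
            DecaySeries("p", [0, 0, 1, 1], [4, 4, 2, 2])

    def test_negative_signal_rejected(self):
        with pytest.raises(ValidationError):
            DecaySeries("p", [0, 1, 2, 3], [4, 3, -1, 1])


class TestInitialize:
    def test_noiseless_start_converges(self):
        series = make_series(100.0, 10.0, 0.2)
        fit = fit_decay(series)
        assert fit.converged and fit.lrc == pytest.approx(math.log(0.2), rel=1e-6)

    def test_increasing_series_takes_fallback(self):
        series = DecaySeries("up", T7, np.linspace(1, 50, 7))
        y0, yf, lrc = initialize_fit(series)
        assert all(map(math.isfinite, (y0, yf, lrc)))

    def test_minimal_log_linear_input(self):
        series = DecaySeries("m", [0.0, 1.0, 2.0, 3.0], [8.0, 4.0, 2.0, 2.0])
        assert math.isfinite(initialize_fit(series)[2])


class TestFitDecay:
    def test_exact_recovery_zero_noise(self):
        fit = fit_decay(make_series(100.0, 10.0, 0.2))
        assert fit.converged
        assert fit.y0 == pytest.approx(100.0, rel=1e-6)
        assert fit.yf == pytest.approx(10.0, rel=1e-6)
        assert fit.lrc == pytest.approx(math.log(0.2), rel=1e-6)

    def test_constant_series_non_identifiable(self):
        fit = fit_decay(DecaySeries("flat", T7, np.full(7, 5.0)))
        assert not fit.converged or not math.isfinite(fit.se_lrc)

    @pytest.mark.parametrize("seed", range(5))
    def test_fit_beats_grid_oracle(self, seed):
        series = make_series(100.0, 10.0, 0.2, noise=5.0, seed=seed)
        fit = fit_decay(series)
        assert fit.rss <= grid_search_rss(series, n=60) + 1e-9

    def test_scale_equivariance(self):
        base = make_series(100.0, 10.0, 0.2, noise=4.0, seed=3)
        scaled = DecaySeries("s", base.t, base.y * 3.0)
        f1, f2 = fit_decay(base), fit_decay(scaled)
        assert f2.y0 == pytest.approx(3.0 * f1.y0, rel=1e-6)
        assert f2.yf == pytest.approx(3.0 * f1.yf, rel=1e-6)
        assert f2.lrc == pytest.approx(f1.lrc, abs=1e-8)
        assert f2.p_lrc == pytest.approx(f1.p_lrc, rel=1e-6)

    def test_time_shift_is_not_an_invariance(self):
        """t = 0 anchors y0: shifting times must change the y0 estimate."""
        base = make_series(100.0, 10.0, 0.2)
        shifted = DecaySeries("sh", base.t + 5.0, base.y)
        f1, f2 = fit_decay(base), fit_decay(shifted)
        assert abs(f2.y0 - f1.y0) / f1.y0 > 0.05

    def test_zero_noise_identifiability_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y0 = rng.uniform(5, 500)
            yf = rng.uniform(0, 0.5 * y0)
            tau = rng.uniform(0.5, 60)
            t = np.linspace(0, 3 * tau, 7)
            fit = fit_decay(DecaySeries("z", t, asymp_model_eval(y0, yf, math.log(1 / tau), t)))
            assert fit.converged
            assert fit.y0 == pytest.approx(y0, rel=1e-6)
            assert fit.yf == pytest.approx(yf, rel=1e-6, abs=1e-6 * y0)
            assert fit.lrc == pytest.approx(math.log(1 / tau), rel=1e-6)


class TestWaldFilter:
    def _fit(self, lrc, se, df=4, converged=True):
        return DecayFit("p", 10, 1, lrc, 0.1, 0.1, se, np.nan, converged, 1.0, df)

    def test_lrc_zero_gives_p_one(self):
        assert wald_pvalue(self._fit(0.0, 0.5)) == 1.0

    def test_vanishing_se_gives_p_zero(self):
        assert wald_pvalue(self._fit(-1.0, 1e-12)) < 1e-10
        assert wald_pvalue(self._fit(-1.0, 0.0)) == 0.0

    def test_t_distribution_value(self):
        # statistic 2.0 at df=3: two-sided p from the t CDF
        assert wald_pvalue(self._fit(1.0, 0.5, df=3)) == pytest.approx(0.13932596855884305, rel=1e-10)

    def test_filter_retains_below_alpha(self):
        from dataclasses import replace

        fits = [self._fit(-1.0, 0.1), self._fit(-1.0, 2.0)]
        fits = [replace(f, p_lrc=wald_pvalue(f)) for f in fits]
        assert filter_fits(fits, alpha=0.05) == fits[:1]

    def test_filter_empty_input(self):
        assert filter_fits([], alpha=0.05) == []

    def test_filter_monotone_in_alpha(self):
        from dataclasses import replace

        rng = np.random.default_rng(11)
        fits = []
        for i in range(40):
            f = self._fit(rng.normal(-1, 1), rng.uniform(0.05, 2.0))
            fits.append(replace(f, peak_id=f"p{i}", p_lrc=wald_pvalue(f)))
        ids = {a: [f.peak_id for f in filter_fits(fits, a)] for a in (0.01, 0.05, 0.10)}
        assert set(ids[0.01]) <= set(ids[0.05]) <= set(ids[0.10])

    def test_residence_time_reciprocal(self):
        assert residence_time(self._fit(math.log(0.2), 0.1)) == pytest.approx(5.0)
        assert residence_time(self._fit(0.0, 0.1)) == pytest.approx(1.0)


def test_f_test_flat_data_not_significant():
    series = DecaySeries("flat", T7, np.array([5.0, 5.1, 4.9, 5.0, 5.05, 4.95, 5.0]))
    fit = fit_decay(series)
    if fit.converged:
        assert decay_f_test(series, fit) > 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_fit_matches_r_nls_ssasymp(tmp_path):
    """Independent oracle: R's self-starting asymptotic nls on the same series."""
    rng = np.random.default_rng(42)
    t = np.tile(T7, 2)
    y = np.maximum(
        asymp_model_eval(120.0, 15.0, math.log(0.15), t) + rng.normal(0, 6, len(t)), 0.0
    )
    data = tmp_path / "series.tsv"
    np.savetxt(data, np.column_stack([t, y]), delimiter="\t", header="time\tChIP", comments="")
    script = tmp_path / "oracle.R"
    script.write_text(
        f'd <- read.delim("{data}")\n'
        "m <- nls(ChIP ~ SSasymp(time, yf, y0, log_koff), data = d)\n"
        's <- summary(m)$coefficients\n'
        'cat(sprintf("%.12g %.12g %.12g %.12g %.12g\\n",\n'
        '    s["y0","Estimate"], s["yf","Estimate"], s["log_koff","Estimate"],\n'
        '    s["log_koff","Std. Error"], s["log_koff","Pr(>|t|)"]))\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
    r_y0, r_yf, r_lrc, r_se, r_p = map(float, out.stdout.split())
    fit = fit_decay(DecaySeries("x", t, y))
    assert fit.y0 == pytest.approx(r_y0, rel=1e-5)
    assert fit.yf == pytest.approx(r_yf, rel=1e-5)
    assert fit.lrc == pytest.approx(r_lrc, rel=1e-5)
    assert fit.se_lrc == pytest.approx(r_se, rel=1e-4)
    assert fit.p_lrc == pytest.approx(r_p, rel=1e-4)
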
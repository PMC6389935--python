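"""Mixed-model cosinor: recovery, classification, invariances, FDR."""

import numpy as np
import pandas as pd
import pytest

from adipoclock.rhythm import (
    AlignedSeries,
    CosinorFit,
    classify_circadian,
    fit_cosinor_batch,
    fit_cosinor_mixed,
    peak_time_histogram,
    permutation_fdr,
)
from adipoclock.simulate import SimulationConfig, simulate_expression


def _series(times, subjects, values, probe_id="p"):
    return AlignedSeries(probe_id, np.asarray(subjects), np.asarray(times),
                         np.asarray(values))


class TestExactRecovery:
    def test_noise_free_cosinor_recovered_exactly(
        self, study_times_subjects, make_cosinor
    ):
        times, subjects = study_times_subjects
        y = make_cosinor(times, mesor=5.0, amplitude=2.0, peak_h=8.8)
        fit = fit_cosinor_mixed(_series(times, subjects, y))
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.peak_time_h == pytest.approx(8.8, abs=1e-3)
        assert fit.r_squared >= 1 - 1e-9
        assert fit.is_circadian
        assert fit.mesor == pytest.approx(5.0, abs=1e-6)

    def test_trend_recovered(self, study_times_subjects, make_cosinor):
        times, subjects = study_times_subjects
        y = make_cosinor(times, mesor=7.0, amplitude=1.0, peak_h=-3.0,
                         slope=0.05)
        fit = fit_cosinor_mixed(_series(times, subjects, y))
        assert fit.trend_slope == pytest.approx(0.05, abs=1e-8)
        assert fit.peak_time_h == pytest.approx(-3.0, abs=1e-3)

    def test_constant_series_not_circadian(self, study_times_subjects):
        times, subjects = study_times_subjects
        fit = fit_cosinor_mixed(_series(times, subjects, np.full(35, 7.0)))
        assert fit.amplitude == 0.0
        assert fit.amplitude_ci_low <= 0 or fit.amplitude_ci_low == 0.0
        assert not fit.is_circadian

    def test_evening_and_morning_sign_convention(
        self, study_times_subjects, make_cosinor
    ):
        """A morning gene peaks ~+8.8 h after DLMO, an evening gene ~-0.9 h."""
        times, subjects = study_times_subjects
        morning = fit_cosinor_mixed(
            _series(times, subjects, make_cosinor(times, peak_h=8.8))
        )
        evening = fit_cosinor_mixed(
            _series(times, subjects, make_cosinor(times, peak_h=-0.9))
        )
        assert morning.peak_time_h == pytest.approx(8.8, abs=1e-3)
        assert evening.peak_time_h == pytest.approx(-0.9, abs=1e-3)


class TestClassificationRule:
    @pytest.mark.parametrize(
        "r2,ci_low,expected",
        [
            (0.85, 0.5, True),
            (0.79, 0.5, False),
            (0.95, -0.1, False),
            (0.80, 0.5, False),  # strict inequality on R^2
        ],
    )
    def test_boundary_cases(self, r2, ci_low, expected):
        fit = CosinorFit(
            probe_id="p", mesor=0, trend_slope=0, beta_cos=1, beta_sin=0,
            amplitude=1, amplitude_se=0.2, amplitude_ci_low=ci_low,
            amplitude_ci_high=1.5, peak_time_h=0, r_squared=r2,
            is_circadian=False,
        )
        assert classify_circadian(fit, r2_threshold=0.8) is expected


class TestInvariances:
    def test_amplitude_invariant_to_constant_shift(
        self, study_times_subjects, make_cosinor
    ):
        times, subjects = study_times_subjects
        rng = np.random.default_rng(0)
        y = make_cosinor(times, amplitude=1.3, peak_h=4.0) + rng.normal(
            0, 0.3, times.size
        )
        f1 = fit_cosinor_mixed(_series(times, subjects, y))
        f2 = fit_cosinor_mixed(_series(times, subjects, y + 100.0))
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-6)
        assert f2.peak_time_h == pytest.approx(f1.peak_time_h, abs=1e-6)

    def test_time_translation_shifts_peak(
        self, study_times_subjects, make_cosinor
    ):
        times, subjects = study_times_subjects
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.2, times.size)
        delta = 3.7
        f1 = fit_cosinor_mixed(
            _series(times, subjects, make_cosinor(times, peak_h=2.0) + noise)
        )
        f2 = fit_cosinor_mixed(
            _series(times + delta, subjects,
                    make_cosinor(times, peak_h=2.0) + noise)
        )
        shifted = (f1.peak_time_h + delta + 12) % 24 - 12
        assert f2.peak_time_h == pytest.approx(shifted, abs=1e-6)

    def test_single_fit_matches_batch(self, study_times_subjects, make_cosinor):
        times, subjects = study_times_subjects
        rng = np.random.default_rng(2)
        Y = np.column_stack([
            make_cosinor(times, amplitude=a, peak_h=p) + rng.normal(0, 0.4, 35)
            for a, p in [(1.0, 3.0), (0.5, -6.0), (2.0, 11.0)]
        ])
        batch = fit_cosinor_batch(times, subjects, Y)
        for j in range(3):
            single = fit_cosinor_mixed(_series(times, subjects, Y[:, j]))
            assert single.amplitude == pytest.approx(
                batch["amplitude"][j], rel=1e-9
            )
            assert single.r_squared == pytest.approx(
                batch["r_squared"][j], rel=1e-9
            )


class TestAgainstStatsmodels:
    def test_fixed_effects_match_mixedlm(self, study_times_subjects):
        """Dual route: REML profile search vs statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        times, subjects = study_times_subjects
        w = 2 * np.pi / 24
        rng = np.random.default_rng(8)
        for i in range(3):
            intercepts = rng.normal(0, 0.5, 7)
            y = (
                6.0 + 1.2 * np.cos(w * (times - 5.0))
                + np.repeat(intercepts, 5)
                + rng.normal(0, 0.4, times.size)
            )
            mine = fit_cosinor_mixed(_series(times, subjects, y))
            df = pd.DataFrame(
                {"y": y, "t": times, "c": np.cos(w * times),
                 "s": np.sin(w * times), "subj": subjects}
            )
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = smf.mixedlm("y ~ t + c + s", df, groups=df["subj"]
                                     ).fit(reml=True)
            assert mine.beta_cos == pytest.approx(sm_fit.params["c"], abs=1e-4)
            assert mine.beta_sin == pytest.approx(sm_fit.params["s"], abs=1e-4)
            assert mine.mesor == pytest.approx(
                sm_fit.params["Intercept"], abs=1e-4
            )
            assert mine.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
            ratio_sm = float(sm_fit.cov_re.iloc[0, 0] / sm_fit.scale)
            assert mine.variance_ratio == pytest.approx(ratio_sm, abs=2e-3)


class TestMonteCarloRecovery:
    def test_bias_peak_error_and_coverage(self):
        cfg = SimulationConfig(
            n_probes=500, rhythmic_fraction=1.0, amplitude_range=(1.0, 1.0),
            noise_sd=0.5, subject_intercept_sd=0.5, trend_slope_sd=0.0,
            seed=42,
        )
        expr, meta, truth = simulate_expression(cfg)
        fits = fit_cosinor_batch(
            meta["time_rel_dlmo_h"].to_numpy(),
            meta["subject_id"].to_numpy(),
            expr.to_numpy().T,
        )
        bias = fits["amplitude"].mean() / 1.0 - 1.0
        err = (fits["peak_time_h"].to_numpy()
               - truth.probes["peak_time_h"].to_numpy() + 12) % 24 - 12
        coverage = (
            (fits["amplitude_ci_low"] <= 1.0)
            & (fits["amplitude_ci_high"] >= 1.0)
        ).mean()
        assert abs(bias) < 0.10
        assert np.abs(err).mean() < 1.0
        assert 0.92 <= coverage <= 0.98


class TestPermutationFdr:
    def test_reproducible_given_seed(self, study_times_subjects, make_cosinor):
        times, subjects = study_times_subjects
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(35, 40))
        a = permutation_fdr(times, subjects, Y, n_permutations=20, seed=7)
        b = permutation_fdr(times, subjects, Y, n_permutations=20, seed=7)
        assert np.array_equal(a.permuted_counts, b.permuted_counts)
        assert a.fdr == b.fdr or (np.isnan(a.fdr) and np.isnan(b.fdr))

    def test_constant_dataset_undefined_fdr(self, study_times_subjects):
        times, subjects = study_times_subjects
        Y = np.full((35, 10), 3.0)
        est = permutation_fdr(times, subjects, Y, n_permutations=10, seed=1)
        assert est.n_observed_circadian == 0
        assert est.mean_permuted_circadian == 0
        assert np.isnan(est.fdr) and np.isnan(est.fdr_capped)

    def test_rejects_bad_permutation_count(self, study_times_subjects):
        times, subjects = study_times_subjects
        with pytest.raises(ValueError):
            permutation_fdr(times, subjects, np.zeros((35, 2)),
                            n_permutations=0, seed=1)

    def test_permutation_preserves_subject_means(
        self, study_times_subjects, monkeypatch
    ):
        from adipoclock.rhythm import _permute_within_subjects

        times, subjects = study_times_subjects
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(35, 6))
        codes = pd.factorize(subjects)[0]
        Yp = _permute_within_subjects(Y, codes, 3, np.random.default_rng(0))
        for p in range(3):
            block = Yp[:, p * 6:(p + 1) * 6]
            for c in np.unique(codes):
                idx = codes == c
                assert np.allclose(
                    np.sort(block[idx], axis=0), np.sort(Y[idx], axis=0)
                )


class TestPeakTimeHistogram:
    def test_single_bin(self):
        counts, edges = peak_time_histogram(np.full(10, 8.5))
        assert counts.sum() == 10
        assert counts.max() == 10
        assert edges[np.argmax(counts)] == 8.0

    def test_count_conservation_and_range(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-12, 12, 137)
        counts, edges = peak_time_histogram(pts)
        assert counts.sum() == 137
        assert edges[0] == -12 and edges[-1] == 12

    def test_empty_input(self):
        counts, _ = peak_time_histogram(np.array([]))
        assert counts.sum() == 0


def test_few_observations_warns():
    with pytest.warns(UserWarning, match="< 3 observations"):
        AlignedSeries(
            "p", np.array(["a", "a", "b"]), np.array([0.0, 6.0, 0.0]),
            np.array([1.0, 2.0, 3.0]),
        )


def test_single_subject_falls_back_to_fixed_effects(make_cosinor):
    times = np.arange(0.0, 30.0, 6.0)
    subjects = np.array(["a"] * 5)
    y = make_cosinor(times, amplitude=1.5, peak_h=2.0)
    with pytest.warns(UserWarning, match="fixed effects"):
        fit = fit_cosinor_mixed(_series(times, subjects, y))
    assert fit.amplitude == pytest.approx(1.5, abs=1e-6)
    assert fit.variance_ratio == 0.0
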
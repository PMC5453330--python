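"""Occupancy summaries and moderated day/night comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from dielfit import OccupancySimSpec, generate_occupancy
from dielfit.errors import InsufficientDataError
from dielfit.occupancy import (
    condition_mean,
    condition_summary,
    cosine_fit_fraction,
    day_night_compare,
    fit_variance_prior,
    moderated_group_test,
    squeeze_variances,
    timepoint_means,
    timepoint_pair_compare,
    trigamma_inverse,
)
from dielfit.timecourse import OccupancyTable

from conftest import occupancy_design


def _occ(scores, zts, condition="wt", occupied=None):
    scores = np.atleast_2d(scores)
    values = pd.DataFrame(scores, index=[f"l{i}" for i in range(scores.shape[0])],
                          columns=[f"s{i}" for i in range(scores.shape[1])])
    samples = pd.DataFrame(
        {"condition": condition, "zt_time": zts, "day": 1,
         "replicate": np.arange(len(zts))},
        index=values.columns,
    )
    return OccupancyTable(values, samples, occupied)


ZT12 = np.tile([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 2)


class TestSummaries:
    def test_condition_mean_identical_scores(self):
        occ = _occ(np.full((2, 12), 1.5), ZT12)
        means = condition_mean(occ)
        assert np.allclose(means["wt"], 1.5)

    def test_condition_offset_recovered_noiseless(self):
        base, _ = generate_occupancy(
            OccupancySimSpec(n_loci=5, base_mean=1.0, noise_sd=0.0, seed=1,
                             name="wt"),
            occupancy_design(),
        )
        shifted, _ = generate_occupancy(
            OccupancySimSpec(n_loci=5, base_mean=1.0, condition_offset=0.3,
                             noise_sd=0.0, seed=1, name="ko"),
            occupancy_design(),
        )
        diff = condition_mean(shifted)["ko"] - condition_mean(base)["wt"].to_numpy()
        assert np.allclose(diff, 0.3)

    def test_mean_of_timepoint_means_is_grand_mean_when_balanced(self):
        rng = np.random.default_rng(0)
        occ = _occ(rng.normal(size=(4, 12)), ZT12)
        tp = timepoint_means(occ)
        assert np.allclose(tp.mean(axis=1), occ.values.mean(axis=1))

    def test_timepoint_means_average_replicates(self):
        occ = _occ([[1.0, 2.0] + [0.0] * 10],
                   np.array([2.0, 2.0, 6, 6, 10, 10, 14, 14, 18, 18, 22, 22]))
        tp = timepoint_means(occ)
        assert tp.loc["l0", "ZT2"] == pytest.approx(1.5)

    def test_missing_replicate_uses_available(self):
        scores = np.ones((1, 12))
        scores[0, 0] = np.nan
        occ = _occ(scores, ZT12)
        tp = timepoint_means(occ)
        assert tp.loc["l0", "ZT2"] == pytest.approx(1.0)

    def test_condition_summary_reports_mean_and_median(self):
        occ = _occ(np.arange(24.0).reshape(2, 12), ZT12)
        summary = condition_summary(condition_mean(occ))
        assert set(summary.columns) == {"mean", "median"}


class TestVariancePrior:
    def test_trigamma_inverse_round_trip(self):
        for y in (0.1, 0.5, 2.0, 10.0, 100.0):
            assert trigamma_inverse(float(special.polygamma(1, y))) == \
                pytest.approx(y, rel=1e-6)

    def test_prior_recovers_planted_hyperparameters(self):
        """Variances drawn from s0^2 * d0/chi2_d0 scaled chi2_d sampling noise."""
        rng = np.random.default_rng(6)
        d, d0, s0 = 10, 8.0, 0.25
        true_var = s0 * d0 / rng.chisquare(d0, size=20_000)
        s2 = true_var * rng.chisquare(d, size=20_000) / d
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(7)
        s2 = rng.chisquare(6, size=500) / 6 * 0.3
        post, d0, s0_sq = squeeze_variances(s2, 6)
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_prior_df_zero_disables_moderation(self):
        s2 = np.array([0.1, 0.5, 1.0])
        post, d0, _ = squeeze_variances(s2, 4, prior_df=0)
        assert d0 == 0 and np.allclose(post, s2)

    def test_prior_df_infinite_pools_fully(self):
        s2 = np.array([0.1, 0.5, 1.0])
        post, d0, s0_sq = squeeze_variances(s2, 4, prior_df=np.inf)
        assert np.isinf(d0) and np.allclose(post, s0_sq)


class TestModeratedTest:
    def test_identical_groups_null_result(self):
        scores = np.tile(np.arange(6.0), (3, 2)).reshape(3, 12)
        occ = _occ(np.hstack([scores[:, :6], scores[:, :6]]), ZT12)
        res = moderated_group_test(occ, [f"s{i}" for i in range(6)],
                                   [f"s{i}" for i in range(6, 12)])
        assert np.allclose(res.table["M"], 0.0)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_prior_df_zero_equals_classical_pooled_t(self):
        """Closed-form oracle: ordinary two-sample pooled-variance t."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(10, 12))
        occ = _occ(scores, ZT12)
        a = [f"s{i}" for i in range(6)]
        b = [f"s{i}" for i in range(6, 12)]
        res = moderated_group_test(occ, a, b, prior_df=0)
        for i in range(10):
            t_oracle, p_oracle = stats.ttest_ind(scores[i, 6:], scores[i, :6],
                                                 equal_var=True)
            assert res.table["t"].iloc[i] == pytest.approx(t_oracle, abs=1e-10)
            assert res.table["p_value"].iloc[i] == pytest.approx(p_oracle, abs=1e-10)

    def test_group_too_small(self):
        occ = _occ(np.ones((2, 12)), ZT12)
        with pytest.raises(InsufficientDataError):
            moderated_group_test(occ, ["s0"], [f"s{i}" for i in range(1, 12)])

    def test_m_a_bijection(self):
        rng = np.random.default_rng(9)
        occ = _occ(rng.normal(size=(20, 12)), ZT12)
        res = day_night_compare(occ)
        t = res.table
        assert np.allclose(t["mean_b"], t["A"] + t["M"] / 2)
        assert np.allclose(t["mean_a"], t["A"] - t["M"] / 2)


class TestDayNight:
    def test_simple_day_night_values(self):
        scores = np.where(np.asarray(ZT12) >= 12, 2.0, 1.0)[None, :]
        occ = _occ(scores, ZT12)
        res = day_night_compare(occ, prior_df=0)
        assert res.table["A"].iloc[0] == pytest.approx(1.5)
        assert res.table["M"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates_m(self, null_occupancy):
        occ, _ = null_occupancy
        res = day_night_compare(occ)
        flipped = OccupancyTable(
            occ.values,
            occ.samples.assign(zt_time=(occ.samples["zt_time"] + 12) % 24),
            occ.occupied,
        )
        res2 = day_night_compare(flipped)
        assert np.allclose(res2.table["M"], -res.table["M"])
        assert np.allclose(res2.table["A"], res.table["A"])

    def test_null_calibration(self, null_occupancy):
        occ, _ = null_occupancy
        res = day_night_compare(occ)
        frac = res.table["significant"].mean()
        # 99% binomial band around 0.05 at n=400
        band = 2.58 * np.sqrt(0.05 * 0.95 / 400)
        assert abs(frac - 0.05) <= band + 1e-9

    def test_planted_night_effect_recovered(self):
        spec = OccupancySimSpec(n_loci=500, night_effect=0.5,
                                affected_fraction=0.1, noise_sd=0.2, seed=11)
        occ, truth = generate_occupancy(spec, occupancy_design())
        res = day_night_compare(occ)
        affected = truth["affected"].to_numpy()
        sig = res.table["significant"].to_numpy()
        assert sig[affected].mean() >= 0.9
        assert sig[~affected].mean() <= 0.07

    def test_restricts_to_occupied_flag(self):
        rng = np.random.default_rng(12)
        occ = _occ(rng.normal(size=(4, 12)), ZT12,
                   occupied=[True, False, True, False])
        res = day_night_compare(occ)
        assert list(res.table.index) == ["l0", "l2"]


class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma_ebayes(self, tmp_path):
        """Independent reference: limma's eBayes on the same two-group fixture
        must reproduce prior df, prior variance, t and p to numerical precision."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(3)
        scores = rng.normal(0.0, 0.3, size=(30, 12))
        scores[:5, 6:] += 0.5
        occ = _occ(scores, ZT12)
        a = [f"s{i}" for i in range(6)]
        b = [f"s{i}" for i in range(6, 12)]
        res = moderated_group_test(occ, a, b)
        mat = tmp_path / "mat.txt"
        out = tmp_path / "limma.txt"
        np.savetxt(mat, scores)
        script = (
            "suppressMessages(library(limma));"
            f"m <- as.matrix(read.table('{mat}'));"
            "grp <- factor(rep(c('a','b'), each=6));"
            "fit <- eBayes(lmFit(m, model.matrix(~grp)));"
            "cat(fit$df.prior, fit$s2.prior, '\\n');"
            f"write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]), '{out}')"
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        d0_ref, s0_ref = map(float, proc.stdout.split())
        assert res.prior_df == pytest.approx(d0_ref, rel=1e-4)
        assert res.prior_var == pytest.approx(s0_ref, rel=1e-4)
        ref = pd.read_csv(out, sep=" ")
        assert np.allclose(res.table["t"], ref["t"], atol=1e-10)
        assert np.allclose(res.table["p_value"], ref["p"], atol=1e-10)


class TestTimepointPair:
    def test_identical_timepoints_zero_m(self):
        occ = _occ(np.ones((3, 12)), ZT12)
        res = timepoint_pair_compare(occ, prior_df=0)
        assert np.allclose(res.table["M"], 0.0)

    def test_noiseless_anticipation_recovered(self):
        spec = OccupancySimSpec(n_loci=10, anticipation_effect=0.4, clock_on=True,
                                affected_fraction=0.5, noise_sd=0.0, seed=4)
        occ, truth = generate_occupancy(spec, occupancy_design())
        with pytest.warns(UserWarning):  # zero variances: moderation disabled
            res = timepoint_pair_compare(occ)
        affected = truth["affected"].to_numpy()
        assert np.allclose(res.table["M"][affected], 0.4)
        assert np.allclose(res.table["M"][~affected], 0.0)
        assert res.table["significant"][affected].all()

    def test_noisy_anticipation_detected(self):
        spec = OccupancySimSpec(n_loci=500, anticipation_effect=0.4, clock_on=True,
                                affected_fraction=0.1, noise_sd=0.1, seed=11,
                                )
        cfg = occupancy_design(replicates_per_timepoint=2)  # 4 samples per ZT
        occ, truth = generate_occupancy(spec, cfg)
        res = timepoint_pair_compare(occ)
        affected = truth["affected"].to_numpy()
        sig = res.table["significant"].to_numpy()
        assert sig[affected].mean() >= 0.9
        assert sig[~affected].mean() <= 0.07

    def test_clock_off_negative_control(self):
        spec = OccupancySimSpec(n_loci=400, anticipation_effect=0.4, clock_on=False,
                                affected_fraction=0.5, noise_sd=0.2, seed=8)
        occ, _ = generate_occupancy(spec, occupancy_design())
        res = timepoint_pair_compare(occ)
        up_sig = (res.table["significant"] & (res.table["M"] > 0)).mean()
        band = 2.58 * np.sqrt(0.025 * 0.975 / 400)
        assert up_sig <= 0.025 + band  # no excess over the null rate


class TestCosineFitFraction:
    def test_null_fraction_near_nominal(self, null_occupancy):
        occ, _ = null_occupancy
        frac = cosine_fit_fraction(occ, p_threshold=0.05)
        band = 2.58 * np.sqrt(0.05 * 0.95 / occ.n_features)
        assert abs(frac.fraction - 0.05) <= band + 1e-9

    def test_saturated_when_all_cosine(self):
        rng = np.random.default_rng(5)
        t = np.asarray(ZT12, dtype=float)
        scores = 1.0 + np.cos(2 * np.pi * (t - 10) / 24)[None, :] \
            + rng.normal(0, 0.05, size=(50, 12))
        occ = _occ(scores, ZT12)
        frac = cosine_fit_fraction(occ)
        assert frac.fraction >= 0.98

    def test_empty_table_errors(self):
        occ = _occ(np.empty((0, 12)), ZT12)
        with pytest.raises(InsufficientDataError):
            cosine_fit_fraction(occ)
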
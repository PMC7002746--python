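import json
import math
import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps
from scipy.special import comb
from scipy.stats import multivariate_normal

from erqc.simulate import default_cohort_specs, simulate_cohort
from erqc.stats import (ObservationTable, OptimizationError, compare_cohorts,
                        fisher_exact, fit_lmm_varpower, plot_log_response,
                        select_variance_structure, spearman, students_t)


def make_table(rows):
    return ObservationTable(pd.DataFrame(
        rows, columns=["case_id", "cohort", "response", "positive_count"]))


def simulate_lmm(rng, m=20, ducts=5, beta1=0.0, sb=0.4, sw=0.6, delta=0.0,
                 counts=(2, 61)):
    """Independent generator for the model y* = b0 + b1*g + b_i + eps_ij."""
    rows = []
    for i in range(m):
        b = rng.normal(0.0, sb)
        g = i >= m // 2
        for _ in range(ducts):
            v = int(rng.integers(*counts))
            e = rng.normal(0.0, sw * v ** delta)
            rows.append((f"c{i}", "grp2" if g else "grp1",
                         math.exp(1.0 + beta1 * g + b + e), v))
    return make_table(rows)


def dense_loglik(fit, table):
    """Brute-force marginal Gaussian log-likelihood at the fitted parameters."""
    df = table.data
    d = (df["cohort"] == fit.contrast).to_numpy(float)
    mu = fit.beta[0] + fit.beta[1] * d
    idx = pd.factorize(df["case_id"])[0]
    v = np.abs(df["positive_count"].to_numpy(float))
    V = fit.sigma_b2 * (idx[:, None] == idx[None, :]).astype(float) \
        + np.diag(fit.sigma2 * v ** (2.0 * fit.delta))
    return multivariate_normal(mean=mu, cov=V).logpdf(
        df["log_response"].to_numpy())


class TestObservationTable:
    def test_rejects_nonpositive_response(self):
        with pytest.raises(ValueError):
            make_table([("a", "x", 0.0, 3), ("b", "x", 1.0, 3)])

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            make_table([("a", "x", 1.0, 0), ("b", "x", 1.0, 3)])

    def test_log_response_derived(self):
        t = make_table([("a", "x", math.e, 3), ("b", "x", 1.0, 3)])
        assert t.data["log_response"].iloc[0] == pytest.approx(1.0)

    def test_csv_roundtrip(self, tmp_path):
        t = make_table([("a", "x", 2.0, 3), ("b", "y", 4.0, 5)])
        t.to_csv(tmp_path / "t.csv")
        back = ObservationTable.from_csv(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(t.data, back.data)


class TestMixedModel:
    def test_balanced_one_duct_beta_is_mean_difference(self):
        rng = np.random.default_rng(0)
        t = simulate_lmm(rng, m=12, ducts=1)
        fit = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        y = t.data["log_response"]
        g = t.data["cohort"] == "grp2"
        assert fit.beta[1] == pytest.approx(y[g].mean() - y[~g].mean(),
                                            abs=1e-8)
        assert fit.beta[0] == pytest.approx(y[~g].mean(), abs=1e-8)

    def test_one_duct_per_case_reduces_to_pooled_t_test(self):
        rng = np.random.default_rng(1)
        t = simulate_lmm(rng, m=17, ducts=1)
        fit = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        y = t.data["log_response"]
        g = t.data["cohort"] == "grp2"
        tt = students_t(y[g], y[~g])
        assert fit.p_cohort == pytest.approx(tt.p_value, abs=1e-10)

    @pytest.mark.parametrize("fix_delta", [0.0, None])
    def test_loglik_matches_dense_oracle(self, fix_delta):
        rng = np.random.default_rng(2)
        t = simulate_lmm(rng, m=15, ducts=4, beta1=0.5, delta=-0.3)
        fit = fit_lmm_varpower(t, fix_delta=fix_delta, baseline="grp1")
        assert fit.converged
        assert fit.loglik == pytest.approx(dense_loglik(fit, t), abs=1e-6)

    def test_bruteforce_optimizer_cannot_improve(self):
        """Full-likelihood Nelder-Mead over all raw parameters finds no better optimum."""
        rng = np.random.default_rng(3)
        t = simulate_lmm(rng, m=12, ducts=4, beta1=0.4, delta=-0.2)
        fit = fit_lmm_varpower(t, baseline="grp1")
        df = t.data
        d = (df["cohort"] == fit.contrast).to_numpy(float)
        idx = pd.factorize(df["case_id"])[0]
        v = np.abs(df["positive_count"].to_numpy(float))
        y = df["log_response"].to_numpy()

        def negll(p):
            b0, b1, ls2, lsb2, delta = p
            V = math.exp(lsb2) * (idx[:, None] == idx[None, :]).astype(float) \
                + np.diag(math.exp(ls2) * v ** (2.0 * delta))
            try:
                return -multivariate_normal(mean=b0 + b1 * d, cov=V).logpdf(y)
            except np.linalg.LinAlgError:
                return 1e10

        from scipy.optimize import minimize
        x0 = np.array([fit.beta[0] + 0.05, fit.beta[1] - 0.05,
                       math.log(fit.sigma2) + 0.1,
                       math.log(max(fit.sigma_b2, 1e-8)) - 0.1,
                       fit.delta + 0.05])
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        assert -res.fun <= fit.loglik + 1e-4

    def test_fix_delta_zero_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(4)
        t = simulate_lmm(rng, m=15, ducts=4, beta1=0.5)
        fit = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        sm_fit = smf.mixedlm("log_response ~ C(cohort, Treatment('grp1'))",
                             t.data, groups=t.data["case_id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.beta[1] == pytest.approx(sm_fit.params.iloc[1], abs=1e-4)

    def test_varpower_matches_r_nlme(self, tmp_path):
        """R nlme::lme with varPower — the canonical implementation — agrees."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        specs = default_cohort_specs()
        low, _ = simulate_cohort(specs["low_er"], 11)
        ctl, _ = simulate_cohort(specs["control"], 12)
        comb = low.concat(ctl)
        fit = fit_lmm_varpower(comb, baseline="control")
        csv = tmp_path / "obs.csv"
        comb.data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text("""
suppressMessages(library(nlme))
a <- commandArgs(TRUE)
d <- read.csv(a[1])
d$cohort <- factor(d$cohort, levels = c(a[2], a[3]))
m <- lme(log(response) ~ cohort, random = ~1 | case_id,
         weights = varPower(form = ~positive_count),
         data = d, method = "ML",
         control = lmeControl(maxIter = 500, msMaxIter = 500,
                              returnObject = TRUE))
out <- list(loglik = as.numeric(logLik(m)),
            beta1 = as.numeric(fixef(m)[2]),
            delta = as.numeric(coef(m$modelStruct$varStruct,
                                    unconstrained = FALSE)),
            sigma_b2 = as.numeric(VarCorr(m)[1, 1]))
cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
""")
        res = subprocess.run(["Rscript", str(script), str(csv),
                              "control", "low_er"],
                             capture_output=True, text=True, check=True)
        r = json.loads(res.stdout)
        assert fit.loglik == pytest.approx(r["loglik"], abs=1e-3)
        assert fit.beta[1] == pytest.approx(r["beta1"], abs=1e-3)
        assert fit.delta == pytest.approx(r["delta"], abs=0.02)
        assert fit.sigma_b2 == pytest.approx(r["sigma_b2"], rel=0.01)

    def test_aic_definition_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        t = simulate_lmm(rng, m=10, ducts=3)
        fit = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        shifted = make_table([(r.case_id, r.cohort, r.response * math.e,
                               r.positive_count)
                              for r in t.data.itertuples()])
        fit2 = fit_lmm_varpower(shifted, fix_delta=0.0, baseline="grp1")
        assert fit2.beta[0] == pytest.approx(fit.beta[0] + 1.0, abs=1e-6)
        assert fit2.beta[1] == pytest.approx(fit.beta[1], abs=1e-6)
        assert fit2.sigma2 == pytest.approx(fit.sigma2, rel=1e-6)
        assert fit2.sigma_b2 == pytest.approx(fit.sigma_b2, abs=1e-6)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            fit_lmm_varpower(make_table([("a", "x", 1.0, 2)]))


class TestVarianceSelection:
    def test_identical_logliks_choose_null(self):
        rng = np.random.default_rng(6)
        t = simulate_lmm(rng, m=10, ducts=3)
        null = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        alt = replace(null, delta_fixed=False, n_params=5,
                      aic=-2 * null.loglik + 10)
        chosen, lrt = select_variance_structure(null, alt)
        assert lrt.statistic == 0.0 and lrt.p_value == 1.0
        assert chosen is null

    def test_alt_worse_than_null_raises(self):
        rng = np.random.default_rng(7)
        t = simulate_lmm(rng, m=10, ducts=3)
        null = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
        bad_alt = replace(null, delta_fixed=False, loglik=null.loglik - 1.0)
        with pytest.raises(OptimizationError):
            select_variance_structure(null, bad_alt)

    def test_lrt_detects_strong_variance_power(self):
        """delta = -0.5 with wide count spread: alternative chosen in > 80% of reps."""
        rng = np.random.default_rng(8)
        wins = 0
        reps = 25
        for _ in range(reps):
            t = simulate_lmm(rng, m=20, ducts=5, delta=-0.5, counts=(2, 101))
            null = fit_lmm_varpower(t, fix_delta=0.0, baseline="grp1")
            alt = fit_lmm_varpower(t, baseline="grp1")
            chosen, _ = select_variance_structure(null, alt)
            wins += not chosen.delta_fixed
        assert wins / reps > 0.8


class TestClassicalTests:
    def test_t_identical_samples(self):
        r = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_t_degenerate_variance(self):
        assert students_t([1.0, 1.0], [1.0, 1.0]).p_value == 1.0
        assert students_t([1.0, 1.0], [2.0, 2.0]).p_value == 0.0

    def test_t_matches_quadrature_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        r = students_t(x, y)
        df = len(x) + len(y) - 2
        tail, _ = integrate.quad(lambda u: sps.t.pdf(u, df),
                                 abs(r.statistic), np.inf)
        assert r.p_value == pytest.approx(2 * tail, rel=1e-8)

    def test_fisher_unit_diagonal(self):
        assert fisher_exact([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)

    def test_fisher_modal_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_fisher_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_fisher_matches_enumeration_oracle(self):
        """Point-probability two-sided rule vs exhaustive hypergeometric sum."""
        def oracle(a, b, c, d):
            r1, c1, n = a + b, a + c, a + b + c + d
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            probs = {k: comb(c1, k, exact=True)
                     * comb(n - c1, r1 - k, exact=True)
                     for k in range(lo, hi + 1)}
            total = comb(n, r1, exact=True)
            p_obs = probs[a]
            return sum(p for p in probs.values()
                       if p <= p_obs * (1 + 1e-7)) / total

        rng = np.random.default_rng(10)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 9, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            expected = oracle(int(a), int(b), int(c), int(d))
            got = fisher_exact([[a, b], [c, d]]).p_value
            assert got == pytest.approx(expected, rel=1e-7)

    def test_spearman_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 8.0, 20.0]).statistic == pytest.approx(1.0)
        assert spearman(x, [20.0, 8.0, 3.0, 2.0]).statistic == pytest.approx(-1.0)

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_rank_formula_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x, y = rng.normal(size=(2, 6))
            expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert spearman(x, y).statistic == pytest.approx(expected,
                                                             abs=1e-12)

    def test_spearman_p_near_exact_permutation_p(self):
        # the n-2 df t approximation tracks the exact permutation null to
        # ~0.02 for clear monotone association (mid-range r is cruder)
        from itertools import permutations
        rng = np.random.default_rng(110)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        r = spearman(x, y)
        rank = sps.rankdata
        expected_r = np.corrcoef(rank(x), rank(y))[0, 1]
        assert r.statistic == pytest.approx(expected_r, abs=1e-12)
        null = [abs(np.corrcoef(rank(x), rank(np.asarray(p)))[0, 1])
                for p in permutations(y)]
        perm_p = np.mean([v >= abs(expected_r) - 1e-12 for v in null])
        assert abs(r.p_value - perm_p) <= 0.02


class TestCompareCohorts:
    def test_recovers_published_median_ratio(self):
        """beta1 ~ ln(16.5/30.8) when cohorts differ only in location."""
        specs = default_cohort_specs()
        est = []
        ss = np.random.SeedSequence(12)
        for _ in range(10):
            a, b = ss.spawn(2)
            low, _ = simulate_cohort(specs["low_er"], a)
            ctl, _ = simulate_cohort(specs["control"], b)
            est.append(compare_cohorts(low, ctl).chosen.beta[1])
        assert np.mean(est) == pytest.approx(math.log(16.5 / 30.8), abs=0.1)

    def test_null_rejection_rate_near_alpha(self):
        """Identical generators: about 5% of comparisons reject at 0.05."""
        from dataclasses import replace as dreplace
        specs = default_cohort_specs()
        spec_a = specs["control"]
        spec_b = dreplace(spec_a, name="other")
        rejections = 0
        reps = 40
        ss = np.random.SeedSequence(13)
        for _ in range(reps):
            a, b = ss.spawn(2)
            ta, _ = simulate_cohort(spec_a, a)
            tb, _ = simulate_cohort(spec_b, b)
            rejections += compare_cohorts(ta, tb).p_cohort < 0.05
        assert rejections / reps <= 0.175  # ~5% plus binomial noise at n=40

    def test_refuses_multi_cohort_table(self):
        specs = default_cohort_specs()
        low, _ = simulate_cohort(specs["low_er"], 1)
        ctl, _ = simulate_cohort(specs["control"], 2)
        with pytest.raises(ValueError):
            compare_cohorts(low.concat(ctl), ctl)

    def test_report_and_plot(self, tmp_path):
        specs = default_cohort_specs()
        low, _ = simulate_cohort(specs["low_er"], 3)
        ctl, _ = simulate_cohort(specs["control"], 4)
        res = compare_cohorts(low, ctl)
        payload = res.to_dict()
        assert payload["baseline"] == "control"
        assert payload["contrast"] == "low_er"
        assert 0.0 <= payload["p_cohort"] <= 1.0
        md = res.to_markdown()
        assert "Cohort contrast" in md and "low_er" in md
        plot_log_response([low, ctl], tmp_path / "box.png")
        assert (tmp_path / "box.png").stat().st_size > 0
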
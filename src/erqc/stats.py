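"""Cohort inference: random-intercept mixed model with power-of-count variance.

Ducts from the same patient are correlated, so cohort comparisons of the
per-duct measurement y (dynamic range or mean nuclear OD) use a linear mixed
model on the log scale,

    ln y_ij = beta0 + beta1 * 1[cohort_i = contrast] + b_i + eps_ij,
    b_i   ~ N(0, sigma_b^2)                         (case random intercept)
    eps_ij ~ N(0, sigma^2 * |v_ij|^(2*delta))       (varPower residual)

where v_ij is the duct's positive-cell count: the precision of a mean
nuclear OD depends on how many positive nuclei contributed, and the power
exponent delta lets the residual variance shrink (delta < 0) or grow with
the count.  Parameters are estimated by maximum likelihood; beta and sigma^2
are profiled out in closed form by generalized least squares given
(sigma_b^2/sigma^2, delta), and the profiled log-likelihood is optimised
numerically over those two parameters (Woodbury identities keep each
case-block solve O(n_i)).  The homoscedastic random-intercept model is the
special case delta = 0, and the choice between the two variance structures
is made by a 1-df likelihood-ratio test backed by AIC.

Inference for the cohort contrast defaults to a Wald t statistic with
``N - p`` degrees of freedom and the bias-corrected residual scale
``RSS/(N - p)``; with one duct per case and delta = 0 this reduces exactly
to the pooled two-sample t-test.  A plain normal-reference Wald test is
available via ``inference="normal"``.  Classical auxiliary tests (Student's
t, Fisher's exact, Spearman) are exposed behind the same result type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ObservationTable",
    "MixedModelFit",
    "TestResult",
    "CohortComparison",
    "OptimizationError",
    "fit_lmm_varpower",
    "select_variance_structure",
    "students_t",
    "fisher_exact",
    "spearman",
    "compare_cohorts",
    "plot_log_response",
]

_OBS_COLUMNS = ("case_id", "cohort", "response", "positive_count")


class OptimizationError(RuntimeError):
    """Raised when nested fits are inconsistent (alternative worse than null)."""


@dataclass(frozen=True)
class ObservationTable:
    """Duct-level observations: one row per duct, grouped by case.

    Columns: ``case_id``, ``cohort``, ``response`` (the untransformed per-duct
    measurement, strictly positive), ``positive_count`` (the variance
    covariate, >= 1) and the derived ``log_response`` (natural log).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _OBS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if len(df) == 0:
            raise ValueError("observation table is empty")
        resp = df["response"].to_numpy(dtype=float)
        if not np.all(np.isfinite(resp)) or np.any(resp <= 0):
            raise ValueError("response must be finite and > 0 (log transform)")
        counts = df["positive_count"].to_numpy(dtype=float)
        if np.any(counts < 1):
            raise ValueError("positive_count must be >= 1")
        df = df.copy()
        df["log_response"] = np.log(resp)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationTable":
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data[list(_OBS_COLUMNS)].to_csv(path, index=False)

    def concat(self, other: "ObservationTable") -> "ObservationTable":
        return ObservationTable(
            pd.concat([self.data[list(_OBS_COLUMNS)],
                       other.data[list(_OBS_COLUMNS)]], ignore_index=True)
        )

    @property
    def cohorts(self) -> list[str]:
        return list(pd.unique(self.data["cohort"]))

    def n_cases(self, cohort: str | None = None) -> int:
        df = self.data
        if cohort is not None:
            df = df[df["cohort"] == cohort]
        return df["case_id"].nunique()


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  #: one of {t_test, fisher_exact, spearman, lrt}

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class MixedModelFit:
    """Maximum-likelihood fit of the random-intercept varPower model."""

    beta: np.ndarray  #: (intercept, cohort contrast)
    beta_se: np.ndarray
    sigma_b2: float  #: between-case (random-intercept) variance, ML
    sigma2: float  #: residual variance scale, ML
    delta: float  #: variance power exponent (0 when fixed homoscedastic)
    loglik: float
    aic: float
    p_cohort: float  #: two-sided Wald p for the cohort contrast
    wald_statistic: float
    df_resid: int
    converged: bool
    n_obs: int
    n_cases: int
    n_params: int
    baseline: str  #: reference cohort (indicator 0)
    contrast: str  #: cohort carried by the indicator (beta1 = contrast - baseline)
    delta_fixed: bool
    inference: str
    message: str = ""


def _prepare(table: ObservationTable, baseline: str | None):
    df = table.data
    cohorts = list(pd.unique(df["cohort"]))
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    if baseline is None:
        baseline = cohorts[0]
    if baseline not in cohorts:
        raise ValueError(f"baseline {baseline!r} not among cohorts {cohorts}")
    contrast = cohorts[1] if cohorts[0] == baseline else cohorts[0]
    for c in cohorts:
        if df.loc[df["cohort"] == c, "case_id"].nunique() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 cases")
    if len(df) < 3:
        raise ValueError("singular case structure: too few observations")
    y = df["log_response"].to_numpy(dtype=float)
    d = (df["cohort"] == contrast).to_numpy(dtype=float)
    v = np.abs(df["positive_count"].to_numpy(dtype=float))
    idx, cases = pd.factorize(df["case_id"])
    return y, d, v, idx, len(cases), baseline, contrast


def _profile_gls(eta: float, delta: float, y, d, v, idx, m):
    """Profiled GLS given (eta = ln(sigma_b^2/sigma^2), delta).

    Uses the Woodbury identity per case block:
    R_i = theta*J + diag(w_i), w_ij = v_ij^(2*delta).
    Returns (loglik, beta, A, rss, sigma2_ml) with A = X' R^{-1} X.
    """
    n = y.size
    theta = math.exp(eta)
    logw = 2.0 * delta * np.log(v)
    iw = np.exp(-logw)
    s = np.bincount(idx, weights=iw, minlength=m)
    c = theta / (1.0 + theta * s)

    def quad(a, b):
        sa = np.bincount(idx, weights=iw * a, minlength=m)
        sb = np.bincount(idx, weights=iw * b, minlength=m)
        return float(np.sum(iw * a * b) - np.sum(c * sa * sb))

    ones = np.ones(n)
    A = np.array([[quad(ones, ones), quad(ones, d)],
                  [0.0, quad(d, d)]])
    A[1, 0] = A[0, 1]
    bvec = np.array([quad(ones, y), quad(d, y)])
    beta = np.linalg.solve(A, bvec)
    r = y - beta[0] - beta[1] * d
    rss = quad(r, r)
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / n
    logdet = float(np.sum(logw) + np.sum(np.log1p(theta * s)))
    loglik = -0.5 * n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0) \
        - 0.5 * logdet
    return loglik, beta, A, rss, sigma2


_ETA_BOUNDS = (-20.0, 10.0)
_DELTA_BOUNDS = (-3.0, 3.0)


def _moment_start(y, idx, m) -> float:
    """ln(theta) start: half the between-case variance of case means over within var."""
    case_mean = np.bincount(idx, weights=y) / np.bincount(idx)
    between = float(np.var(case_mean)) if m > 1 else 0.0
    within = float(np.var(y - case_mean[idx]))
    theta0 = max(between / 2.0, 1e-4) / max(within, 1e-6)
    return float(np.clip(math.log(theta0), *_ETA_BOUNDS))


def fit_lmm_varpower(
    table: ObservationTable,
    fix_delta: float | None = None,
    baseline: str | None = None,
    inference: str = "t",
) -> MixedModelFit:
    """ML fit of ``log_response ~ cohort`` with case random intercept and varPower.

    Parameters
    ----------
    table
        Observation table holding exactly two cohorts.
    fix_delta
        Hold the variance power exponent fixed (``0.0`` gives the
        homoscedastic random-intercept model); ``None`` estimates it.
    baseline
        Reference cohort (indicator 0).  Defaults to the first cohort in
        table order; ``beta[1]`` is the contrast-minus-baseline effect on the
        log scale.
    inference
        ``"t"`` (default): Wald t with ``N - 2`` df and residual scale
        ``RSS/(N - 2)``; ``"normal"``: Wald z with the ML residual scale.
    """
    if inference not in ("t", "normal"):
        raise ValueError("inference must be 't' or 'normal'")
    y, d, v, idx, m, baseline, contrast = _prepare(table, baseline)
    n = y.size
    eta0 = _moment_start(y, idx, m)

    if fix_delta is None:
        starts = [(eta0, 0.0), (eta0 - 2.0, 0.0), (eta0 + 2.0, 0.0),
                  (eta0, -0.5), (eta0, 0.5)]
        bounds = [_ETA_BOUNDS, _DELTA_BOUNDS]

        def nll(params):
            try:
                return -_profile_gls(params[0], params[1], y, d, v, idx, m)[0]
            except np.linalg.LinAlgError:
                return 1e10  # numerically singular corner of the bounds
    else:
        starts = [(eta0,), (eta0 - 2.0,), (eta0 + 2.0,),
                  (_ETA_BOUNDS[0],), (0.0,)]
        bounds = [_ETA_BOUNDS]

        def nll(params):
            try:
                return -_profile_gls(params[0], fix_delta, y, d, v, idx, m)[0]
            except np.linalg.LinAlgError:
                return 1e10

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(nll, np.asarray(x0), method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-9})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    eta_hat = float(best.x[0])
    delta_hat = float(best.x[1]) if fix_delta is None else float(fix_delta)
    loglik, beta, A, rss, sigma2 = _profile_gls(eta_hat, delta_hat, y, d, v, idx, m)
    theta = math.exp(eta_hat)

    p_fixed = 2
    cov_unscaled = np.linalg.inv(A)
    if inference == "t":
        df_resid = n - p_fixed
        scale = rss / df_resid
        beta_se = np.sqrt(scale * np.diag(cov_unscaled))
        wald = beta[1] / beta_se[1]
        p_cohort = 2.0 * sps.t.sf(abs(wald), df_resid)
    else:
        df_resid = n
        beta_se = np.sqrt(sigma2 * np.diag(cov_unscaled))
        wald = beta[1] / beta_se[1]
        p_cohort = 2.0 * sps.norm.sf(abs(wald))

    n_params = 4 if fix_delta is not None else 5  # beta0, beta1, sigma2, sigma_b2[, delta]
    return MixedModelFit(
        beta=beta,
        beta_se=beta_se,
        sigma_b2=theta * sigma2,
        sigma2=sigma2,
        delta=delta_hat,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        p_cohort=float(p_cohort),
        wald_statistic=float(wald),
        df_resid=df_resid,
        converged=bool(any_success and np.isfinite(loglik)),
        n_obs=n,
        n_cases=m,
        n_params=n_params,
        baseline=baseline,
        contrast=contrast,
        delta_fixed=fix_delta is not None,
        inference=inference,
        message=str(best.message),
    )


def select_variance_structure(
    fit_null: MixedModelFit,
    fit_alt: MixedModelFit,
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> tuple[MixedModelFit, TestResult]:
    """Choose between delta = 0 and free delta by a 1-df LRT, backed by AIC.

    The alternative is chosen when the LRT rejects at ``alpha``; otherwise the
    lower-AIC fit wins.  A null log-likelihood exceeding the alternative's by
    more than ``tol`` indicates an optimisation failure and raises.
    """
    if not (fit_null.delta_fixed and not fit_alt.delta_fixed):
        raise ValueError("expected (fixed-delta null, free-delta alternative)")
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits were not computed on the same data")
    diff = fit_alt.loglik - fit_null.loglik
    if diff < -tol:
        raise OptimizationError(
            f"free-delta fit is worse than the null by {-diff:.3g}; "
            "optimization failed"
        )
    stat = max(0.0, 2.0 * diff)
    p = float(sps.chi2.sf(stat, df=1))
    if p < alpha:
        chosen = fit_alt
    else:
        chosen = fit_alt if fit_alt.aic < fit_null.aic else fit_null
    return chosen, TestResult(statistic=stat, p_value=p, method="lrt")


# ---------------------------------------------------------------------------
# classical auxiliary tests


def students_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample Student's t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        # degenerate: no within-group variability
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "t_test")
        return TestResult(math.inf if x.mean() > y.mean() else -math.inf,
                          0.0, "t_test")
    stat, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(stat), float(p), "t_test")


def fisher_exact(table2x2) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided point-probability rule.

    The two-sided p-value sums hypergeometric probabilities of all tables with
    the observed margins whose point probability does not exceed that of the
    observed table.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    odds, p = sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher_exact")


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties), p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant sample")
    r, p = sps.spearmanr(x, y)
    return TestResult(float(r), float(p), "spearman")


# ---------------------------------------------------------------------------
# cohort comparison report


@dataclass(frozen=True)
class CohortComparison:
    """Outcome of comparing one cohort against a reference via the mixed model."""

    fit_null: MixedModelFit
    fit_alt: MixedModelFit
    chosen: MixedModelFit
    lrt: TestResult
    cohort_summary: dict  #: per-cohort median / min / max / n of the raw response
    response_name: str

    @property
    def p_cohort(self) -> float:
        return self.chosen.p_cohort

    @property
    def direction(self) -> str:
        b1 = self.chosen.beta[1]
        rel = "lower" if b1 < 0 else "higher"
        return (f"{self.chosen.contrast} {rel} than {self.chosen.baseline} "
                f"(log-scale effect {b1:+.3f})")

    def to_dict(self) -> dict:
        c = self.chosen
        return {
            "response": self.response_name,
            "baseline": c.baseline,
            "contrast": c.contrast,
            "beta": list(map(float, c.beta)),
            "beta_se": list(map(float, c.beta_se)),
            "p_cohort": c.p_cohort,
            "delta": c.delta,
            "delta_fixed": c.delta_fixed,
            "sigma_b2": c.sigma_b2,
            "sigma2": c.sigma2,
            "loglik": c.loglik,
            "aic": c.aic,
            "variance_structure": "varPower" if not c.delta_fixed else "constant",
            "lrt": {"statistic": self.lrt.statistic, "p_value": self.lrt.p_value},
            "cohort_summary": self.cohort_summary,
            "direction": self.direction,
        }

    def to_markdown(self) -> str:
        c = self.chosen
        lines = [
            f"# Cohort comparison ({self.response_name})",
            "",
            f"Model: log response ~ cohort, case random intercept, "
            f"{'varPower(count)' if not c.delta_fixed else 'constant'} residual "
            f"variance (ML).",
            "",
            "| cohort | n cases | n ducts | median | min | max |",
            "|---|---|---|---|---|---|",
        ]
        for name, s in self.cohort_summary.items():
            lines.append(
                f"| {name} | {s['n_cases']} | {s['n_ducts']} | "
                f"{s['median']:.3g} | {s['min']:.3g} | {s['max']:.3g} |"
            )
        lines += [
            "",
            f"- Cohort contrast ({c.contrast} vs {c.baseline}): "
            f"beta1 = {c.beta[1]:.4f} (SE {c.beta_se[1]:.4f}), "
            f"p = {c.p_cohort:.3g} ({c.inference}-reference Wald)",
            f"- Direction: {self.direction}",
            f"- Variance structure LRT (free delta vs delta=0): "
            f"stat = {self.lrt.statistic:.4f}, p = {self.lrt.p_value:.3g}; "
            f"chosen: {'varPower, delta=%.3f' % c.delta if not c.delta_fixed else 'constant'}",
            f"- sigma_b^2 = {c.sigma_b2:.4f}, sigma^2 = {c.sigma2:.4f}, "
            f"logLik = {c.loglik:.3f}, AIC = {c.aic:.2f}",
            "",
        ]
        return "\n".join(lines)


def _summary(table: ObservationTable) -> dict:
    out = {}
    for name, grp in table.data.groupby("cohort", sort=False):
        resp = grp["response"].to_numpy(dtype=float)
        out[str(name)] = {
            "n_cases": int(grp["case_id"].nunique()),
            "n_ducts": int(len(grp)),
            "median": float(np.median(resp)),
            "min": float(resp.min()),
            "max": float(resp.max()),
        }
    return out


def compare_cohorts(
    low: ObservationTable,
    ref: ObservationTable,
    response_name: str = "dynamic_range",
    inference: str = "t",
) -> CohortComparison:
    """Compare a study cohort against a reference cohort via the mixed model.

    Fits the homoscedastic (delta = 0) and free-delta models, selects the
    variance structure by LRT/AIC, and reports the chosen fit together with
    per-cohort medians and ranges of the untransformed response.  The
    reference cohort is the model baseline, so ``beta1`` is the log-scale
    effect of the study cohort relative to the reference.
    """
    if len(low.cohorts) != 1 or len(ref.cohorts) != 1:
        raise ValueError("each input table must hold exactly one cohort")
    combined = low.concat(ref)
    baseline = ref.cohorts[0]
    fit_null = fit_lmm_varpower(combined, fix_delta=0.0, baseline=baseline,
                                inference=inference)
    fit_alt = fit_lmm_varpower(combined, fix_delta=None, baseline=baseline,
                               inference=inference)
    chosen, lrt = select_variance_structure(fit_null, fit_alt)
    return CohortComparison(
        fit_null=fit_null,
        fit_alt=fit_alt,
        chosen=chosen,
        lrt=lrt,
        cohort_summary=_summary(combined),
        response_name=response_name,
    )


def plot_log_response(tables: Sequence[ObservationTable], path) -> None:
    """Box plot of log-transformed responses by cohort with per-duct points."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, samples = [], []
    for t in tables:
        for name, grp in t.data.groupby("cohort", sort=False):
            labels.append(str(name))
            samples.append(grp["log_response"].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(labels), 4.0))
    ax.boxplot(samples, tick_labels=labels, whis=(0, 100))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for k, vals in enumerate(samples, start=1):
        ax.plot(k + rng.uniform(-0.12, 0.12, vals.size), vals,
                "o", ms=3, color="gray", alpha=0.6)
    ax.set_ylabel("log response")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
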
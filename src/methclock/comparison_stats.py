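"""Full-vs-reduced and cross-platform DNAm-age comparison analyses.

Given per-sample DNAm ages from a clock run with its complete probe set
("full") and from the same samples with platform-missing probes masked
and imputed ("reduced"), these routines quantify the induced bias:

* paired deviation summaries (overall, per dataset, per 5-year age bin),
* OLS regressions of DNAm age on chronological age stratified at the
  transform's adult-age cutoff,
* a t-test for slope equality between independent fits,
* age-acceleration residuals and their regression on covariates,
* an adjusted platform-offset regression for cohorts measured on
  different array generations.

Ordinary least squares throughout (via statsmodels); Pearson
correlations; two-sided tests at alpha = 0.05, no multiplicity
correction.  Samples with unknown chronological age are excluded from
age-dependent outputs but retained in paired deviation summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clock_core import ClockAgeResult, SampleAnnotation, results_to_frame

logger = logging.getLogger(__name__)

DEFAULT_AGE_CUTOFF = 20.0
DEFAULT_BIN_WIDTH = 5.0
MIN_STRATUM_N = 3


# ---------------------------------------------------------------------------
# OLS plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    """Simple-OLS fit of y on x: estimates, SEs, 95% CIs, residuals."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    n: int
    df_resid: int
    residuals: np.ndarray = field(repr=False)
    p_slope: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "ci_intercept_low": self.ci_intercept[0],
            "ci_intercept_high": self.ci_intercept[1],
            "ci_slope_low": self.ci_slope[0],
            "ci_slope_high": self.ci_slope[1],
            "p_slope": self.p_slope,
            "n": self.n,
        }


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS of y on x with intercept; 95% CIs use the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < MIN_STRATUM_N:
        raise ValueError(f"need at least {MIN_STRATUM_N} observations, got {len(x)}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        ci_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        ci_slope=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        residuals=np.asarray(res.resid, dtype=float),
        p_slope=float(res.pvalues[1]),
    )


# ---------------------------------------------------------------------------
# Paired deviation summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    """Paired full-vs-reduced DNAm-age comparison.

    Deviation is ``full - reduced`` throughout, so a positive mean means
    the reduced probe set underestimates DNAm age.
    """

    n: int
    deviation_mean: float
    deviation_sd: float
    corr_full_reduced: float
    corr_full_age: float
    corr_reduced_age: float
    paired_t: float
    paired_p: float
    by_age_bin: pd.DataFrame  # index: bin label; columns: n, mean, sd
    by_dataset: pd.DataFrame  # index: dataset;  columns: n, mean, sd
    bin_width: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "deviation_mean": self.deviation_mean,
            "deviation_sd": self.deviation_sd,
            "corr_full_reduced": self.corr_full_reduced,
            "corr_full_age": self.corr_full_age,
            "corr_reduced_age": self.corr_reduced_age,
            "paired_t": self.paired_t,
            "paired_p": self.paired_p,
            "by_age_bin": self.by_age_bin.to_dict(orient="index"),
            "by_dataset": self.by_dataset.to_dict(orient="index"),
        }


def _aligned_ages(
    full: Sequence[ClockAgeResult], reduced: Sequence[ClockAgeResult]
) -> pd.DataFrame:
    f = results_to_frame(list(full))["dnam_age"]
    r = results_to_frame(list(reduced))["dnam_age"]
    if set(f.index) != set(r.index):
        only_f = sorted(set(f.index) - set(r.index))
        only_r = sorted(set(r.index) - set(f.index))
        raise ValueError(
            f"full and reduced runs cover different samples "
            f"(only-full: {only_f[:5]}, only-reduced: {only_r[:5]})"
        )
    r = r.reindex(f.index)
    return pd.DataFrame({"full": f, "reduced": r})


def paired_deviation_summary(
    full: Sequence[ClockAgeResult],
    reduced: Sequence[ClockAgeResult],
    annotation: SampleAnnotation | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ComparisonReport:
    """Summarise per-sample deviation between two runs of the same clock.

    Age-binned rows use closed-open bins [0, w), [w, 2w), ...; samples
    with unknown age are kept in the overall summary but excluded from
    bins and age correlations.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pair = _aligned_ages(full, reduced)
    dev = pair["full"] - pair["reduced"]

    ages = pd.Series(np.nan, index=pair.index)
    datasets = pd.Series("all", index=pair.index)
    if annotation is not None:
        ann = annotation.table.reindex(pair.index)
        ages = ann["age"]
        datasets = ann["dataset"].fillna("unknown")

    if dev.std(ddof=1) == 0 or pair["full"].std(ddof=1) == 0 or \
            pair["reduced"].std(ddof=1) == 0:
        corr_fr = 1.0 if np.allclose(pair["full"], pair["reduced"]) else float("nan")
    else:
        corr_fr = float(pair["full"].corr(pair["reduced"]))

    known = ages.notna()
    def _age_corr(col: pd.Series) -> float:
        if known.sum() < 2 or col[known].std(ddof=1) == 0 or ages[known].std(ddof=1) == 0:
            return float("nan")
        return float(col[known].corr(ages[known]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance differences
        t_stat, t_p = stats.ttest_rel(pair["full"], pair["reduced"])
    if np.isnan(t_stat) and np.allclose(pair["full"], pair["reduced"]):
        t_stat, t_p = 0.0, 1.0

    binned = pd.DataFrame(columns=["n", "mean", "sd"])
    if known.any():
        edges = np.arange(0.0, float(ages[known].max()) + bin_width, bin_width)
        if edges[-1] <= ages[known].max():
            edges = np.append(edges, edges[-1] + bin_width)
        labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
        cats = pd.cut(ages[known], bins=edges, right=False, labels=labels)
        grouped = dev[known].groupby(cats, observed=True)
        binned = pd.DataFrame({
            "n": grouped.size(),
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1),
        })

    by_ds = dev.groupby(datasets).agg(["size", "mean", lambda s: s.std(ddof=1)])
    by_ds.columns = ["n", "mean", "sd"]

    return ComparisonReport(
        n=len(dev),
        deviation_mean=float(dev.mean()),
        deviation_sd=float(dev.std(ddof=1)),
        corr_full_reduced=corr_fr,
        corr_full_age=_age_corr(pair["full"]),
        corr_reduced_age=_age_corr(pair["reduced"]),
        paired_t=float(t_stat),
        paired_p=float(t_p),
        by_age_bin=binned,
        by_dataset=by_ds,
        bin_width=float(bin_width),
    )


# ---------------------------------------------------------------------------
# Stratified regressions and slope comparison
# ---------------------------------------------------------------------------

def stratified_clock_regression(
    dnam_ages: pd.Series,
    chronological_ages: pd.Series,
    cutoff: float = DEFAULT_AGE_CUTOFF,
) -> dict[str, RegressionFit]:
    """OLS of DNAm age on chronological age within age strata.

    Strata are ``"below"`` (< cutoff) and ``"above"`` (>= cutoff,
    inclusive).  A stratum with fewer than 3 samples of known age is
    omitted with a warning.
    """
    dnam_ages, chronological_ages = dnam_ages.align(chronological_ages, join="inner")
    known = chronological_ages.notna() & dnam_ages.notna()
    fits: dict[str, RegressionFit] = {}
    for name, sel in (
        ("below", known & (chronological_ages < cutoff)),
        ("above", known & (chronological_ages >= cutoff)),
    ):
        if sel.sum() < MIN_STRATUM_N:
            logger.warning(
                "stratum '%s' (%s %g y) has %d samples; omitted",
                name, "<" if name == "below" else ">=", cutoff, int(sel.sum()),
            )
            continue
        fits[name] = ols_fit(
            chronological_ages[sel].to_numpy(), dnam_ages[sel].to_numpy()
        )
    return fits


def compare_slopes(fit_a: RegressionFit, fit_b: RegressionFit) -> tuple[float, float]:
    """t-test for equality of two independent regression slopes.

    t = (b_a - b_b) / sqrt(SE_a^2 + SE_b^2) on n_a + n_b - 4 degrees of
    freedom; two-sided p.  Returns (t, p).  Differences within floating
    precision of zero (e.g. two noiseless fits of the same line) count
    as equal.
    """
    return _t_compare(fit_a.slope, fit_b.slope, fit_a.se_slope, fit_b.se_slope,
                      fit_a.n + fit_b.n - 4)


def _t_compare(est_a: float, est_b: float, se_a: float, se_b: float,
               df: int) -> tuple[float, float]:
    diff = est_a - est_b
    if abs(diff) <= 1e-10 * max(1.0, abs(est_a), abs(est_b)):
        return 0.0, 1.0
    se = np.hypot(se_a, se_b)
    if se == 0:
        return float(np.inf * np.sign(diff)), 0.0
    t = diff / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def compare_intercepts(fit_a: RegressionFit, fit_b: RegressionFit) -> tuple[float, float]:
    """Same form of t-test applied to the two intercepts."""
    return _t_compare(fit_a.intercept, fit_b.intercept,
                      fit_a.se_intercept, fit_b.se_intercept,
                      fit_a.n + fit_b.n - 4)


# ---------------------------------------------------------------------------
# Age acceleration
# ---------------------------------------------------------------------------

def age_acceleration(
    dnam_ages: pd.Series,
    chronological_ages: pd.Series,
    direction: str = "dnam_on_age",
) -> pd.Series:
    """Age-acceleration residuals.

    ``"dnam_on_age"`` (conventional): residuals of DNAm age regressed on
    chronological age; positive = epigenetically older than expected.
    ``"age_on_dnam"`` inverts the regression.  Samples with unknown age
    are excluded; residuals have mean zero by construction.
    """
    if direction not in ("dnam_on_age", "age_on_dnam"):
        raise ValueError(f"unknown direction {direction!r}")
    dnam_ages, chronological_ages = dnam_ages.align(chronological_ages, join="inner")
    known = chronological_ages.notna() & dnam_ages.notna()
    x, y = (chronological_ages, dnam_ages) if direction == "dnam_on_age" \
        else (dnam_ages, chronological_ages)
    fit = ols_fit(x[known].to_numpy(), y[known].to_numpy())
    return pd.Series(fit.residuals, index=dnam_ages.index[known], name="acceleration")


@dataclass(frozen=True)
class AccelerationComparison:
    """Covariate effect on age acceleration, full vs reduced probe set."""

    fit_full: RegressionFit
    fit_reduced: RegressionFit
    slope_t: float
    slope_p: float
    covariate: str
    reference_level: str | None = None

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "reference_level": self.reference_level,
            "full": self.fit_full.to_dict(),
            "reduced": self.fit_reduced.to_dict(),
            "slope_t": self.slope_t,
            "slope_p": self.slope_p,
        }


def _encode_covariate(cov: pd.Series, reference: str | None) -> tuple[pd.Series, str | None]:
    if cov.dtype.kind in "biufc":
        return cov.astype(float), None
    levels = sorted(cov.dropna().unique().tolist())
    if len(levels) < 2:
        raise ValueError(f"covariate is constant ({levels}); cannot regress on it")
    if len(levels) > 2:
        raise ValueError(f"categorical covariate must be binary, got levels {levels}")
    ref = reference if reference in levels else levels[0]
    other = [l for l in levels if l != ref][0]
    return cov.map({ref: 0.0, other: 1.0}).astype(float), str(ref)


def acceleration_covariate_regression(
    accel_full: pd.Series,
    accel_reduced: pd.Series,
    covariate: pd.Series,
    covariate_name: str = "covariate",
    reference: str | None = None,
) -> AccelerationComparison:
    """Regress full- and reduced-probe-set acceleration on a covariate.

    The covariate may be numeric or binary-categorical (encoded 0/1
    against ``reference``, default the lexicographically first level).
    Slopes are compared with :func:`compare_slopes`.
    """
    common = accel_full.index.intersection(accel_reduced.index)
    common = common.intersection(covariate.index)
    if len(common) < MIN_STRATUM_N:
        raise ValueError("too few samples shared between versions and covariate")
    cov, ref = _encode_covariate(covariate.reindex(common), reference)
    if cov.dropna().nunique() < 2:
        raise ValueError("covariate is constant on the analysed samples")
    fit_f = ols_fit(cov.to_numpy(), accel_full.reindex(common).to_numpy())
    fit_r = ols_fit(cov.to_numpy(), accel_reduced.reindex(common).to_numpy())
    t, p = compare_slopes(fit_f, fit_r)
    return AccelerationComparison(
        fit_full=fit_f, fit_reduced=fit_r, slope_t=t, slope_p=p,
        covariate=covariate_name, reference_level=ref,
    )


# ---------------------------------------------------------------------------
# Cross-platform offset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformOffset:
    """Age-adjusted mean DNAm-age difference between two platforms."""

    offset: float
    ci: tuple[float, float]
    se: float
    p: float
    n: int
    reference_platform: str
    other_platform: str

    def to_dict(self) -> dict:
        return {
            "offset": self.offset,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "se": self.se,
            "p": self.p,
            "n": self.n,
            "reference_platform": self.reference_platform,
            "other_platform": self.other_platform,
        }


def platform_offset_regression(
    dnam_ages: pd.Series,
    platform_labels: pd.Series,
    chronological_ages: pd.Series,
    reference_platform: str,
) -> PlatformOffset:
    """OLS of DNAm age on a platform indicator, controlling for age.

    The coefficient on the indicator is the adjusted mean difference of
    the non-reference platform relative to ``reference_platform``.
    Exactly two platform labels must be present among samples with known
    age.
    """
    df = pd.DataFrame({
        "dnam": dnam_ages,
        "platform": platform_labels,
        "age": chronological_ages,
    }).dropna()
    platforms = sorted(df["platform"].unique().tolist())
    if len(platforms) != 2:
        raise ValueError(f"need exactly two platforms, got {platforms}")
    if reference_platform not in platforms:
        raise ValueError(
            f"reference platform {reference_platform!r} not among {platforms}"
        )
    other = [p for p in platforms if p != reference_platform][0]
    indicator = (df["platform"] == other).astype(float)
    X = sm.add_constant(np.column_stack([indicator.to_numpy(),
                                         df["age"].to_numpy()]))
    res = sm.OLS(df["dnam"].to_numpy(), X).fit()
    ci = res.conf_int(alpha=0.05)
    return PlatformOffset(
        offset=float(res.params[1]),
        ci=(float(ci[1, 0]), float(ci[1, 1])),
        se=float(res.bse[1]),
        p=float(res.pvalues[1]),
        n=int(res.nobs),
        reference_platform=reference_platform,
        other_platform=other,
    )
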
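"""Two-state Approved -> Published analysis: Kaplan-Meier, median CI, Cox.

The simplified analysis collapses the four-state graph to a single
transition and treats time from approval to first full publication as a
standard right-censored survival outcome on the yearly time scale.  It
provides the Kaplan-Meier complement CDF of time to publication with
Greenwood pointwise variance, a Brookmeyer-Crowley confidence interval for
the median (inverting the test ``(S(t) - 1/2)^2 / Var S(t) <= chi^2_1``),
Cox proportional-hazards regression with the Efron tie correction (yearly
data produce many ties), and the variance-inflation-factor multicollinearity
check computed from the correlation structure of the coefficient covariance
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

from .records import COVARIATE_NAMES, StudyRecord, ValidationError, design_matrix

__all__ = [
    "SurvivalSample",
    "KMEstimate",
    "MedianCI",
    "CoxResult",
    "to_survival_sample",
    "km_fit",
    "median_ci_brookmeyer_crowley",
    "cox_fit",
    "variance_inflation_factors",
    "conditional_published_median",
    "km_curve_frame",
    "plot_publication_cdf",
]

_Z975 = scipy.stats.norm.ppf(0.975)

#: A survival sample is a plain DataFrame with columns ``study_id``,
#: ``time``, ``event`` and the encoded covariates of COVARIATE_NAMES.
SurvivalSample = pd.DataFrame

#: Duration assigned when publication (or censoring) falls in the approval
#: year itself: the event happened within the first year, so the exact
#: duration is in (0, 1); mid-year keeps it strictly positive.
_ZERO_DURATION = 0.5


def to_survival_sample(records: list[StudyRecord]) -> pd.DataFrame:
    """Per-study (time, event) rows with encoded covariates.

    ``time`` is years from approval to publication (event = 1) or to end of
    follow-up (event = 0).  Requires imputed sample sizes.
    """
    times, events, ids = [], [], []
    for r in records:
        if r.publication_year is not None:
            if r.publication_year > r.followup_end_year:
                raise ValidationError(
                    f"{r.study_id}: publication year outside follow-up window"
                )
            t = float(r.publication_year - r.approval_year)
            e = 1
        else:
            t = float(r.followup_end_year - r.approval_year)
            e = 0
        times.append(t if t > 0 else _ZERO_DURATION)
        events.append(e)
        ids.append(r.study_id)
    df = design_matrix(records)
    df.insert(0, "event", events)
    df.insert(0, "time", times)
    df.insert(0, "study_id", ids)
    return df


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate at the observed event times.

    ``variance`` is the Greenwood pointwise variance of S(t).
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(sample: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier fit of time to publication.

    Ties at yearly times reduce the risk set simultaneously.  With zero
    events the estimate is flat 1 (with a warning).
    """
    T = np.asarray(sample["time"], dtype=float)
    E = np.asarray(sample["event"], dtype=int)
    if E.sum() == 0:
        warnings.warn("no events: Kaplan-Meier estimate is constant 1")
        return KMEstimate(
            times=np.array([]),
            survival=np.array([]),
            variance=np.array([]),
            n_risk=np.array([]),
            n_event=np.array([]),
            n_total=len(T),
        )
    kmf = KaplanMeierFitter().fit(T, E)
    table = kmf.event_table
    obs = table[table["observed"] > 0]
    times = obs.index.to_numpy(dtype=float)
    d = obs["observed"].to_numpy(dtype=float)
    n = obs["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # cross-check against the library curve
    lib = kmf.survival_function_at_times(times).to_numpy()
    if not np.allclose(surv, lib, atol=1e-10):  # pragma: no cover
        raise AssertionError("product-limit recomputation disagrees with lifelines")
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
    var = np.where(surv > 0, surv**2 * greenwood, 0.0)
    return KMEstimate(
        times=times,
        survival=surv,
        variance=var,
        n_risk=n,
        n_event=d,
        n_total=len(T),
    )


@dataclass(frozen=True)
class MedianCI:
    median: float  # nan when the curve never reaches 1/2
    lower: float
    upper: float  # +inf when the acceptance region includes the last event time
    level: float


def median_ci_brookmeyer_crowley(
    km: KMEstimate, level: float = 0.95, transform: str = "linear"
) -> MedianCI:
    """Median time to publication with a test-inversion confidence interval.

    The CI is the set of event times where the standardized distance of
    S(t) from 1/2 does not exceed the chi-square critical value; it is
    reported as an interval, unbounded above when the acceptance region
    extends to the largest event time.  ``transform`` selects the scale of
    the test statistic: ``"linear"`` (the original construction, Greenwood
    variance on the survival scale) or ``"loglog"``.
    """
    if transform not in ("linear", "loglog"):
        raise ValueError("transform must be 'linear' or 'loglog'")
    if len(km.times) == 0:
        return MedianCI(np.nan, np.nan, np.inf, level)
    S, V = km.survival, km.variance
    crit = scipy.stats.chi2.ppf(level, df=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "linear":
            stat = (S - 0.5) ** 2 / V
        else:
            ok = (S > 0) & (S < 1) & (V > 0)
            stat = np.full_like(S, np.inf)
            num = (np.log(-np.log(S[ok])) - np.log(-np.log(0.5))) ** 2
            stat[ok] = num / (V[ok] / (S[ok] * np.log(S[ok])) ** 2)
    stat = np.where(np.isfinite(stat), stat, np.inf)
    accepted = stat <= crit

    below = np.nonzero(S <= 0.5)[0]
    median = float(km.times[below[0]]) if len(below) else np.nan

    acc_times = km.times[accepted]
    if len(acc_times) == 0:
        # degenerate: the curve jumps straight past 1/2 with no variance
        return MedianCI(median, median, median if np.isfinite(median) else np.inf, level)
    lower = float(acc_times[0])
    if accepted[-1]:
        upper = np.inf
    else:
        upper = float(acc_times[-1])
    if np.isfinite(median):
        lower = min(lower, median)
        upper = max(upper, median) if np.isfinite(upper) else upper
    return MedianCI(median, lower, upper, level)


def conditional_published_median(sample: pd.DataFrame) -> float:
    """Descriptive median time among studies actually published.

    Biased as an estimator of time to publication (it conditions on the
    future success of the study); reported only as a labelled description.
    """
    pub = sample.loc[sample["event"] == 1, "time"]
    return float(np.median(pub)) if len(pub) else np.nan


@dataclass(frozen=True)
class CoxResult:
    params: pd.Series
    cov: pd.DataFrame
    hr_table: pd.DataFrame
    loglik: float
    dropped: tuple[str, ...]
    ties: str


def cox_fit(
    sample: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATE_NAMES,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards regression of time to publication.

    All covariates enter simultaneously.  Zero-variance columns (rank
    deficiency) are dropped with a warning and reported in ``dropped``.
    """
    if sample["event"].sum() == 0:
        raise ValidationError("Cox regression requires at least one event")
    cols = list(covariates)
    X = sample[cols].to_numpy(dtype=float)
    keep, dropped = [], []
    for j, name in enumerate(cols):
        if np.ptp(X[:, j]) > 0:
            keep.append(name)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping rank-deficient covariate(s): {', '.join(dropped)}")
    if not keep:
        raise ValidationError("no estimable covariates after rank screening")
    model = PHReg(
        sample["time"].to_numpy(dtype=float),
        sample[keep].to_numpy(dtype=float),
        status=sample["event"].to_numpy(dtype=int),
        ties=ties,
    )
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    params = pd.Series(res.params, index=keep)
    cov = pd.DataFrame(res.cov_params(), index=keep, columns=keep)
    se = np.sqrt(np.diag(cov))
    hr = pd.DataFrame(
        {
            "covariate": keep,
            "log_hr": params.to_numpy(),
            "se": se,
            "hr": np.exp(params.to_numpy()),
            "ci_lower": np.exp(params.to_numpy() - _Z975 * se),
            "ci_upper": np.exp(params.to_numpy() + _Z975 * se),
        }
    )
    return CoxResult(
        params=params,
        cov=cov,
        hr_table=hr,
        loglik=float(model.loglike(res.params)),
        dropped=tuple(dropped),
        ties=ties,
    )


def variance_inflation_factors(cov: pd.DataFrame | np.ndarray) -> pd.Series:
    """VIF per coefficient from the coefficient covariance matrix.

    Computed as the diagonal of the inverse of the correlation matrix of
    the estimates; values near 1 indicate no variance inflation from
    correlation with the other coefficients.
    """
    if isinstance(cov, pd.DataFrame):
        names = list(cov.columns)
        C = cov.to_numpy(dtype=float)
    else:
        C = np.asarray(cov, dtype=float)
        names = list(range(C.shape[0]))
    sd = np.sqrt(np.diag(C))
    if np.any(sd <= 0):
        raise ValueError("covariance matrix has non-positive diagonal entries")
    corr = C / np.outer(sd, sd)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    return pd.Series(np.diag(inv), index=names, name="vif")


# ---------------------------------------------------------------------------
# Export / plotting

def km_curve_frame(km: KMEstimate) -> pd.DataFrame:
    """KM curve as a tidy frame (time, survival, SE, risk set, events)."""
    return pd.DataFrame(
        {
            "time": km.times,
            "survival": km.survival,
            "se": np.sqrt(km.variance),
            "n_risk": km.n_risk,
            "n_event": km.n_event,
        }
    )


def plot_publication_cdf(km: KMEstimate, path) -> None:
    """Complement-of-KM cumulative publication curve with 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = np.concatenate([[0.0], km.times])
    cdf = np.concatenate([[0.0], 1.0 - km.survival])
    se = np.concatenate([[0.0], np.sqrt(km.variance)])
    ax.step(t, cdf, where="post", color="C0")
    ax.fill_between(
        t,
        np.clip(cdf - _Z975 * se, 0, 1),
        np.clip(cdf + _Z975 * se, 0, 1),
        step="post",
        alpha=0.25,
        color="C0",
        linewidth=0,
    )
    ax.set_xlabel("Years since approval")
    ax.set_ylabel("Cumulative probability of publication")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
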
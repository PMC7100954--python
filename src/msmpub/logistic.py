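"""Timing-free sensitivity analysis: per-transition logistic regressions.

Because the year of completion or discontinuation is missing for most
studies, the event-history results are cross-checked by logistic
regressions that ignore time altogether: the outcome is simply whether a
transition was achieved during follow-up.  Risk sets follow the state
graph — every analysed study is at risk of completion and of
discontinuation; only completed studies are at risk of publication after
completion; only discontinued studies of publication after
discontinuation.  Studies with ongoing or unclear status demonstrably did
not reach Completed or Discontinued during follow-up and therefore count
as non-events for the two initial transitions.

With extended follow-up the odds ratio is a biased stand-in for the hazard
ratio (it drifts away from 1 as events accumulate), which is why these
fits are a sensitivity check rather than the primary analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .msm import TRANSITION_LABELS
from .records import COVARIATE_NAMES, Status, StudyRecord, design_matrix

__all__ = ["LogisticResult", "transition_outcome_table", "logistic_fit"]

_Z975 = scipy.stats.norm.ppf(0.975)


def transition_outcome_table(records: list[StudyRecord]) -> dict[str, pd.DataFrame]:
    """Binary outcome + covariate table per transition.

    Keys follow :data:`msmpub.msm.TRANSITION_LABELS`.  Requires imputed
    sample sizes.
    """
    X = design_matrix(records)
    status = pd.Series([r.status for r in records])
    published = pd.Series([r.published for r in records])

    def table(mask: pd.Series, outcome: pd.Series) -> pd.DataFrame:
        df = X[mask.to_numpy()].reset_index(drop=True).copy()
        df.insert(0, "outcome", outcome[mask.to_numpy()].astype(int).to_numpy())
        return df

    everyone = pd.Series([True] * len(records))
    return {
        TRANSITION_LABELS[0]: table(everyone, status == Status.COMPLETED),
        TRANSITION_LABELS[1]: table(everyone, status == Status.DISCONTINUED),
        TRANSITION_LABELS[2]: table(status == Status.COMPLETED, published),
        TRANSITION_LABELS[3]: table(status == Status.DISCONTINUED, published),
    }


@dataclass(frozen=True)
class LogisticResult:
    or_table: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    flagged: tuple[str, ...]

    def format(self, title: str = "") -> str:
        lines = [title] if title else []
        lines.append(f"(n = {self.n}, events = {self.n_events})")
        for _, row in self.or_table.iterrows():
            if row.separation:
                lines.append(f"  {row.covariate:<28s} --")
            else:
                lines.append(
                    f"  {row.covariate:<28s} {row.odds_ratio:.3f}"
                    f" [{row.ci_lower:.3f}, {row.ci_upper:.3f}]"
                )
        return "\n".join(lines) + "\n"


def _screen_separation(df: pd.DataFrame, covariates) -> list[str]:
    """Covariates that perfectly predict the outcome (or are constant)."""
    y = df["outcome"]
    flagged = []
    for name in covariates:
        x = df[name]
        if x.nunique() <= 1:
            flagged.append(name)
            continue
        if set(np.unique(x)) <= {0.0, 1.0}:
            tab = pd.crosstab(x, y)
            if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
                flagged.append(name)
    return flagged


def logistic_fit(
    outcome_table: pd.DataFrame, covariates: tuple[str, ...] = COVARIATE_NAMES
) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald CIs.

    Same covariate set as the survival models, entered simultaneously.
    Covariate levels causing separation (a zero cell against the outcome)
    are detected, excluded from the fit and reported as NA — separation is
    flagged, not corrected.
    """
    y = outcome_table["outcome"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    cols = list(covariates)
    flagged = _screen_separation(outcome_table, cols)
    keep = [c for c in cols if c not in flagged]
    if flagged:
        warnings.warn(f"separation or degeneracy flagged for: {', '.join(flagged)}")
    n_minority = int(min(y.sum(), len(y) - y.sum()))
    fit = None
    if keep and n_minority > len(keep):
        X = sm.add_constant(outcome_table[keep].to_numpy(dtype=float))
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception as exc:  # quasi-separation the screen cannot see
            warnings.warn(f"logistic fit degenerate ({exc}); reporting NA")
    elif not keep:
        warnings.warn("every covariate is degenerate; odds ratios reported as NA")
    else:
        warnings.warn(
            "fewer events than parameters; logistic odds ratios reported as NA"
        )
    if fit is None:
        flagged = cols
        keep, params, se = [], np.array([]), np.array([])
        loglik = np.nan
    else:
        params = fit.params[1:]
        se = fit.bse[1:]
        loglik = float(fit.llf)
        # a diverging coefficient that escaped the screen is still flagged
        diverged = [
            keep[j] for j in range(len(keep)) if abs(params[j]) > 15 or se[j] > 50
        ]
        if diverged:
            warnings.warn(f"diverging coefficient(s) flagged for: {', '.join(diverged)}")
            flagged = flagged + diverged

    rows = []
    for name in cols:
        if name in flagged:
            rows.append(
                {
                    "covariate": name,
                    "log_or": np.nan,
                    "se": np.nan,
                    "odds_ratio": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "separation": True,
                }
            )
        else:
            j = keep.index(name)
            rows.append(
                {
                    "covariate": name,
                    "log_or": params[j],
                    "se": se[j],
                    "odds_ratio": np.exp(params[j]),
                    "ci_lower": np.exp(params[j] - _Z975 * se[j]),
                    "ci_upper": np.exp(params[j] + _Z975 * se[j]),
                    "separation": False,
                }
            )
    return LogisticResult(
        or_table=pd.DataFrame(rows),
        loglik=loglik,
        n=len(y),
        n_events=int(y.sum()),
        flagged=tuple(flagged),
    )
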
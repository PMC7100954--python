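"""Four-state progressive multi-state model with piecewise-constant intensities.

The model describes a study's progression Approved -> Completed /
Discontinued -> Published on a single clock-forward time scale (years since
approval).  Each of the four allowed transitions ``h`` has intensity

    lambda_h(t | x) = lambda0_h(t) * exp(x' beta_h)

where the baseline ``lambda0_h`` is a right-continuous step function on a
grid of cutpoints shared across transitions and ``beta_h`` are
per-transition log hazard ratios.  The full likelihood of an
interval-censored cohort is available in closed form (see
:mod:`msmpub._likelihood`); this module adds the public model type,
maximum-likelihood fitting with Wald confidence intervals from the observed
information, identifiability screening, transition-probability matrices and
hazard-ratio tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.linalg
import scipy.optimize
import scipy.stats

from ._likelihood import LikelihoodBundle, _Grid
from .records import COVARIATE_NAMES, CovariateVector, ObservationCase, PathType

__all__ = [
    "TRANSITION_LABELS",
    "DEFAULT_CUTPOINTS",
    "PiecewiseIntensityModel",
    "ModelFit",
    "FitConfig",
    "transition_intensity",
    "cumulative_intensity",
    "case_loglikelihood",
    "total_loglikelihood",
    "quadrature_oracle_loglikelihood",
    "detect_nonidentifiable",
    "fit_msm",
    "transition_probability_matrix",
    "hazard_ratio_table",
    "format_hazard_ratio_table",
]

TRANSITION_LABELS = (
    "Approved -> Completed",
    "Approved -> Discontinued",
    "Completed -> Published",
    "Discontinued -> Published",
)

#: Default baseline cutpoints (years since approval).  Motivated by the
#: publication process being most active roughly four to seven years after
#: approval and largely exhausted beyond nine.
DEFAULT_CUTPOINTS = (2.0, 4.0, 7.0, 9.0)

_Z975 = scipy.stats.norm.ppf(0.975)


def _as_x(x) -> np.ndarray:
    if x is None:
        return np.zeros(8)
    if isinstance(x, CovariateVector):
        return x.as_array()
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PiecewiseIntensityModel:
    """Cutpoints, per-interval log baseline rates and covariate log-HRs.

    ``log_baseline`` has shape ``(4, K)`` with ``K = len(cutpoints) + 1``;
    ``beta`` has shape ``(4, P)``.  Transition order: A->C, A->D, C->P,
    D->P.
    """

    cutpoints: tuple[float, ...]
    log_baseline: np.ndarray
    beta: np.ndarray
    covariate_names: tuple[str, ...] = COVARIATE_NAMES

    def __post_init__(self):
        object.__setattr__(self, "cutpoints", tuple(float(c) for c in self.cutpoints))
        lb = np.atleast_2d(np.asarray(self.log_baseline, dtype=float))
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim == 1:
            beta = beta.reshape(4, -1)
        object.__setattr__(self, "log_baseline", lb)
        object.__setattr__(self, "beta", beta)
        grid = _Grid(self.cutpoints)  # validates monotonicity
        if lb.shape != (4, grid.n_intervals):
            raise ValueError(
                f"log_baseline must have shape (4, {grid.n_intervals}), got {lb.shape}"
            )
        if beta.shape[0] != 4:
            raise ValueError("beta must have one row per transition")
        names = tuple(self.covariate_names)
        if len(names) != beta.shape[1]:
            if names == COVARIATE_NAMES:  # default: truncate to the beta width
                names = names[: beta.shape[1]]
            else:
                raise ValueError("covariate_names must match beta columns")
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "_grid", grid)

    @property
    def grid(self) -> _Grid:
        return self._grid

    @property
    def n_intervals(self) -> int:
        return self._grid.n_intervals

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[1]

    def linear_predictor(self, transition: int, x) -> float:
        xv = _as_x(x)[: self.n_covariates]
        return float(xv @ self.beta[transition])

    def intensity(self, transition: int, t: float, x=None) -> float:
        if not 0 <= transition < 4:
            raise ValueError(f"unknown transition index {transition}")
        if t < 0:
            raise ValueError("time must be non-negative")
        k = self._grid.interval_index(t)
        return float(
            np.exp(self.log_baseline[transition, k] + self.linear_predictor(transition, x))
        )

    def cumulative(self, transition: int, t0: float, t1: float, x=None) -> float:
        if not 0 <= transition < 4:
            raise ValueError(f"unknown transition index {transition}")
        if t0 < 0:
            raise ValueError("times must be non-negative")
        if t1 < t0:
            raise ValueError(f"t1={t1} precedes t0={t0}")
        expo = self._grid.exposure(t0, t1)
        rates = np.exp(self.log_baseline[transition])
        return float((expo @ rates) * np.exp(self.linear_predictor(transition, x)))


def transition_intensity(model: PiecewiseIntensityModel, transition: int, t: float, x=None):
    """lambda_h(t | x): instantaneous transition rate (right-continuous in t)."""
    return model.intensity(transition, t, x)


def cumulative_intensity(model: PiecewiseIntensityModel, transition, t0, t1, x=None):
    """Exact integral of the step-function intensity over [t0, t1]."""
    return model.cumulative(transition, t0, t1, x)


# ---------------------------------------------------------------------------
# Likelihood

def case_loglikelihood(case: ObservationCase, model: PiecewiseIntensityModel) -> float:
    """Exact log-likelihood contribution of a single observation case."""
    bundle = LikelihoodBundle([case], model.cutpoints)
    return float(bundle.per_case_loglik(model.log_baseline, model.beta)[0])


def total_loglikelihood(
    cases: Sequence[ObservationCase], model: PiecewiseIntensityModel
) -> float:
    """Sum of per-study contributions (independence across studies)."""
    bundle = LikelihoodBundle(cases, model.cutpoints)
    return bundle.loglik(model.log_baseline, model.beta)


def quadrature_oracle_loglikelihood(
    case: ObservationCase, model: PiecewiseIntensityModel
) -> float:
    """Same contract as :func:`case_loglikelihood`, by adaptive quadrature.

    Evaluates the defining integral numerically from pointwise intensity
    calls; intended as an independent cross-check of the closed-form path,
    not for production use.
    """
    x = case.covariates
    if case.path is PathType.CENSORED_IN_APPROVED:
        c = case.absorbing_upper
        return -(model.cumulative(0, 0.0, c, x) + model.cumulative(1, 0.0, c, x))

    if case.path is PathType.UNPUBLISHED_UNKNOWN:
        # P(no publication by c): still approved, or completed/discontinued
        # without a publication
        c = case.absorbing_upper
        p_approved = np.exp(
            -(model.cumulative(0, 0.0, c, x) + model.cumulative(1, 0.0, c, x))
        )
        total = p_approved
        if c > 0:
            for m in (0, 1):
                sub = ObservationCase(
                    path=(
                        PathType.COMPLETED_CENSORED
                        if m == 0
                        else PathType.DISCONTINUED_CENSORED
                    ),
                    covariates=x,
                    intermediate_lower=0.0,
                    intermediate_upper=c,
                    absorbing_lower=c,
                    absorbing_upper=c,
                    study_id=case.study_id,
                )
                total += np.exp(quadrature_oracle_loglikelihood(sub, model))
        return float(np.log(total))

    m = case.initial_transition
    q = m + 2
    a, b = case.intermediate_lower, case.intermediate_upper
    published = case.path in (PathType.COMPLETED_PUBLISHED, PathType.DISCONTINUED_PUBLISHED)

    def survive_approved(s):
        return np.exp(-model.cumulative(0, 0.0, s, x) - model.cumulative(1, 0.0, s, x))

    if published:
        if case.absorbing_exact:
            v = case.absorbing_lower

            def tail(s):
                return model.intensity(q, v, x) * np.exp(-model.cumulative(q, s, v, x))

        else:
            p = case.absorbing_lower

            def tail(s):
                hi = np.exp(-model.cumulative(q, s, max(s, p), x))
                lo = np.exp(-model.cumulative(q, s, p + 1.0, x))
                return hi - lo

    else:
        c = case.absorbing_upper

        def tail(s):
            return np.exp(-model.cumulative(q, s, max(s, c), x))

    if case.intermediate_exact:
        t = a
        return float(
            np.log(model.intensity(m, t, x)) + np.log(survive_approved(t)) + np.log(tail(t))
        )

    def integrand(s):
        return survive_approved(s) * model.intensity(m, s, x) * tail(s)

    points = [c for c in model.cutpoints if a < c < b]
    if published and not case.absorbing_exact and a < case.absorbing_lower < b:
        points.append(case.absorbing_lower)
    if not published and a < case.absorbing_upper < b:
        points.append(case.absorbing_upper)
    val, err = scipy.integrate.quad(
        integrand, a, b, points=sorted(points) or None, limit=400, epsabs=0, epsrel=1e-11
    )
    if not np.isfinite(val) or (val > 0 and err > 1e-6 * val):
        raise RuntimeError(f"quadrature did not converge (value {val}, error {err})")
    with np.errstate(divide="ignore"):
        return float(np.log(val))


# ---------------------------------------------------------------------------
# Identifiability screening

def _event_transitions(case: ObservationCase) -> list[int]:
    out = []
    m = case.initial_transition
    if m is not None:
        out.append(m)
    if case.path is PathType.COMPLETED_PUBLISHED:
        out.append(2)
    elif case.path is PathType.DISCONTINUED_PUBLISHED:
        out.append(3)
    return out


def event_counts(cases: Sequence[ObservationCase]) -> np.ndarray:
    """Observed number of studies making each of the four transitions."""
    counts = np.zeros(4, dtype=int)
    for case in cases:
        for t in _event_transitions(case):
            counts[t] += 1
    return counts


def detect_nonidentifiable(
    cases: Sequence[ObservationCase],
    covariate_names: Sequence[str] = COVARIATE_NAMES,
) -> set[tuple[int, str]]:
    """Flag (transition, covariate-level) pairs with no information.

    A dummy covariate level is flagged for a transition when no observed
    event on that transition carries the level (or when every one does, the
    symmetric degeneracy): the corresponding log-HR would diverge and is
    frozen out of the optimization, mirroring the "--" cells of sparse
    transitions.
    """
    names = list(covariate_names)
    idx = [COVARIATE_NAMES.index(n) for n in names]
    X_events: dict[int, list[np.ndarray]] = {0: [], 1: [], 2: [], 3: []}
    for case in cases:
        row = case.covariates.as_array()[idx]
        for t in _event_transitions(case):
            X_events[t].append(row)
    flagged = set()
    for t in range(4):
        rows = X_events[t]
        if not rows:
            flagged.update((t, n) for n in names)
            continue
        arr = np.array(rows)
        for j, name in enumerate(names):
            col = arr[:, j]
            if not set(np.unique(np.concatenate([[0.0, 1.0], col]))) <= {0.0, 1.0}:
                continue  # continuous covariate: never frozen by this rule
            s = col.sum()
            if s == 0 or s == len(col):
                flagged.add((t, name))
    return flagged


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FitConfig:
    """Optimizer and standard-error settings for :func:`fit_msm`."""

    max_iter: int = 2000
    ftol: float = 1e-10
    gtol: float = 1e-6
    bound: float = 20.0           # |log rate| and |log HR| are kept below this
    newton_polish: bool = True
    newton_max_iter: int = 30
    newton_gtol: float = 1e-8
    hessian_step: float = 1e-5    # relative central-difference step
    compute_covariance: bool = True


@dataclass
class ModelFit:
    """Maximum-likelihood fit: estimates, covariance and HR table inputs."""

    model: PiecewiseIntensityModel
    loglik: float
    converged: bool
    n_iter: int
    message: str
    covariate_names: tuple[str, ...]
    se_log_baseline: np.ndarray
    se_beta: np.ndarray
    nonidentifiable: set = field(default_factory=set)
    frozen_baseline: set = field(default_factory=set)
    covariance: np.ndarray | None = None
    free_index: list = field(default_factory=list)
    event_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))
    n_cases: int = 0
    grad_norm: float = np.nan

    def hazard_ratios(self) -> pd.DataFrame:
        return hazard_ratio_table(self)

    def to_dict(self) -> dict:
        return {
            "cutpoints": list(self.model.cutpoints),
            "covariate_names": list(self.covariate_names),
            "log_baseline": self.model.log_baseline.tolist(),
            "beta": self.model.beta.tolist(),
            "se_log_baseline": self.se_log_baseline.tolist(),
            "se_beta": self.se_beta.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_norm": float(self.grad_norm),
            "message": self.message,
            "nonidentifiable": sorted(
                [TRANSITION_LABELS[t], name] for t, name in self.nonidentifiable
            ),
            "event_counts": self.event_counts.tolist(),
            "n_cases": self.n_cases,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "free_index": [list(fi) for fi in self.free_index],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _crude_initial_rates(cases, grid, counts_floor=0.5):
    """Event/exposure rates per transition and interval, intervals at midpoints."""
    K = grid.n_intervals
    events = np.zeros((4, K))
    exposure = np.zeros((4, K))
    top = grid.edges[-2] + 5.0  # midpoint proxy for the open last interval
    for case in cases:
        if case.path in (PathType.CENSORED_IN_APPROVED, PathType.UNPUBLISHED_UNKNOWN):
            c = case.absorbing_upper
            exposure[0] += grid.exposure(0.0, c)
            exposure[1] += grid.exposure(0.0, c)
            continue
        m = case.initial_transition
        q = m + 2
        a, b = case.intermediate_lower, case.intermediate_upper
        tm = a if case.intermediate_exact else 0.5 * (a + min(b, top))
        exposure[0] += grid.exposure(0.0, tm)
        exposure[1] += grid.exposure(0.0, tm)
        events[m, grid.interval_index(tm)] += 1
        if case.path in (PathType.COMPLETED_PUBLISHED, PathType.DISCONTINUED_PUBLISHED):
            tp = (
                case.absorbing_lower
                if case.absorbing_exact
                else case.absorbing_lower + 0.5
            )
            tp = max(tp, tm)
            events[q, grid.interval_index(tp)] += 1
            exposure[q] += grid.exposure(tm, tp)
        else:
            exposure[q] += grid.exposure(tm, max(case.absorbing_upper, tm))
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = (events + counts_floor) / np.where(exposure > 0, exposure, np.nan)
    rate = np.where(np.isfinite(rate), rate, 1e-3)
    return np.clip(np.log(rate), -8.0, 3.0), exposure


def fit_msm(
    cases: Sequence[ObservationCase],
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    covariates: Sequence[str] | None = COVARIATE_NAMES,
    config: FitConfig | None = None,
) -> ModelFit:
    """Maximize the full interval-censored likelihood.

    Parameters enter on the log scale (log baseline rates, log hazard
    ratios), so positivity is automatic and the problem is smooth and
    unconstrained; a quasi-Newton pass (L-BFGS-B with the analytic score)
    is followed by a safeguarded Newton polish on the same score.  Standard
    errors come from the inverse of the central-difference observed
    information at the optimum.

    ``covariates`` selects which encoded covariates enter all four
    transitions (empty sequence fits baseline-only intensities).
    """
    cfg = config or FitConfig()
    cov_names = tuple(covariates) if covariates is not None else ()
    cov_idx = [COVARIATE_NAMES.index(n) for n in cov_names]
    P = len(cov_idx)
    bundle = LikelihoodBundle(cases, cutpoints, covariate_index=cov_idx)
    grid = bundle.grid
    K = grid.n_intervals

    flagged = detect_nonidentifiable(cases, cov_names) if P else set()
    lb0, exposure = _crude_initial_rates(cases, grid)
    frozen_baseline = {
        (t, k) for t in range(4) for k in range(K) if exposure[t, k] <= 1e-8
    }

    free_index: list[tuple] = []
    for t in range(4):
        for k in range(K):
            if (t, k) not in frozen_baseline:
                free_index.append(("lb", t, k))
    for t in range(4):
        for j, name in enumerate(cov_names):
            if (t, name) not in flagged:
                free_index.append(("beta", t, j))

    lb_full = lb0.copy()
    for t, k in frozen_baseline:
        lb_full[t, k] = -10.0
    beta_full = np.zeros((4, P))

    def unpack(theta):
        lb = lb_full.copy()
        beta = beta_full.copy()
        for val, (kind, t, j) in zip(theta, free_index):
            if kind == "lb":
                lb[t, j] = val
            else:
                beta[t, j] = val
        return lb, beta

    def objective(theta):
        lb, beta = unpack(theta)
        ll, g_lb, g_beta = bundle.loglik_and_grad(lb, beta)
        grad = np.empty(len(free_index))
        for i, (kind, t, j) in enumerate(free_index):
            grad[i] = g_lb[t, j] if kind == "lb" else g_beta[t, j]
        if not np.isfinite(ll) or not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(grad)
        return -ll, -grad

    theta0 = np.array(
        [lb_full[t, j] if kind == "lb" else 0.0 for kind, t, j in free_index]
    )

    def projected(theta, grad):
        # components pinned at the box bound with the gradient pointing
        # outward (e.g. a baseline rate running to zero) do not count
        # against convergence
        out = grad.copy()
        out[(theta >= cfg.bound - 1e-8) & (grad < 0)] = 0.0
        out[(theta <= -cfg.bound + 1e-8) & (grad > 0)] = 0.0
        return out
    n_iter = 0
    message = ""
    if len(free_index):
        res = scipy.optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-cfg.bound, cfg.bound)] * len(free_index),
            options={"maxiter": cfg.max_iter, "ftol": cfg.ftol, "gtol": cfg.gtol,
                     "maxcor": 25},
        )
        theta = res.x
        n_iter = int(res.nit)
        message = str(res.message)
        f_cur, g_cur = objective(theta)

        if cfg.newton_polish:
            for _ in range(cfg.newton_max_iter):
                g_proj = projected(theta, g_cur)
                if np.max(np.abs(g_proj)) < cfg.newton_gtol:
                    break
                # Newton step on the components not pinned at a bound; the
                # pinned ones would make the system artificially singular
                active = np.abs(g_proj) > 0
                if not np.any(active):
                    break
                H = _numeric_hessian(objective, theta, cfg.hessian_step)
                Ha = H[np.ix_(active, active)]
                try:
                    step_a = np.linalg.solve(Ha, -g_cur[active])
                except np.linalg.LinAlgError:
                    step_a, *_ = np.linalg.lstsq(Ha, -g_cur[active], rcond=None)
                step = np.zeros_like(theta)
                step[active] = step_a
                accepted = False
                scale = 1.0
                for _ in range(25):
                    cand = np.clip(theta + scale * step, -cfg.bound, cfg.bound)
                    f_new, g_new = objective(cand)
                    if f_new <= f_cur + 1e-12 * max(1.0, abs(f_cur)):
                        theta, f_cur, g_cur = cand, f_new, g_new
                        accepted = True
                        break
                    scale *= 0.5
                n_iter += 1
                if not accepted:
                    break
    else:
        theta = theta0
        f_cur, g_cur = objective(theta)

    lb_hat, beta_hat = unpack(theta)
    ll_hat = -objective(theta)[0]
    grad_norm = (
        float(np.max(np.abs(projected(theta, objective(theta)[1]))))
        if len(free_index)
        else 0.0
    )
    converged = grad_norm <= max(cfg.gtol, 1e-4 * max(1.0, abs(ll_hat) / max(len(cases), 1)))

    covariance = None
    se_lb = np.full((4, K), np.nan)
    se_beta = np.full((4, P), np.nan)
    if cfg.compute_covariance and len(free_index):
        H = _numeric_hessian(objective, theta, cfg.hessian_step)
        H = 0.5 * (H + H.T)
        try:
            covariance = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; covariance reported as NA")
            covariance = None
        if covariance is not None:
            diag = np.diag(covariance).copy()
            if np.any(diag <= 0):
                warnings.warn(
                    "observed information not positive definite at the optimum; "
                    "affected standard errors reported as NA"
                )
                diag[diag <= 0] = np.nan
            ses = np.sqrt(diag)
            for se, (kind, t, j) in zip(ses, free_index):
                if kind == "lb":
                    se_lb[t, j] = se
                else:
                    se_beta[t, j] = se

    model = PiecewiseIntensityModel(
        cutpoints=tuple(cutpoints),
        log_baseline=lb_hat,
        beta=beta_hat if P else np.zeros((4, 0)),
        covariate_names=cov_names,
    )
    return ModelFit(
        model=model,
        loglik=float(ll_hat),
        converged=bool(converged),
        n_iter=n_iter,
        message=message,
        covariate_names=cov_names,
        se_log_baseline=se_lb,
        se_beta=se_beta,
        nonidentifiable=flagged,
        frozen_baseline=frozen_baseline,
        covariance=covariance,
        free_index=free_index,
        event_counts=event_counts(cases),
        n_cases=len(cases),
        grad_norm=grad_norm,
    )


def _numeric_hessian(objective, theta, rel_step):
    """Central differences of the analytic gradient."""
    n = len(theta)
    H = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(theta[j]))
        up = theta.copy()
        up[j] += h
        dn = theta.copy()
        dn[j] -= h
        H[:, j] = (objective(up)[1] - objective(dn)[1]) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Derived outputs

def transition_probability_matrix(
    model: PiecewiseIntensityModel, x, s: float, t: float
) -> np.ndarray:
    """P(s, t | x): 4x4 matrix of state-transition probabilities.

    Product over constant-intensity pieces of exact matrix exponentials of
    the generator; rows sum to one and state 4 (Published) is absorbing.
    """
    if t < s:
        raise ValueError(f"t={t} precedes s={s}")
    if s < 0:
        raise ValueError("times must be non-negative")
    breaks = [s] + [c for c in model.cutpoints if s < c < t] + [t]
    P = np.eye(4)
    for u, v in zip(breaks[:-1], breaks[1:]):
        rates = [model.intensity(h, u, x) for h in range(4)]
        Q = np.array(
            [
                [-(rates[0] + rates[1]), rates[0], rates[1], 0.0],
                [0.0, -rates[2], 0.0, rates[2]],
                [0.0, 0.0, -rates[3], rates[3]],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        P = P @ scipy.linalg.expm(Q * (v - u))
    P = np.clip(P, 0.0, 1.0)
    return P / P.sum(axis=1, keepdims=True)


def hazard_ratio_table(fit: ModelFit) -> pd.DataFrame:
    """Per-transition hazard ratios with Wald 95% CIs.

    Frozen (non-identifiable) parameters are reported as NA.
    """
    rows = []
    for t in range(4):
        for j, name in enumerate(fit.covariate_names):
            flagged = (t, name) in fit.nonidentifiable
            b = fit.model.beta[t, j]
            se = fit.se_beta[t, j]
            if flagged:
                hr = lo = hi = np.nan
                se = np.nan
            else:
                hr = np.exp(b)
                lo = np.exp(b - _Z975 * se) if np.isfinite(se) else np.nan
                hi = np.exp(b + _Z975 * se) if np.isfinite(se) else np.nan
            rows.append(
                {
                    "transition": TRANSITION_LABELS[t],
                    "n_events": int(fit.event_counts[t]),
                    "covariate": name,
                    "log_hr": np.nan if flagged else b,
                    "se": se,
                    "hr": hr,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "nonidentifiable": flagged,
                }
            )
    return pd.DataFrame(rows)


_ROW_LABELS = {
    "log_sample_size": "Log sample size",
    "rct": "RCT vs. other",
    "funding_commercial": "Funding: Commercial vs. non-commercial",
    "funding_not_reported": "Funding: Unstated vs. non-commercial",
    "industry": "Industry: Involved vs. not involved",
    "primary_outcome": "Primary outcome: Yes vs. no",
    "collab_multi_national": "Collaboration: National multi-centre vs. single-centre",
    "collab_multi_international": "Collaboration: International multi-centre vs. single-centre",
}

_HEADER_LABELS = (
    "Approved -> Completed",
    "Approved -> Discontinued",
    "Completed -> Published",
    "Discontinued -> Published",
)


def format_hazard_ratio_table(fit: ModelFit) -> str:
    """Plain-text HR table, one block per transition with its event count."""
    table = hazard_ratio_table(fit)
    lines = []
    for t, header in enumerate(_HEADER_LABELS):
        sub = table[table.transition == TRANSITION_LABELS[t]]
        lines.append(f"{header} (n = {int(fit.event_counts[t])})")
        for _, row in sub.iterrows():
            label = _ROW_LABELS.get(row.covariate, row.covariate)
            if row.nonidentifiable or not np.isfinite(row.hr):
                lines.append(f"  {label:<58s} --")
            elif not (np.isfinite(row.ci_lower) and np.isfinite(row.ci_upper)):
                lines.append(f"  {label:<58s} {row.hr:.3f} [NA, NA]")
            else:
                lines.append(
                    f"  {label:<58s} {row.hr:.3f} [{row.ci_lower:.3f}, {row.ci_upper:.3f}]"
                )
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
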
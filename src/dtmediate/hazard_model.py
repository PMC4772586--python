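"""Maximum-likelihood estimation of the discrete-time logistic hazard model.

The hazard in period j for subject i is

    h_ij = expit(logit_ij),   logit_ij = beta_j + kappa_x' x_i + kappa_zj' z_ij

where ``beta_j`` is the baseline logit for period j (unstructured: one free
intercept per period; constant: a single intercept; piecewise: one intercept
per group of periods) and the covariate coefficients are either shared across
periods (the proportional hazard-odds model) or period-specific. Because the
person-period indicators are conditionally independent Bernoulli draws, the
model is fitted as a logistic regression on the expanded table; equality
constraints across periods are imposed exactly by sharing design-matrix
columns rather than by post-hoc restriction.

The default covariance estimator is the sandwich (robust) estimator clustered
by subject; the model-based observed-information covariance is available via
``vcov="model"``. Periods with zero events under a free baseline have their
intercepts fixed at a large negative logit (hazard effectively 0) instead of
diverging; this is reported in the fit and logged as a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .person_period import EVENT_IND_COL, ID_COL, PERIOD_COL, PersonPeriodTable

logger = logging.getLogger(__name__)

#: logit at which intercepts of event-free periods are pinned (hazard ~ 3e-7)
FIXED_EMPTY_LOGIT = -15.0

GRADIENT_TOL = 1e-8
MAX_ITER = 100


class ConvergenceError(RuntimeError):
    """Newton iteration failed (separation, divergence or iteration cap)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class HazardSpec:
    """Specification of the discrete-time hazard equation.

    ``free`` lists covariates whose coefficients are period-specific
    (used to relax, and thereby test, the proportionality constraint).
    Setting ``proportional=False`` frees every covariate.
    """

    covariates: tuple[str, ...] = ()
    time_varying: tuple[str, ...] = ()
    baseline: str = "unstructured"  # unstructured | constant | piecewise
    piecewise_groups: tuple[tuple[int, ...], ...] | None = None
    proportional: bool = True
    free: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline not in ("unstructured", "constant", "piecewise"):
            raise ValueError(f"unknown baseline type {self.baseline!r}")
        if self.baseline == "piecewise" and not self.piecewise_groups:
            raise ValueError("piecewise baseline requires piecewise_groups")

    def free_covariates(self) -> tuple[str, ...]:
        if not self.proportional:
            return self.covariates + self.time_varying
        return self.free


@dataclass(frozen=True)
class HazardModelFit:
    """Fitted discrete-time hazard model."""

    params: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_obs: int
    n_subjects: int
    n_events: int
    J_max: int
    spec: HazardSpec
    converged: bool
    n_iter: int
    max_grad: float
    fixed_intercepts: Mapping[int, float] = field(default_factory=dict)
    vcov_type: str = "robust"
    linpred_var: float = float("nan")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index
        )

    def baseline_logits(self) -> pd.Series:
        """Per-period baseline logits beta_j, resolving the baseline structure."""
        beta = pd.Series(np.nan, index=range(1, self.J_max + 1), name="beta")
        if self.spec.baseline == "constant":
            beta[:] = self.params["baseline"]
        elif self.spec.baseline == "unstructured":
            for j in beta.index:
                name = f"period_{j}"
                if name in self.params.index:
                    beta[j] = self.params[name]
        else:
            for g, group in enumerate(self.spec.piecewise_groups, start=1):
                name = f"periods_g{g}"
                if name in self.params.index:
                    beta[list(group)] = self.params[name]
        for j, val in self.fixed_intercepts.items():
            beta[j] = val
        return beta

    def thresholds(self) -> pd.Series:
        """Latent-response thresholds tau_j = -beta_j."""
        return -self.baseline_logits().rename("tau")

    def coefficient(self, name: str, period: int | None = None) -> float:
        """Coefficient for a covariate; ``period`` required if it is free."""
        if name in self.params.index:
            return float(self.params[name])
        if period is not None and f"{name}:{period}" in self.params.index:
            return float(self.params[f"{name}:{period}"])
        raise KeyError(f"no coefficient for covariate {name!r} (period={period})")

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.params / se
        p = chi2.sf(z**2, df=1)
        return pd.DataFrame(
            {"estimate": self.params, "se": se, "z": z, "p": p}
        ).rename_axis("parameter")


@dataclass(frozen=True)
class HazardCurve:
    """Per-period hazard and survival probabilities for one covariate profile."""

    hazard: pd.Series  # indexed by period 1..J
    survival: pd.Series

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hazard": self.hazard, "survival": self.survival}
        ).rename_axis("period")


def hazard_from_logit(logit_value: float | np.ndarray) -> float | np.ndarray:
    """Inverse-logit map from the linear predictor to a hazard probability."""
    arr = np.asarray(logit_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logit must be finite")
    out = expit(arr)
    return float(out) if np.isscalar(logit_value) or arr.ndim == 0 else out


def survival_from_hazard(h: Sequence[float]) -> np.ndarray:
    """S_j = prod_{k<=j} (1 - h_k)."""
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - h)


def _build_design(
    table: PersonPeriodTable, spec: HazardSpec
) -> tuple[np.ndarray, list[str], np.ndarray, dict[int, float]]:
    """Design matrix, column names, offset, and fixed (pinned) intercepts."""
    df = table.frame
    J = table.J_max
    period = df[PERIOD_COL].to_numpy()
    u = df[EVENT_IND_COL].to_numpy()
    events_by_period = {
        int(j): int(s)
        for j, s in df.groupby(PERIOD_COL)[EVENT_IND_COL].sum().items()
    }
    periods_present = sorted(events_by_period)

    cols: list[np.ndarray] = []
    names: list[str] = []
    offset = np.zeros(len(df))
    fixed: dict[int, float] = {}

    if spec.baseline == "constant":
        cols.append(np.ones(len(df)))
        names.append("baseline")
    elif spec.baseline == "unstructured":
        for j in periods_present:
            mask = period == j
            if events_by_period[j] == 0:
                offset[mask] += FIXED_EMPTY_LOGIT
                fixed[j] = FIXED_EMPTY_LOGIT
            else:
                cols.append(mask.astype(float))
                names.append(f"period_{j}")
        if fixed:
            logger.warning(
                "periods %s have no events; intercepts fixed at %.1f",
                sorted(fixed), FIXED_EMPTY_LOGIT,
            )
    else:  # piecewise
        groups = spec.piecewise_groups
        covered = sorted(j for g in groups for j in g)
        if covered != list(range(1, J + 1)):
            raise ValueError("piecewise groups must partition 1..J_max")
        for g, group in enumerate(groups, start=1):
            mask = np.isin(period, list(group))
            n_ev = sum(events_by_period.get(j, 0) for j in group)
            if not mask.any():
                continue
            if n_ev == 0:
                offset[mask] += FIXED_EMPTY_LOGIT
                for j in group:
                    fixed[j] = FIXED_EMPTY_LOGIT
                logger.warning(
                    "piecewise group %s has no events; intercept fixed", group
                )
            else:
                cols.append(mask.astype(float))
                names.append(f"periods_g{g}")

    free = set(spec.free_covariates())
    for name in spec.covariates + spec.time_varying:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not in person-period table")
        vals = df[name].to_numpy(dtype=float)
        if name in free:
            # a period-specific coefficient is identifiable only where the
            # period has events; elsewhere the hazard is pinned anyway
            for j in periods_present:
                if events_by_period[j] == 0:
                    continue
                cols.append(vals * (period == j))
                names.append(f"{name}:{j}")
        else:
            cols.append(vals)
            names.append(name)

    X = np.column_stack(cols)
    _check_rank(X, names)
    return X, names, offset, fixed


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    bad = d < 1e-10 * max(d.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.where(bad)[0]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """Newton-Raphson for the Bernoulli-logit likelihood.

    Returns (beta, observed-information Hessian, loglik, n_iter, max|grad|).
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll = _bernoulli_loglik(X @ beta + offset, y)
    H = np.empty((p, p))
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta + offset
        mu = expit(eta)
        grad = X.T @ (y - mu)
        max_grad = float(np.max(np.abs(grad)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        if max_grad < GRADIENT_TOL:
            return beta, H, ll, it, max_grad
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular Hessian at iteration {it} (possible separation)"
            ) from exc
        # step halving keeps the ascent monotone on flat stretches
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_loglik(X @ cand + offset, y)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {it} (max|grad|={max_grad:.3g})"
            )
        if np.max(np.abs(beta)) > 30.0:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 30); data are likely separated"
            )
    raise ConvergenceError(
        f"no convergence in {MAX_ITER} iterations (max|grad|={max_grad:.3g})"
    )


def _cluster_sandwich(
    X: np.ndarray,
    resid: np.ndarray,
    H_inv: np.ndarray,
    groups: np.ndarray,
) -> np.ndarray:
    scores = X * resid[:, None]
    g = pd.DataFrame(scores).groupby(groups, sort=False).sum().to_numpy()
    meat = g.T @ g
    return H_inv @ meat @ H_inv


def fit_dtsm(
    table: PersonPeriodTable, spec: HazardSpec, vcov: str = "robust"
) -> HazardModelFit:
    """Fit the discrete-time survival model by maximum likelihood.

    ``vcov="robust"`` (default) gives the sandwich estimator clustered by
    subject; ``vcov="model"`` the inverse observed information.
    """
    if vcov not in ("robust", "model"):
        raise ValueError(f"unknown vcov type {vcov!r}")
    df = table.frame
    y = df[EVENT_IND_COL].to_numpy(dtype=float)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError("degenerate table: need at least one event and one non-event")

    X, names, offset, fixed = _build_design(table, spec)
    beta, H, ll, n_iter, max_grad = _newton_logistic(X, y, offset)

    H_inv = np.linalg.inv(H)
    if vcov == "model":
        V = H_inv
    else:
        mu = expit(X @ beta + offset)
        V = _cluster_sandwich(X, y - mu, H_inv, df[ID_COL].to_numpy())
    V = 0.5 * (V + V.T)  # enforce symmetry against round-off

    cov_cols = [n for n in names if n in spec.covariates + spec.time_varying]
    if cov_cols:
        lp = df[cov_cols].to_numpy(dtype=float) @ beta[
            [names.index(c) for c in cov_cols]
        ]
        linpred_var = float(np.var(lp))
    else:
        linpred_var = 0.0

    return HazardModelFit(
        params=pd.Series(beta, index=names),
        vcov=pd.DataFrame(V, index=names, columns=names),
        loglik=ll,
        n_obs=len(df),
        n_subjects=table.n_subjects,
        n_events=n_events,
        J_max=table.J_max,
        spec=spec,
        converged=True,
        n_iter=n_iter,
        max_grad=max_grad,
        fixed_intercepts=fixed,
        vcov_type=vcov,
        linpred_var=linpred_var,
    )


def predict_curve(
    fit: HazardModelFit,
    profile: Mapping[str, float],
    time_varying: Mapping[str, Sequence[float]] | None = None,
) -> HazardCurve:
    """Hazard and survival curves for one covariate profile.

    The all-zero profile returns the baseline hazard. Time-varying covariates
    must be supplied as sequences covering periods ``1..J_max``.
    """
    spec = fit.spec
    for name in spec.covariates:
        if name not in profile:
            raise KeyError(f"profile is missing covariate {name!r}")
    tv = time_varying or {}
    for name in spec.time_varying:
        if name not in tv:
            raise KeyError(f"missing time-varying covariate {name!r}")
        if len(tv[name]) < fit.J_max:
            raise ValueError(f"time-varying covariate {name!r} shorter than J_max")

    beta = fit.baseline_logits()
    free = set(spec.free_covariates())
    periods = np.arange(1, fit.J_max + 1)
    eta = beta.to_numpy(dtype=float).copy()

    def _coef(name: str, j: int) -> float:
        # free covariates may lack a coefficient in event-free periods;
        # those periods' hazards are pinned near zero anyway
        try:
            return fit.coefficient(name, period=j)
        except KeyError:
            if name in free:
                return 0.0
            raise

    for k, j in enumerate(periods):
        if np.isnan(eta[k]):
            continue
        for name in spec.covariates:
            eta[k] += _coef(name, int(j)) * profile[name]
        for name in spec.time_varying:
            eta[k] += _coef(name, int(j)) * tv[name][k]

    h = np.where(np.isnan(eta), np.nan, expit(np.nan_to_num(eta)))
    # periods never observed carry no estimate; propagate survival through
    # them by treating the hazard as unknown-but-zero and flagging via NaN h
    h_for_S = np.nan_to_num(h, nan=0.0)
    S = survival_from_hazard(h_for_S)
    idx = pd.Index(periods, name="period")
    return HazardCurve(
        hazard=pd.Series(h, index=idx, name="hazard"),
        survival=pd.Series(S, index=idx, name="survival"),
    )


@dataclass(frozen=True)
class ProportionalityTest:
    """Likelihood-ratio test of period-constant vs period-specific effects."""

    statistic: float
    df: int
    pvalue: float
    loglik_constrained: float
    loglik_free: float
    covariate: str


def test_proportionality(
    table: PersonPeriodTable, spec: HazardSpec, covariate: str
) -> ProportionalityTest:
    """LR test freeing one covariate's coefficient across periods.

    The constrained model carries a single shared coefficient; the free model
    one coefficient per period with events. LR = 2 (ll_free - ll_constrained),
    referred to a chi-square with df = number of freed parameters.
    """
    if covariate not in spec.covariates + spec.time_varying:
        raise ValueError(f"covariate {covariate!r} is not in the model")
    constrained_spec = replace(
        spec, free=tuple(f for f in spec.free if f != covariate), proportional=True
    )
    free_spec = replace(spec, free=constrained_spec.free + (covariate,))

    fit_c = fit_dtsm(table, constrained_spec, vcov="model")
    try:
        fit_f = fit_dtsm(table, free_spec, vcov="model")
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"free (period-specific) model for {covariate!r} did not converge; "
            f"proportionality test abstains: {exc}"
        ) from exc

    df_diff = fit_f.n_params - fit_c.n_params
    lr = max(0.0, 2.0 * (fit_f.loglik - fit_c.loglik))
    if df_diff == 0:
        lr, p = 0.0, 1.0
    else:
        p = float(chi2.sf(lr, df=df_diff))
    return ProportionalityTest(
        statistic=lr,
        df=df_diff,
        pvalue=p,
        loglik_constrained=fit_c.loglik,
        loglik_free=fit_f.loglik,
        covariate=covariate,
    )
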
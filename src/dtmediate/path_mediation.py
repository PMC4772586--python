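"""Recursive path system with a discrete-time survival outcome.

The structural model is a recursive (acyclic) system of equations: binary
mediators are regressed on the exposure and exogenous covariates with linear
probability models, and the terminal equation is the discrete-time logistic
hazard. Under the latent-response reading of the hazard equation the whole
system is linear, so natural indirect effects are products of path
coefficients, the natural direct effect is the exposure coefficient in the
outcome equation, and the total effect is their sum.

Standard errors for products come from the first-order delta method. Because
the system is recursive with independent equation errors, cross-equation
parameter covariances are fixed at zero by default; within-equation
covariances (for paths sharing coefficients from one equation) can be
switched on when a full fit is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2

from . import person_period as pp
from .hazard_model import HazardModelFit, HazardSpec, fit_dtsm

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"
Z95 = 1.959963984540054


class SpecError(ValueError):
    """Invalid path-model specification."""


@dataclass(frozen=True)
class Equation:
    dependent: str
    regressors: tuple[str, ...]
    link: str = "linear"  # linear | discrete_time_logit

    def __post_init__(self) -> None:
        if self.link not in ("linear", "discrete_time_logit"):
            raise SpecError(f"unknown link {self.link!r} for {self.dependent!r}")
        object.__setattr__(self, "regressors", tuple(self.regressors))


@dataclass(frozen=True)
class OutcomeSpec:
    """How to fit the survival (terminal) equation."""

    name: str = "hazard"
    time: str = "time"
    event: str = "event"
    J_max: int = 24
    baseline: str = "unstructured"
    proportional: bool = True
    piecewise_groups: tuple[tuple[int, ...], ...] | None = None


@dataclass(frozen=True)
class PathModelSpec:
    """Ordered recursive equation system with one survival outcome."""

    exposure: str
    equations: tuple[Equation, ...]
    outcome: OutcomeSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "equations", tuple(self.equations))

    @property
    def outcome_equation(self) -> Equation:
        return self.equations[-1]

    @property
    def mediators(self) -> tuple[str, ...]:
        return tuple(
            eq.dependent for eq in self.equations if eq.link == "linear"
        )

    def exogenous(self) -> tuple[str, ...]:
        dependents = {eq.dependent for eq in self.equations}
        seen: list[str] = []
        for eq in self.equations:
            for r in eq.regressors:
                if r not in dependents and r not in seen:
                    seen.append(r)
        return tuple(seen)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for eq in self.equations:
            for r in eq.regressors:
                g.add_edge(r, eq.dependent)
        return g


def validate_spec(spec: PathModelSpec) -> PathModelSpec:
    """Check acyclicity, ordering and outcome terminality; return the spec."""
    logits = [eq for eq in spec.equations if eq.link == "discrete_time_logit"]
    if len(logits) != 1:
        raise SpecError(
            f"exactly one discrete_time_logit equation required, got {len(logits)}"
        )
    if spec.equations[-1].link != "discrete_time_logit":
        raise SpecError("the survival equation must come last")
    outcome = logits[0].dependent
    if outcome != spec.outcome.name:
        raise SpecError(
            f"outcome equation dependent {outcome!r} does not match "
            f"outcome.name {spec.outcome.name!r}"
        )
    defined: set[str] = set()
    dependents = {eq.dependent for eq in spec.equations}
    for eq in spec.equations:
        if eq.dependent in eq.regressors:
            raise SpecError(f"self-loop on {eq.dependent!r}")
        if outcome in eq.regressors:
            raise SpecError(
                f"outcome {outcome!r} used as a regressor in equation for "
                f"{eq.dependent!r}"
            )
        for r in eq.regressors:
            if r in dependents and r not in defined:
                raise SpecError(
                    f"regressor {r!r} in equation for {eq.dependent!r} is a "
                    "dependent of a later equation (ordering violated)"
                )
        defined.add(eq.dependent)
    g = spec.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise SpecError(f"equation system is cyclic: {cycle}")
    if spec.exposure not in g:
        raise SpecError(f"exposure {spec.exposure!r} appears in no equation")
    return spec


def spec_from_dict(cfg: Mapping) -> PathModelSpec:
    """Build a spec from a parsed YAML/JSON mapping (the model config file)."""
    try:
        out = cfg["outcome"]
        equations = tuple(
            Equation(e["dependent"], tuple(e["regressors"]), e.get("link", "linear"))
            for e in cfg["equations"]
        )
        outcome_name = next(
            e.dependent for e in equations if e.link == "discrete_time_logit"
        )
        spec = PathModelSpec(
            exposure=cfg["exposure"],
            equations=equations,
            outcome=OutcomeSpec(
                name=outcome_name,
                time=out.get("time", "time"),
                event=out.get("event", "event"),
                J_max=int(out.get("J_max", 24)),
                baseline=out.get("baseline", "unstructured"),
                proportional=bool(out.get("proportional", True)),
                piecewise_groups=tuple(
                    tuple(g) for g in out["piecewise_groups"]
                ) if out.get("piecewise_groups") else None,
            ),
        )
    except (KeyError, StopIteration) as exc:
        raise SpecError(f"malformed model config: {exc!r}") from exc
    return validate_spec(spec)


def spec_from_yaml(path) -> PathModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return spec_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class EquationFit:
    """Least-squares fit of one linear (probability) equation."""

    dependent: str
    params: pd.Series  # index: intercept + regressors
    vcov: pd.DataFrame
    resid_var: float
    n_obs: int
    n_out_of_range: int  # fitted probabilities outside [0, 1]


def _ols_robust(y: np.ndarray, X: np.ndarray, names: list[str], dep: str):
    n, k = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise ValueError(f"equation {dep!r}: collinear regressors")
    bread = np.linalg.inv(XtX)
    beta = bread @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    sigma2 = float(resid @ resid) / (n - k)
    meat = X.T @ (X * (resid**2)[:, None])
    vcov = bread @ meat @ bread * n / (n - k)  # HC1
    n_oob = int(np.sum((fitted < 0) | (fitted > 1)))
    return (
        pd.Series(beta, index=names),
        pd.DataFrame(0.5 * (vcov + vcov.T), index=names, columns=names),
        sigma2,
        n_oob,
    )


@dataclass(frozen=True)
class PathModelFit:
    """Separately-estimated recursive system (block-diagonal covariance)."""

    spec: PathModelSpec
    linear: Mapping[str, EquationFit]
    hazard_fit: HazardModelFit
    n_subjects: int

    def coef(self, dependent: str, regressor: str) -> float:
        if dependent == self.spec.outcome.name:
            return float(self.hazard_fit.params[regressor])
        return float(self.linear[dependent].params[regressor])

    def se(self, dependent: str, regressor: str) -> float:
        if dependent == self.spec.outcome.name:
            return float(
                np.sqrt(self.hazard_fit.vcov.loc[regressor, regressor])
            )
        return float(np.sqrt(self.linear[dependent].vcov.loc[regressor, regressor]))

    def cov(self, dependent: str, r1: str, r2: str) -> float:
        """Within-equation coefficient covariance (zero across equations)."""
        if dependent == self.spec.outcome.name:
            return float(self.hazard_fit.vcov.loc[r1, r2])
        return float(self.linear[dependent].vcov.loc[r1, r2])

    def has_cov(self) -> bool:
        return True

    def coefficient_frame(self) -> pd.DataFrame:
        """Tidy per-equation estimates mirroring a direct-effects table."""
        rows = []
        for eq in self.spec.equations[:-1]:
            f = self.linear[eq.dependent]
            se = np.sqrt(np.diag(f.vcov.to_numpy()))
            for name, s in zip(f.params.index, se):
                est = f.params[name]
                z = est / s if s > 0 else np.nan
                rows.append((eq.dependent, name, est, s, z, float(chi2.sf(z**2, 1))))
            rows.append(
                (eq.dependent, "residual_variance", f.resid_var, np.nan, np.nan, np.nan)
            )
        hs = self.hazard_fit.summary_frame()
        for name, r in hs.iterrows():
            rows.append(
                (self.spec.outcome.name, name, r["estimate"], r["se"], r["z"], r["p"])
            )
        return pd.DataFrame(
            rows, columns=["equation", "regressor", "estimate", "se", "z", "p"]
        )


class CoefficientTable:
    """Edge coefficients supplied directly (no raw data), e.g. from a printed
    direct-effects table. Covariances between coefficients are unavailable and
    taken as zero."""

    def __init__(self, frame: pd.DataFrame):
        need = {"equation", "regressor", "estimate", "se"}
        missing = need - set(frame.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns {sorted(missing)}")
        dup = frame.duplicated(["equation", "regressor"])
        if dup.any():
            raise ValueError("duplicate (equation, regressor) rows")
        self.frame = frame.reset_index(drop=True)
        self._idx = {
            (r.equation, r.regressor): (float(r.estimate), float(r.se))
            for r in frame.itertuples()
        }

    def _get(self, dependent: str, regressor: str):
        try:
            return self._idx[(dependent, regressor)]
        except KeyError:
            raise KeyError(
                f"no coefficient for regressor {regressor!r} in equation "
                f"{dependent!r}"
            ) from None

    def coef(self, dependent: str, regressor: str) -> float:
        return self._get(dependent, regressor)[0]

    def se(self, dependent: str, regressor: str) -> float:
        return self._get(dependent, regressor)[1]

    def cov(self, dependent: str, r1: str, r2: str) -> float:
        if r1 == r2:
            return self.se(dependent, r1) ** 2
        return 0.0

    def has_cov(self) -> bool:
        return False


def fit_path_system(
    data: pd.DataFrame,
    spec: PathModelSpec,
    J_max: int | None = None,
    vcov: str = "robust",
) -> PathModelFit:
    """Estimate the recursive system equation by equation.

    Linear (probability) equations are fitted by least squares with
    heteroskedasticity-robust (HC1) standard errors; the survival equation by
    `fit_dtsm` on the person-period expansion. The recursive structure with
    independent errors lets the likelihood factorize, so separate estimation
    is the maximum-likelihood solution and cross-equation covariances are zero.
    """
    spec = validate_spec(spec)
    out = spec.outcome
    J = J_max or out.J_max
    for col in (out.time, out.event):
        if col not in data.columns:
            raise ValueError(f"data is missing required column {col!r}")

    linear: dict[str, EquationFit] = {}
    for eq in spec.equations[:-1]:
        missing = [c for c in (eq.dependent,) + eq.regressors if c not in data.columns]
        if missing:
            raise ValueError(f"equation {eq.dependent!r}: missing columns {missing}")
        y = data[eq.dependent].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(data))] + [data[r].to_numpy(dtype=float) for r in eq.regressors]
        )
        names = [INTERCEPT, *eq.regressors]
        try:
            params, V, sigma2, n_oob = _ols_robust(y, X, names, eq.dependent)
        except Exception as exc:
            raise RuntimeError(f"equation {eq.dependent!r} failed: {exc}") from exc
        if n_oob:
            logger.info(
                "equation %r: %d of %d fitted probabilities outside [0, 1]",
                eq.dependent, n_oob, len(y),
            )
        linear[eq.dependent] = EquationFit(
            dependent=eq.dependent,
            params=params,
            vcov=V,
            resid_var=sigma2,
            n_obs=len(y),
            n_out_of_range=n_oob,
        )

    out_eq = spec.outcome_equation
    frame = data.rename(columns={out.time: "time", out.event: "event"})
    if pp.ID_COL not in frame.columns:
        frame = frame.assign(**{pp.ID_COL: np.arange(len(frame))})
    records = pp.frame_to_records(frame, covariates=out_eq.regressors)
    table = pp.expand_person_period(records, J_max=J)
    hspec = HazardSpec(
        covariates=out_eq.regressors,
        baseline=out.baseline,
        piecewise_groups=out.piecewise_groups,
        proportional=out.proportional,
    )
    try:
        hfit = fit_dtsm(table, hspec, vcov=vcov)
    except Exception as exc:
        raise RuntimeError(
            f"survival equation {out.name!r} failed: {exc}"
        ) from exc

    return PathModelFit(
        spec=spec, linear=linear, hazard_fit=hfit, n_subjects=len(data)
    )


# ---------------------------------------------------------------------------
# mediation engine


def enumerate_paths(spec: PathModelSpec) -> list[tuple[str, ...]]:
    """All exposure-to-outcome chains through at least one mediator.

    Deterministic order: shorter chains first, then lexicographic.
    """
    spec = validate_spec(spec)
    g = spec.graph()
    if spec.exposure not in g:
        raise SpecError(f"exposure {spec.exposure!r} absent from the system")
    paths = [
        tuple(p)
        for p in nx.all_simple_paths(g, spec.exposure, spec.outcome.name)
        if len(p) >= 3
    ]
    return sorted(paths, key=lambda p: (len(p), p))


def _edges(path: Sequence[str]) -> list[tuple[str, str]]:
    return list(zip(path[:-1], path[1:]))


def indirect_effect(path: Sequence[str], fit) -> float:
    """Product of the chain's coefficients (natural indirect effect)."""
    prod = 1.0
    for src, dst in _edges(path):
        prod *= fit.coef(dst, src)
    return prod


def delta_se(path: Sequence[str], fit) -> float:
    """First-order delta-method SE of the product along one chain.

    Successive edges belong to distinct equations of the recursive system, so
    their estimates are uncorrelated under the block-diagonal convention:
    Var = sum_k (prod_{j != k} c_j)^2 Var(c_k).
    """
    edges = _edges(path)
    coefs = np.array([fit.coef(dst, src) for src, dst in edges])
    ses = np.array([fit.se(dst, src) for src, dst in edges])
    var = 0.0
    for k in range(len(edges)):
        others = np.prod(np.delete(coefs, k))
        var += (others * ses[k]) ** 2
    return float(np.sqrt(var))


@dataclass(frozen=True)
class EffectEstimate:
    label: str
    estimate: float
    se: float

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.nan

    @property
    def pvalue(self) -> float:
        z = self.z
        return float(chi2.sf(z**2, df=1)) if np.isfinite(z) else np.nan

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)


@dataclass(frozen=True)
class PathEffect(EffectEstimate):
    chain: tuple[str, ...] = ()


@dataclass(frozen=True)
class MediationDecomposition:
    """Direct / per-path indirect / total decomposition of an exposure effect."""

    exposure: str
    outcome: str
    direct: EffectEstimate
    paths: tuple[PathEffect, ...]
    total_indirect: EffectEstimate
    total: EffectEstimate
    proportion_mediated: float
    inconsistent: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [("direct", self.direct.label, self.direct.estimate,
                 self.direct.se, self.direct.z, self.direct.pvalue)]
        for p in self.paths:
            rows.append(("indirect", p.label, p.estimate, p.se, p.z, p.pvalue))
        rows.append(("total_indirect", "all indirect effects",
                     self.total_indirect.estimate, self.total_indirect.se,
                     self.total_indirect.z, self.total_indirect.pvalue))
        rows.append(("total", self.total.label, self.total.estimate,
                     self.total.se, self.total.z, self.total.pvalue))
        rows.append(("proportion_mediated", self.exposure,
                     self.proportion_mediated, np.nan, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["effect", "label", "estimate", "se", "z", "p"]
        )


def decompose(
    fit,
    spec: PathModelSpec | None = None,
    within_equation_cov: bool = False,
) -> MediationDecomposition:
    """Full effect decomposition of the exposure on the survival outcome.

    The total indirect effect is the sum of path products; its SE comes from
    the delta method over the distinct edge coefficients (gradient of the sum
    with respect to each coefficient). With ``within_equation_cov=True`` and a
    full fit available, covariances between coefficients of the same equation
    are included; across equations they are identically zero.
    """
    if spec is None:
        spec = fit.spec
    spec = validate_spec(spec)
    outcome = spec.outcome.name
    if spec.exposure not in spec.outcome_equation.regressors:
        raise SpecError(
            f"exposure {spec.exposure!r} is not a regressor of the outcome equation"
        )
    paths = enumerate_paths(spec)

    path_effects = []
    for p in paths:
        est = indirect_effect(p, fit)
        se = delta_se(p, fit)
        path_effects.append(
            PathEffect(label=" -> ".join(p), estimate=est, se=se, chain=p)
        )

    # gradient of the summed products w.r.t. each distinct edge coefficient
    edge_list: list[tuple[str, str]] = []
    for p in paths:
        for e in _edges(p):
            if e not in edge_list:
                edge_list.append(e)
    grad = {e: 0.0 for e in edge_list}
    for p in paths:
        edges = _edges(p)
        coefs = np.array([fit.coef(dst, src) for src, dst in edges])
        for k, e in enumerate(edges):
            grad[e] += float(np.prod(np.delete(coefs, k)))

    def _quadratic_form(gradient: dict[tuple[str, str], float]) -> float:
        var = 0.0
        items = list(gradient.items())
        for i, ((s1, d1), g1) in enumerate(items):
            var += g1**2 * fit.se(d1, s1) ** 2
            if within_equation_cov and fit.has_cov():
                for (s2, d2), g2 in items[i + 1:]:
                    if d1 == d2:
                        var += 2.0 * g1 * g2 * fit.cov(d1, s1, s2)
        return var

    ti_est = float(sum(p.estimate for p in path_effects))
    ti_se = float(np.sqrt(_quadratic_form(grad))) if paths else 0.0

    direct_est = fit.coef(outcome, spec.exposure)
    direct_se = fit.se(outcome, spec.exposure)

    grad_total = dict(grad)
    direct_edge = (spec.exposure, outcome)
    grad_total[direct_edge] = grad_total.get(direct_edge, 0.0) + 1.0
    total_est = direct_est + ti_est
    total_se = float(np.sqrt(_quadratic_form(grad_total)))

    if total_est == 0.0:
        logger.warning("total effect is exactly zero; mediation proportion undefined")
        proportion = np.nan
        inconsistent = False
    else:
        proportion = ti_est / total_est
        inconsistent = direct_est * ti_est < 0
        if inconsistent:
            logger.warning(
                "direct (%.3g) and indirect (%.3g) effects have opposite signs: "
                "inconsistent mediation, proportion outside [0, 1]",
                direct_est, ti_est,
            )

    return MediationDecomposition(
        exposure=spec.exposure,
        outcome=outcome,
        direct=EffectEstimate(spec.exposure, direct_est, direct_se),
        paths=tuple(path_effects),
        total_indirect=EffectEstimate("total indirect", ti_est, ti_se),
        total=EffectEstimate(spec.exposure, total_est, total_se),
        proportion_mediated=float(proportion),
        inconsistent=inconsistent,
    )


def standardize_latent(fit: PathModelFit, convention: str = "raw") -> pd.DataFrame:
    """Outcome-equation coefficients under a latent-response standardization.

    ``"raw"`` (default) treats the logit-latent coefficients as linear effects
    on a unit-SD latent response, which is the metric on which the product
    decomposition operates. ``"ystar"`` divides by the latent-response SD
    sqrt(Var(linear predictor) + pi^2 / 3), the classical y*-standardization
    for logistic models. The raw view is always retained alongside.
    """
    if convention not in ("raw", "ystar"):
        raise ValueError(f"unknown standardization convention {convention!r}")
    hf = fit.hazard_fit
    cov_names = [
        n for n in hf.params.index if n in fit.spec.outcome_equation.regressors
    ]
    raw = hf.params[cov_names]
    if convention == "raw":
        scale = 1.0
    else:
        scale = float(np.sqrt(hf.linpred_var + np.pi**2 / 3.0))
    return pd.DataFrame(
        {"raw": raw, "standardized": raw / scale, "convention": convention}
    ).rename_axis("regressor")


# ---------------------------------------------------------------------------
# bootstrap cross-check


@dataclass(frozen=True)
class BootstrapResult:
    samples: pd.DataFrame  # one row per successful replicate
    ci: pd.DataFrame  # percentile 95% CIs + bootstrap SEs
    n_requested: int
    n_failed: int


def bootstrap_indirect(
    data: pd.DataFrame,
    spec: PathModelSpec,
    B: int,
    seed: int | None = None,
    J_max: int | None = None,
    vcov: str = "robust",
) -> BootstrapResult:
    """Nonparametric subject-resampling bootstrap of the decomposition.

    Provides percentile CIs and bootstrap SEs for every decomposition
    quantity as an independent check on the delta-method intervals.
    Replicate-level fit failures are logged and skipped; more than 10%
    failures aborts.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    spec = validate_spec(spec)
    rng = np.random.default_rng(seed)
    n = len(data)
    rows = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        if pp.ID_COL in sample.columns:
            sample = sample.drop(columns=[pp.ID_COL])
        try:
            f = fit_path_system(sample, spec, J_max=J_max, vcov=vcov)
            d = decompose(f)
        except Exception as exc:  # noqa: BLE001 - resampled fits may fail
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
            if n_failed > 0.1 * B:
                raise RuntimeError(
                    f"more than 10% of bootstrap replicates failed "
                    f"({n_failed}/{b + 1})"
                ) from exc
            continue
        row = {"direct": d.direct.estimate,
               "total_indirect": d.total_indirect.estimate,
               "total": d.total.estimate,
               "proportion_mediated": d.proportion_mediated}
        for p in d.paths:
            row[p.label] = p.estimate
        rows.append(row)
    samples = pd.DataFrame(rows)
    ci = pd.DataFrame(
        {
            "lower": samples.quantile(0.025),
            "upper": samples.quantile(0.975),
            "se": samples.std(ddof=1),
        }
    ).rename_axis("quantity")
    return BootstrapResult(
        samples=samples, ci=ci, n_requested=B, n_failed=n_failed
    )
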
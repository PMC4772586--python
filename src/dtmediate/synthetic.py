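"""Synthetic cohorts from the colon-cancer generative system.

The generator draws baseline covariates matching the published cohort's
marginals (affluence on a 0-1 metric with mean 0.58 / SD 0.13; age scaled by
0.1; AJCC stage and treatment-optimality frequencies), produces the two binary
mediators from their linear probability equations (Bernoulli draws with
clipped probabilities, mirroring the analysis model so that parameter recovery
is a true self-consistency check), and then draws the event period from the
discrete-time logistic hazard. Censoring is administrative at period J by
default, with an optional per-period random-censoring probability.

The default coefficients are the published direct effects; the default
baseline logit is the constant that puts the cumulative 24-period event
probability at 0.5 for the covariate means (the study does not print its
per-period baseline logits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import datasets
from .path_mediation import (
    Equation,
    OutcomeSpec,
    PathModelSpec,
    decompose,
    enumerate_paths,
    fit_path_system,
    indirect_effect,
)
from .person_period import SurvivalRecord

logger = logging.getLogger(__name__)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    s = mean * (1 - mean) / sd**2 - 1.0
    return mean * s, (1 - mean) * s


@dataclass(frozen=True)
class SyntheticConfig:
    """True generative parameters for cohort simulation.

    Coefficient dictionaries map regressor name -> true value; linear
    equations carry an ``"intercept"`` entry. ``baseline_logit=None`` solves
    for the constant baseline that yields ``target_cum_event`` by period J at
    the covariate means.
    """

    n: int = datasets.COHORT_N
    J: int = datasets.N_PERIODS
    hazard_coef: Mapping[str, float] = field(
        default_factory=lambda: dict(datasets.COLON_HAZARD_COEF)
    )
    mediator_coefs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "emergency": dict(datasets.COLON_EMERGENCY_COEF),
            "caseload": dict(datasets.COLON_CASELOAD_COEF),
        }
    )
    exposure: str = "affluence"
    exposure_dist: str = "beta"  # beta | uniform
    exposure_mean: float = datasets.COLON_AFFLUENCE_MEAN
    exposure_sd: float = datasets.COLON_AFFLUENCE_SD
    age_mean: float = 69.0
    age_sd: float = 11.5
    age_range: tuple[float, float] = (25.0, 99.0)
    stage_probs: tuple[float, ...] = datasets.COLON_STAGE_PROBS
    treatment_p: float = datasets.COLON_TREATMENT_P
    baseline_logit: float | None = None
    target_cum_event: float = 0.5
    censor_prob: float = 0.0
    mediator_mechanism: str = "lpm"  # lpm | logit (misspecification studies)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.J < 1:
            raise ValueError("n and J must be >= 1")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must be a probability")
        if self.mediator_mechanism not in ("lpm", "logit"):
            raise ValueError(f"unknown mediator mechanism {self.mediator_mechanism!r}")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")

    # -- analytic covariate means used when solving for the baseline ------
    def covariate_means(self) -> dict[str, float]:
        means = {
            self.exposure: self.exposure_mean
            if self.exposure_dist == "beta"
            else 0.5,
            "age10": self.age_mean / 10.0,
            "stage2": self.stage_probs[1],
            "stage3": self.stage_probs[2],
            "stage4": self.stage_probs[3],
            "treatment": self.treatment_p,
        }
        for med, coefs in self.mediator_coefs.items():
            p = coefs.get("intercept", 0.0) + sum(
                c * means[r] for r, c in coefs.items() if r != "intercept"
            )
            means[med] = min(max(p, 0.0), 1.0)
        return means

    def resolved_baseline_logit(self) -> float:
        if self.baseline_logit is not None:
            return self.baseline_logit
        means = self.covariate_means()
        h_target = 1.0 - (1.0 - self.target_cum_event) ** (1.0 / self.J)
        shift = sum(c * means[r] for r, c in self.hazard_coef.items())
        return float(logit(h_target) - shift)

    def model_spec(self, baseline: str = "constant") -> PathModelSpec:
        """Analysis spec matching the generative system."""
        equations = [
            Equation(med, tuple(r for r in coefs if r != "intercept"), "linear")
            for med, coefs in self.mediator_coefs.items()
        ]
        equations.append(
            Equation("hazard", tuple(self.hazard_coef), "discrete_time_logit")
        )
        return PathModelSpec(
            exposure=self.exposure,
            equations=tuple(equations),
            outcome=OutcomeSpec(
                name="hazard", J_max=self.J, baseline=baseline, proportional=True
            ),
        )


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SurvivalRecord], dict]:
    """Draw a cohort; returns records and a manifest of the true parameters."""
    frame, manifest = simulate_frame(config)
    cov_cols = [c for c in frame.columns if c not in ("id", "time", "event")]
    records = [
        SurvivalRecord(
            subject_id=int(row.id),
            time=int(row.time),
            event=int(row.event),
            covariates={c: float(getattr(row, c)) for c in cov_cols},
        )
        for row in frame.itertuples(index=False)
    ]
    return records, manifest


def simulate_frame(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Vectorized cohort draw returning a one-row-per-subject frame."""
    rng = np.random.default_rng(config.seed)
    n, J = config.n, config.J

    if config.exposure_dist == "beta":
        a, b = _beta_params(config.exposure_mean, config.exposure_sd)
        exposure = rng.beta(a, b, size=n)
    elif config.exposure_dist == "uniform":
        exposure = rng.uniform(0.0, 1.0, size=n)
    else:
        raise ValueError(f"unknown exposure distribution {config.exposure_dist!r}")

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), *config.age_range)
    stage = rng.choice(len(config.stage_probs), size=n, p=config.stage_probs)
    cols: dict[str, np.ndarray] = {
        config.exposure: exposure,
        "age10": age / 10.0,
        "stage2": (stage == 1).astype(float),
        "stage3": (stage == 2).astype(float),
        "stage4": (stage == 3).astype(float),
        "treatment": rng.binomial(1, config.treatment_p, size=n).astype(float),
    }

    clip_counts: dict[str, int] = {}
    for med, coefs in config.mediator_coefs.items():
        lin = coefs.get("intercept", 0.0) + sum(
            c * cols[r] for r, c in coefs.items() if r != "intercept"
        )
        if config.mediator_mechanism == "lpm":
            p = np.clip(lin, 0.0, 1.0)
            clip_counts[med] = int(np.sum((lin < 0.0) | (lin > 1.0)))
            if clip_counts[med] > 0.2 * n:
                logger.warning(
                    "equation %r: %.1f%% of linear-probability values clipped",
                    med, 100.0 * clip_counts[med] / n,
                )
        else:
            p = expit(lin)
            clip_counts[med] = 0
        cols[med] = rng.binomial(1, p).astype(float)

    beta0 = config.resolved_baseline_logit()
    eta = np.full(n, beta0)
    for r, c in config.hazard_coef.items():
        eta = eta + c * cols[r]
    h = expit(eta)

    # first period whose Bernoulli(hazard) draw fires; 0 means no event by J
    draws = rng.random((n, J)) < h[:, None]
    any_event = draws.any(axis=1)
    event_period = np.where(any_event, draws.argmax(axis=1) + 1, J + 1)

    if config.censor_prob > 0.0:
        cdraws = rng.random((n, J)) < config.censor_prob
        any_c = cdraws.any(axis=1)
        censor_period = np.where(any_c, cdraws.argmax(axis=1) + 1, J + 1)
    else:
        censor_period = np.full(n, J + 1)

    # event within a fully-observed period wins over censoring at its end
    time = np.minimum.reduce([event_period, censor_period, np.full(n, J)])
    event = ((event_period <= censor_period) & (event_period <= J)).astype(int)
    # if censoring strictly precedes the event, the event is unobserved
    event[censor_period < event_period] = 0

    frame = pd.DataFrame({"id": np.arange(n), "time": time, "event": event, **cols})
    manifest = {
        "n": n,
        "J": J,
        "seed": config.seed,
        "baseline_logit": beta0,
        "hazard_coef": dict(config.hazard_coef),
        "mediator_coefs": {m: dict(c) for m, c in config.mediator_coefs.items()},
        "mediator_mechanism": config.mediator_mechanism,
        "censor_prob": config.censor_prob,
        "clip_counts": clip_counts,
        "n_events": int(event.sum()),
    }
    return frame, manifest


# ---------------------------------------------------------------------------
# parameter-recovery harness


@dataclass(frozen=True)
class RecoveryResult:
    summary: pd.DataFrame  # per parameter: truth, mean, bias, rmse, coverage
    n_replicates: int
    n_failed: int


def true_effects(config: SyntheticConfig) -> dict[tuple[str, str], float]:
    """Truth map (equation, parameter) -> value, including indirect paths."""
    truth: dict[tuple[str, str], float] = {}
    for med, coefs in config.mediator_coefs.items():
        for r, c in coefs.items():
            truth[(med, r)] = c
    for r, c in config.hazard_coef.items():
        truth[("hazard", r)] = c
    return truth


class _TruthTable:
    """Adapter exposing the generative coefficients to the mediation engine."""

    def __init__(self, config: SyntheticConfig):
        self._coefs = {"hazard": dict(config.hazard_coef)}
        for m, c in config.mediator_coefs.items():
            self._coefs[m] = dict(c)

    def coef(self, dependent: str, regressor: str) -> float:
        return self._coefs[dependent][regressor]


def true_indirect_effects(config: SyntheticConfig) -> dict[str, float]:
    spec = config.model_spec()
    table = _TruthTable(config)
    return {
        " -> ".join(p): indirect_effect(p, table) for p in enumerate_paths(spec)
    }


def recovery_experiment(
    config: SyntheticConfig,
    replicates: int,
    seed: int | None = None,
    baseline: str = "constant",
) -> RecoveryResult:
    """Simulate-fit-decompose loop summarizing bias, RMSE and CI coverage.

    Coverage uses each replicate's own 95% Wald interval (delta-method
    intervals for the indirect paths). More than 10% replicate failures
    aborts.
    """
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    spec = config.model_spec(baseline=baseline)
    truth = true_effects(config)
    ind_truth = true_indirect_effects(config)
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)

    est: dict[tuple[str, str], list[float]] = {k: [] for k in truth}
    cover: dict[tuple[str, str], list[bool]] = {k: [] for k in truth}
    ind_est: dict[str, list[float]] = {k: [] for k in ind_truth}
    ind_cover: dict[str, list[bool]] = {k: [] for k in ind_truth}

    n_failed = 0
    for r in range(replicates):
        cfg = replace(config, seed=int(child_seeds[r]))
        frame, _ = simulate_frame(cfg)
        try:
            fit = fit_path_system(frame, spec)
            dec = decompose(fit)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            logger.warning("replicate %d failed: %s", r, exc)
            if n_failed > 0.1 * replicates:
                raise RuntimeError(
                    f"more than 10% of replicates failed ({n_failed}/{r + 1})"
                ) from exc
            continue
        for (dep, reg), tv in truth.items():
            e = fit.coef(dep, reg)
            s = fit.se(dep, reg)
            est[(dep, reg)].append(e)
            cover[(dep, reg)].append(abs(e - tv) <= 1.959964 * s)
        for p in dec.paths:
            ind_est[p.label].append(p.estimate)
            lo, hi = p.ci
            ind_cover[p.label].append(lo <= ind_truth[p.label] <= hi)

    rows = []
    for (dep, reg), tv in truth.items():
        e = np.asarray(est[(dep, reg)])
        rows.append(
            (dep, reg, tv, e.mean(), e.mean() - tv,
             math.sqrt(np.mean((e - tv) ** 2)), float(np.mean(cover[(dep, reg)])))
        )
    for label, tv in ind_truth.items():
        e = np.asarray(ind_est[label])
        rows.append(
            ("indirect", label, tv, e.mean(), e.mean() - tv,
             math.sqrt(np.mean((e - tv) ** 2)), float(np.mean(ind_cover[label])))
        )
    summary = pd.DataFrame(
        rows,
        columns=["equation", "parameter", "truth", "mean", "bias", "rmse", "coverage"],
    )
    return RecoveryResult(
        summary=summary, n_replicates=replicates - n_failed, n_failed=n_failed
    )


def write_cohort(frame: pd.DataFrame, manifest: dict, out_dir) -> tuple[str, str]:
    """Write cohort CSV (the schema `read_subject_csv` expects) + manifest."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.csv"
    manifest_path = out / "manifest.yaml"
    frame.to_csv(cohort_path, index=False, float_format="%.6g")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)
    return str(cohort_path), str(manifest_path)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
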
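"""Discrete time-to-event records and their person-period expansion.

Discrete-time survival analysis treats follow-up as a sequence of intervals
(here: quarters). Each subject contributes one binary risk indicator ``u`` per
period for which they were observed at risk: ``u = 0`` for a period survived in
full, ``u = 1`` for the period in which the event occurred, and nothing at all
after the event or after censoring (post-resolution periods are missing data).
The hazard-model likelihood is an ordinary Bernoulli likelihood over these
person-period rows, which is what makes the model estimable with logistic
regression machinery.

Conventions
-----------
* Periods are 1-based; a subject with ``time = t`` was at risk in periods
  ``1..t``.
* Censored subjects are assumed observed for the whole of their final period,
  so their last row is retained with ``u = 0``.
* Events after the truncation horizon ``J_max`` are recoded as censored at
  ``J_max``.
* Deaths from competing causes must be pre-coded by the caller as censoring
  (``event = 0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of the person-period frame
ID_COL = "id"
PERIOD_COL = "period"
EVENT_IND_COL = "u"

_RESERVED = {ID_COL, PERIOD_COL, EVENT_IND_COL, "time", "event"}


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's discrete time-to-event observation.

    Parameters
    ----------
    subject_id:
        Opaque identifier.
    time:
        1-based period of event or censoring (the discrete random variable T).
    event:
        1 if the event occurred in period ``time``, 0 if the subject was
        censored at the end of period ``time``.
    covariates:
        Time-invariant covariate values (the x vector).
    time_varying:
        Optional per-period covariate sequences (the z vectors); each sequence
        must cover at least periods ``1..time``.
    """

    subject_id: Hashable
    time: int
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)
    time_varying: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if not float(self.time).is_integer() or self.time < 1:
            raise ValueError(
                f"subject {self.subject_id!r}: time must be a positive integer, "
                f"got {self.time!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: event must be 0 or 1, got {self.event!r}"
            )
        if self.time_varying:
            for name, seq in self.time_varying.items():
                if len(seq) < self.time:
                    raise ValueError(
                        f"subject {self.subject_id!r}: time-varying covariate "
                        f"{name!r} has {len(seq)} values but time={self.time}"
                    )


@dataclass(frozen=True)
class PersonPeriodTable:
    """Period-expanded cohort: one row per subject per at-risk period."""

    frame: pd.DataFrame
    J_max: int
    covariate_names: tuple[str, ...]
    time_varying_names: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.frame[ID_COL].nunique()

    @property
    def n_events(self) -> int:
        return int(self.frame[EVENT_IND_COL].sum())

    def validate(self) -> None:
        """Check the structural invariants of the expansion (cheap, O(rows))."""
        df = self.frame
        u = df[EVENT_IND_COL].to_numpy()
        if not np.isin(u, (0, 1)).all():
            raise ValueError("u indicator must be binary")
        per = df[PERIOD_COL].to_numpy()
        if per.min() < 1 or per.max() > self.J_max:
            raise ValueError("periods must lie in 1..J_max")
        grouped = df.groupby(ID_COL, sort=False)
        sizes = grouped[PERIOD_COL].agg(["min", "max", "size"])
        if not ((sizes["min"] == 1) & (sizes["max"] == sizes["size"])).all():
            raise ValueError("each subject must contribute contiguous periods 1..T")
        # u=1 allowed only in a subject's final row
        last = grouped.tail(1).index
        if u[~df.index.isin(last)].any():
            raise ValueError("u = 1 before a subject's final period")


def expand_person_period(
    records: Iterable[SurvivalRecord], J_max: int
) -> PersonPeriodTable:
    """Expand subject-level records to the person-period form.

    Subjects with ``time > J_max`` are administratively censored at ``J_max``
    (all-zero ``u`` over ``J_max`` rows); an event occurring exactly at
    ``time <= J_max`` puts ``u = 1`` in the subject's final row.
    """
    if J_max < 1:
        raise ValueError("J_max must be >= 1")
    records = list(records)
    if not records:
        raise ValueError("no survival records supplied")

    cov_names = tuple(records[0].covariates)
    tv_names = tuple(records[0].time_varying or ())
    for r in records:
        if tuple(r.covariates) != cov_names:
            raise ValueError(
                f"subject {r.subject_id!r}: covariate names differ from the "
                f"first record ({sorted(r.covariates)} vs {sorted(cov_names)})"
            )
        if tuple(r.time_varying or ()) != tv_names:
            raise ValueError(
                f"subject {r.subject_id!r}: time-varying covariate names are "
                "inconsistent across records"
            )

    times = np.array([r.time for r in records], dtype=int)
    events = np.array([r.event for r in records], dtype=int)
    obs = np.minimum(times, J_max)
    n_rows = int(obs.sum())

    period = np.concatenate([np.arange(1, o + 1) for o in obs])
    u = np.zeros(n_rows, dtype=int)
    ends = np.cumsum(obs) - 1
    u[ends[(events == 1) & (times <= J_max)]] = 1

    data: dict[str, np.ndarray] = {
        ID_COL: np.repeat([r.subject_id for r in records], obs),
        PERIOD_COL: period,
        EVENT_IND_COL: u,
    }
    for name in cov_names:
        vals = np.array([r.covariates[name] for r in records], dtype=float)
        data[name] = np.repeat(vals, obs)
    for name in tv_names:
        data[name] = np.concatenate(
            [np.asarray(r.time_varying[name][:o], dtype=float) for r, o in zip(records, obs)]
        )

    frame = pd.DataFrame(data)
    return PersonPeriodTable(
        frame=frame,
        J_max=J_max,
        covariate_names=cov_names,
        time_varying_names=tv_names,
    )


def risk_set_counts(table: PersonPeriodTable) -> pd.DataFrame:
    """Per-period risk-set sizes, event counts and life-table hazards.

    Returns a frame indexed by period ``1..J_max`` with columns ``at_risk``,
    ``events`` and ``hazard`` (= events / at_risk; NaN for empty periods).
    """
    df = table.frame
    counts = df.groupby(PERIOD_COL)[EVENT_IND_COL].agg(at_risk="size", events="sum")
    counts = counts.reindex(range(1, table.J_max + 1), fill_value=0)
    counts.index.name = PERIOD_COL
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["hazard"] = np.where(
            counts["at_risk"] > 0, counts["events"] / counts["at_risk"], np.nan
        )
    return counts


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Flatten records to a one-row-per-subject frame (time-invariant part)."""
    records = list(records)
    rows = {
        ID_COL: [r.subject_id for r in records],
        "time": [r.time for r in records],
        "event": [r.event for r in records],
    }
    for name in records[0].covariates:
        rows[name] = [r.covariates[name] for r in records]
    return pd.DataFrame(rows)


def frame_to_records(
    frame: pd.DataFrame, covariates: Sequence[str] | None = None
) -> list[SurvivalRecord]:
    """Build records from a subject-level frame with id/time/event columns."""
    for col in (ID_COL, "time", "event"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    if covariates is None:
        covariates = [c for c in frame.columns if c not in _RESERVED]
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    cov_arr = frame[list(covariates)].to_numpy(dtype=float)
    return [
        SurvivalRecord(
            subject_id=sid,
            time=int(t),
            event=int(e),
            covariates=dict(zip(covariates, row)),
        )
        for sid, t, e, row in zip(
            frame[ID_COL], frame["time"], frame["event"], cov_arr
        )
    ]


def read_subject_csv(
    path,
    time_varying_path=None,
    missing: str = "complete",
) -> tuple[list[SurvivalRecord], dict]:
    """Read a one-row-per-subject cohort CSV.

    Required columns: ``id``, ``time``, ``event``; every other column is taken
    as a time-invariant covariate. An optional long-format companion CSV
    (``id``, ``period``, covariate columns) supplies time-varying covariates.

    ``missing`` selects the treatment of missing covariate values:
    ``"complete"`` drops subjects with any missing value (the count is logged
    and returned), ``"modal"`` fills each column with its modal value.
    """
    if missing not in ("complete", "modal"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    df = pd.read_csv(path)
    for col in (ID_COL, "time", "event"):
        if col not in df.columns:
            raise ValueError(f"input CSV {path}: missing required column {col!r}")

    n_in = len(df)
    cov_cols = [c for c in df.columns if c not in (ID_COL, "time", "event")]
    info: dict = {"n_read": n_in, "n_dropped": 0, "n_imputed": 0}
    if df[["time", "event"]].isna().any().any():
        bad = df.loc[df[["time", "event"]].isna().any(axis=1), ID_COL].tolist()
        raise ValueError(f"missing time/event for subjects {bad[:5]}")
    if cov_cols:
        na_mask = df[cov_cols].isna().any(axis=1)
        if missing == "complete":
            info["n_dropped"] = int(na_mask.sum())
            if info["n_dropped"]:
                logger.info(
                    "dropped %d of %d subjects with missing covariates",
                    info["n_dropped"], n_in,
                )
            df = df.loc[~na_mask]
        else:
            info["n_imputed"] = int(na_mask.sum())
            for c in cov_cols:
                if df[c].isna().any():
                    df[c] = df[c].fillna(df[c].mode().iloc[0])

    tv: dict[Hashable, dict[str, list[float]]] = {}
    tv_names: tuple[str, ...] = ()
    if time_varying_path is not None:
        long_df = pd.read_csv(time_varying_path)
        for col in (ID_COL, PERIOD_COL):
            if col not in long_df.columns:
                raise ValueError(
                    f"time-varying CSV {time_varying_path}: missing column {col!r}"
                )
        tv_names = tuple(
            c for c in long_df.columns if c not in (ID_COL, PERIOD_COL)
        )
        for sid, grp in long_df.sort_values(PERIOD_COL).groupby(ID_COL):
            periods = grp[PERIOD_COL].to_numpy()
            if not np.array_equal(periods, np.arange(1, len(periods) + 1)):
                raise ValueError(
                    f"subject {sid!r}: time-varying periods must be contiguous from 1"
                )
            tv[sid] = {name: grp[name].tolist() for name in tv_names}

    records = []
    for _, row in df.iterrows():
        sid = row[ID_COL]
        records.append(
            SurvivalRecord(
                subject_id=sid,
                time=int(row["time"]),
                event=int(row["event"]),
                covariates={c: float(row[c]) for c in cov_cols},
                time_varying=tv.get(sid) if time_varying_path is not None else None,
            )
        )
    return records, info
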
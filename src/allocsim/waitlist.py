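"""Dynamic waiting-list model (Poisson queueing with risk-ranked departures).

The waiting list starts from ``n0`` candidates drawn from a reservoir pool by
stratified sampling over age band, blood group, state and PRA band.  Each
simulated day then sees

* arrivals: count ~ Poisson(k_in(t) * lambda_in), candidates moved from the
  pool to the active list (stratum-weighted, listing date set to that day);
* departures without transplant: count ~ Poisson(k_out(t) * lambda_out); all
  active candidates are scored by an exit-risk scorer and the highest-risk
  ones are removed (ties: earlier listing date, then id).

The k schedules are piecewise-constant multipliers keyed by calendar year,
capturing yearly trends in arrival/departure pressure.  Every day draws from
its own random substream, so advancing in one call or many is identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .cohort import age_band, pra_band
from .errors import ConfigError, ValidationError

EXIT_FEATURES = (
    "age",
    "sex_m",
    "lung_disease",
    "smoking",
    "diabetes",
    "cardiovascular_disease",
    "cancer",
    "pra",
    "years_on_dialysis",
    "blood_group",
    "state",
)


@dataclasses.dataclass
class DynamicsConfig:
    """Tunables of the queueing model.

    ``k_in``/``k_out`` map calendar years to non-negative rate multipliers
    (missing years default to 1).  ``strata_targets`` optionally maps each of
    ``age_band``/``blood_group``/``state``/``pra_band`` to target category
    frequencies; candidates are then sampled with importance weights
    target/pool so realised frequencies approximate the targets.
    """

    n0: int = 300
    lambda_in: float = 0.7
    lambda_out: float = 0.4
    k_in: Mapping[int, float] = dataclasses.field(default_factory=dict)
    k_out: Mapping[int, float] = dataclasses.field(default_factory=dict)
    strata_targets: Mapping[str, Mapping[str, float]] | None = None
    reentry_prob: float = 0.0
    start_date: datetime.date | None = None  # None: caller supplies (engine uses
    seed: int = 0                            # the first donation date)

    def validate(self) -> "DynamicsConfig":
        if self.n0 < 0:
            raise ValidationError("dynamics.n0 must be >= 0")
        if self.lambda_in < 0 or self.lambda_out < 0:
            raise ValidationError("dynamics rates must be >= 0")
        for name, sched in (("k_in", self.k_in), ("k_out", self.k_out)):
            for year, mult in sched.items():
                if mult < 0:
                    raise ValidationError(f"dynamics.{name}[{year}] must be >= 0")
        if not 0 <= self.reentry_prob <= 1:
            raise ValidationError("dynamics.reentry_prob must be in [0, 1]")
        return self

    def rate_in(self, day: datetime.date) -> float:
        return float(self.k_in.get(day.year, 1.0)) * self.lambda_in

    def rate_out(self, day: datetime.date) -> float:
        return float(self.k_out.get(day.year, 1.0)) * self.lambda_out


class LogisticExitScorer:
    """Logistic-linear exit-without-transplant risk.

    score = logistic(intercept + sum_f coef_f * x_f) over the default feature
    set (age, sex, five comorbidity flags, PRA, years on dialysis at the
    scoring date, blood group and state category effects).  Higher scores are
    removed first.  This is the parametric default behind the exit-risk
    contract; any callable ``(frame, on_date) -> array`` may replace it, e.g.
    a survival-forest model fitted to registry data.
    """

    def __init__(self, coefficients: Mapping):
        missing = [f for f in EXIT_FEATURES if f not in coefficients]
        if "intercept" not in coefficients:
            missing.append("intercept")
        if missing:
            raise ConfigError(f"exit scorer missing coefficient(s): {missing}")
        self.coefficients = dict(coefficients)

    def _static_linear(self, frame: pd.DataFrame) -> np.ndarray:
        c = self.coefficients
        lin = np.full(len(frame), float(c["intercept"]))
        lin += float(c["age"]) * frame["age"].to_numpy(dtype=float)
        lin += float(c["sex_m"]) * (frame["sex"].to_numpy(dtype=object) == "M")
        for flag in ("lung_disease", "smoking", "diabetes", "cardiovascular_disease", "cancer"):
            lin += float(c[flag]) * frame[flag].to_numpy(dtype=bool)
        lin += float(c["pra"]) * frame["pra"].to_numpy(dtype=float)
        for cat_feature, column in (("blood_group", "blood_group"), ("state", "state")):
            mapping = c[cat_feature]
            lin += np.array(
                [float(mapping[v]) for v in frame[column]], dtype=float
            )
        return lin

    def bind(self, frame: pd.DataFrame) -> "_BoundExitScorer":
        dial = np.array(
            [d.toordinal() if d is not None and not pd.isna(d) else -1
             for d in frame["dialysis_start_date"]],
            dtype=np.int64,
        )
        return _BoundExitScorer(
            self._static_linear(frame), dial, float(self.coefficients["years_on_dialysis"])
        )

    def __call__(self, frame: pd.DataFrame, on_date: datetime.date) -> np.ndarray:
        bound = self.bind(frame)
        return bound.scores(np.arange(len(frame)), on_date.toordinal())


class _BoundExitScorer:
    """Scorer pre-compiled against a fixed candidate frame for fast daily use."""

    def __init__(self, static_linear: np.ndarray, dialysis_ord: np.ndarray, coef_dial: float):
        self._static = static_linear
        self._dial = dialysis_ord
        self._coef = coef_dial

    def scores(self, positions: np.ndarray, day_ordinal: int) -> np.ndarray:
        lin = self._static[positions].copy()
        dial = self._dial[positions]
        on = dial >= 0
        years = np.where(on, np.maximum(day_ordinal - dial, 0) / 365.25, 0.0)
        lin += self._coef * years
        return 1.0 / (1.0 + np.exp(-lin))


def default_exit_scorer(coefficients: Mapping | None = None) -> LogisticExitScorer:
    """Build the packaged logistic exit-risk scorer (or one from ``coefficients``)."""
    if coefficients is None:
        from .config import packaged_defaults

        coefficients = packaged_defaults()["exit_scorer"]["coefficients"]
    return LogisticExitScorer(coefficients)


@dataclasses.dataclass
class WaitlistState:
    """The time-indexed waiting list.

    ``frame`` holds every candidate ever known (active, pooled or departed);
    ``active``/``pool`` are integer positions into it.  ``event_log`` is
    append-only (date, candidate id, event) with event in
    {init, arrival, departure, transplant}.
    """

    frame: pd.DataFrame
    active: np.ndarray
    pool: np.ndarray
    clock: datetime.date
    event_log: list
    departed: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0, dtype=np.int64))
    _weights: np.ndarray | None = None
    _listing_ord: np.ndarray | None = None
    _ids: np.ndarray | None = None

    @property
    def active_frame(self) -> pd.DataFrame:
        return self.frame.iloc[self.active]

    def log(self, day: datetime.date, positions, event: str) -> None:
        for pos in np.atleast_1d(positions):
            self.event_log.append((day, self._ids[int(pos)], event))

    def event_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.event_log, columns=["date", "id", "event"])

    def remove_transplanted(self, position: int, day: datetime.date) -> None:
        """Remove one active candidate as a transplant (engine callback)."""
        self.active = self.active[self.active != position]
        self.log(day, position, "transplant")


def _stratum_weights(
    frame: pd.DataFrame, targets: Mapping[str, Mapping[str, float]] | None
) -> np.ndarray:
    """Importance weight per candidate: prod over variables of target/pool freq."""
    n = len(frame)
    weights = np.ones(n)
    if not targets:
        return weights
    derived = {
        "age_band": lambda f: age_band(f["age"]),
        "blood_group": lambda f: f["blood_group"].to_numpy(dtype=object),
        "state": lambda f: f["state"].to_numpy(dtype=object),
        "pra_band": lambda f: pra_band(f["pra"]),
    }
    for var, target in targets.items():
        if var not in derived:
            raise ValidationError(f"strata_targets: unknown variable {var!r}")
        labels = derived[var](frame)
        pool_freq = pd.Series(labels).value_counts(normalize=True)
        present_mass = sum(p for cat, p in target.items() if cat in pool_freq.index)
        if present_mass <= 0:
            raise ValidationError(f"strata_targets.{var}: no target category present in pool")
        if present_mass < 1 - 1e-9:
            warnings.warn(
                f"strata_targets.{var}: target mass {1 - present_mass:.3f} on empty strata; "
                "renormalising over non-empty strata",
                stacklevel=2,
            )
        factor = np.array(
            [target.get(lab, 0.0) / present_mass / pool_freq.get(lab, np.inf) for lab in labels]
        )
        weights *= factor
    return weights


def _weighted_draw(
    rng: np.random.Generator, pool: np.ndarray, weights: np.ndarray, size: int
) -> np.ndarray:
    """Sample ``size`` positions from ``pool`` without replacement, weight-proportional."""
    w = weights[pool]
    total = w.sum()
    if total <= 0:
        w = np.ones(len(pool))
        total = float(len(pool))
    chosen = rng.choice(len(pool), size=size, replace=False, p=w / total)
    return pool[chosen]


def initialize_waitlist(pool_table: pd.DataFrame, config: DynamicsConfig) -> WaitlistState:
    """Draw the initial active list (size n0) from the candidate pool.

    Sampling is without replacement with stratum importance weights so the
    realised joint frequencies over the four stratification variables
    approximate ``config.strata_targets``; the unchosen remainder stays in the
    pool and feeds future arrivals.
    """
    config.validate()
    start = config.start_date or datetime.date(2010, 1, 1)
    frame = pool_table.reset_index(drop=True)
    if len(frame) < config.n0:
        raise ValidationError(f"pool of {len(frame)} smaller than n0={config.n0}")
    weights = _stratum_weights(frame, config.strata_targets)
    rng = substream(config.seed, "init")
    everyone = np.arange(len(frame), dtype=np.int64)
    chosen = np.sort(_weighted_draw(rng, everyone, weights, config.n0))
    state = WaitlistState(
        frame=frame,
        active=chosen,
        pool=np.setdiff1d(everyone, chosen),
        clock=start,
        event_log=[],
        _weights=weights,
        _listing_ord=np.array(
            [d.toordinal() for d in frame["listing_date"]], dtype=np.int64
        ),
        _ids=frame["id"].to_numpy(dtype=object),
    )
    state.log(start, chosen, "init")
    return state


def step_arrivals(state: WaitlistState, day: datetime.date, config: DynamicsConfig) -> WaitlistState:
    """Admit Poisson(k_in(day) * lambda_in) candidates from the pool."""
    rng = substream(config.seed, "arrivals", day)
    count = int(rng.poisson(config.rate_in(day)))
    if count == 0:
        return state
    if count > len(state.pool):
        if not getattr(state, "_pool_warned", False):
            warnings.warn(
                f"{day}: pool exhausted, admitting {len(state.pool)} of {count} "
                "(further exhaustion warnings suppressed)",
                stacklevel=2,
            )
            state._pool_warned = True
        count = len(state.pool)
        if count == 0:
            return state
    chosen = _weighted_draw(rng, state.pool, state._weights, count)
    day_ord = day.toordinal()
    for pos in chosen:
        state.frame.iat[int(pos), state.frame.columns.get_loc("listing_date")] = day
        state._listing_ord[int(pos)] = day_ord
    state.pool = np.setdiff1d(state.pool, chosen)
    state.active = np.concatenate([state.active, np.sort(chosen)])
    state.log(day, chosen, "arrival")
    return state


def rank_for_departure(
    scores: np.ndarray, listing_ords: np.ndarray, ids: np.ndarray
) -> np.ndarray:
    """Order candidate indices for removal: highest score first, ties broken by
    earlier listing date, then id order."""
    return np.lexsort((ids, listing_ords, -scores))


def step_departures(
    state: WaitlistState,
    day: datetime.date,
    config: DynamicsConfig,
    scorer: Callable | _BoundExitScorer,
) -> WaitlistState:
    """Remove Poisson(k_out(day) * lambda_out) highest-exit-risk candidates."""
    rng = substream(config.seed, "departures", day)
    n_out = int(rng.poisson(config.rate_out(day)))
    if n_out == 0:
        return state
    if n_out > len(state.active):
        warnings.warn(f"{day}: departures {n_out} exceed active {len(state.active)}", stacklevel=2)
        n_out = len(state.active)
        if n_out == 0:
            return state
    if isinstance(scorer, _BoundExitScorer):
        scores = scorer.scores(state.active, day.toordinal())
    else:
        scores = np.asarray(scorer(state.frame.iloc[state.active], day), dtype=float)
    order = rank_for_departure(
        scores, state._listing_ord[state.active], state._ids[state.active]
    )
    leavers = state.active[order[:n_out]]
    state.active = np.setdiff1d(state.active, leavers)
    state.departed = np.concatenate([state.departed, leavers])
    state.log(day, leavers, "departure")
    return state


def _step_reentries(state: WaitlistState, day: datetime.date, config: DynamicsConfig) -> None:
    if config.reentry_prob <= 0 or len(state.departed) == 0:
        return
    rng = substream(config.seed, "reentry", day)
    back = state.departed[rng.random(len(state.departed)) < config.reentry_prob]
    if len(back):
        state.departed = np.setdiff1d(state.departed, back)
        state.pool = np.concatenate([state.pool, back])


def advance_to(
    state: WaitlistState,
    target_date: datetime.date,
    config: DynamicsConfig,
    scorer: Callable | LogisticExitScorer | None = None,
) -> WaitlistState:
    """Apply arrivals then departures for every day in (clock, target_date]."""
    if target_date < state.clock:
        raise ValidationError(f"target_date {target_date} precedes clock {state.clock}")
    if scorer is None:
        scorer = default_exit_scorer()
    bound = scorer.bind(state.frame) if isinstance(scorer, LogisticExitScorer) else scorer
    day = state.clock
    while day < target_date:
        day = day + datetime.timedelta(days=1)
        _step_reentries(state, day, config)
        step_arrivals(state, day, config)
        step_departures(state, day, config, bound)
    state.clock = target_date
    return state


def check_conservation(state: WaitlistState) -> bool:
    """Verify |active| = inits + arrivals - departures - transplants from the log."""
    counts = {"init": 0, "arrival": 0, "departure": 0, "transplant": 0}
    last = None
    for date, _id, event in state.event_log:
        counts[event] += 1
        if last is not None and date < last:
            return False
        last = date
    expected = counts["init"] + counts["arrival"] - counts["departure"] - counts["transplant"]
    return expected == len(state.active)
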
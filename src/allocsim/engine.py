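"""Simulation engine: donor stream -> waitlist -> scoring -> decision -> records.

For each donor in chronological order the engine (optionally) advances the
dynamic waiting list to the donation date, filters the active candidates by
the eligibility rule (default / CORisk / IRisk), scores them, and runs the
configured allocation rounds — national (ABO-strict), state (ABO-strict,
within the balance-adjusted centre), national (ABO-compatible) — handing each
round's offers to the configured decision model.  A match removes the
recipient from the list and appends a :class:`MatchRecord`; an unallocated
kidney is recorded as a discard.

Three preset processes mirror the validation design:
I  maximum-score selection (sdm0), static list;
II shared decision-making (sdm1), static list;
III shared decision-making with the dynamic waiting list.
``process="custom"`` frees the combination (e.g. sdm0 with dynamics, as used
by the policy-comparison strategies).
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._rng import derive_seed, substream
from .cohort import split_alleles
from .decisions import AcceptanceConfig, sdm0_select, sdm1_select
from .errors import ValidationError
from .rules import (
    EligibilityConfig,
    ScoreConfig,
    StateLedger,
    abo_compatible_mask,
    geodesic_center,
    percentile_score,
    raw_epts,
    state_balance_target,
    surrogate_scores,
)
from .waitlist import (
    DynamicsConfig,
    LogisticExitScorer,
    WaitlistState,
    advance_to,
    default_exit_scorer,
    initialize_waitlist,
)

DEFAULT_ROUNDS = (("national", "strict"), ("state", "strict"), ("national", "compatible"))


@dataclasses.dataclass
class MatchRecord:
    """Outcome of one donor's allocation (recipient None = discard)."""

    donor_id: str
    recipient_id: str | None
    tier: str | None
    abo_round: str | None
    consideration: int | None
    score: float | None
    waiting_time_days: int | None
    transplant_date: datetime.date
    centre: str | None

    @property
    def matched(self) -> bool:
        return self.recipient_id is not None


RECORD_COLUMNS = [f.name for f in dataclasses.fields(MatchRecord)]


def records_to_frame(records: Sequence[MatchRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; presets I/II/III pin the decision model and
    waiting-list dynamics, ``custom`` leaves both free."""

    process: str = "III"
    donor_sample_size: int = 800
    dynamics: DynamicsConfig = dataclasses.field(default_factory=DynamicsConfig)
    score: ScoreConfig = dataclasses.field(default_factory=ScoreConfig)
    eligibility: EligibilityConfig = dataclasses.field(default_factory=EligibilityConfig)
    acceptance: AcceptanceConfig = dataclasses.field(default_factory=AcceptanceConfig)
    decision_model: str | None = None
    dynamic_waitlist: bool | None = None
    state_balance: bool = False
    waiting_time_from: str = "listing"
    rounds: Sequence = DEFAULT_ROUNDS
    seed: int = 0
    replications: int = 1
    workers: int = 1

    _PRESETS = {"I": ("sdm0", False), "II": ("sdm1", False), "III": ("sdm1", True)}

    def resolved(self) -> "RunConfig":
        """Validate and fill decision model / dynamics from the process preset."""
        if self.process not in ("I", "II", "III", "custom"):
            raise ValidationError(f"unknown process {self.process!r}")
        decision, dynamic = self.decision_model, self.dynamic_waitlist
        if self.process != "custom":
            preset_decision, preset_dynamic = self._PRESETS[self.process]
            if decision is not None and decision != preset_decision:
                raise ValidationError(
                    f"process {self.process} requires decision model {preset_decision}"
                )
            if dynamic is not None and dynamic != preset_dynamic:
                raise ValidationError(
                    f"process {self.process} requires dynamic_waitlist={preset_dynamic}"
                )
            decision, dynamic = preset_decision, preset_dynamic
        else:
            decision = decision or "sdm1"
            dynamic = True if dynamic is None else dynamic
        if decision not in ("sdm0", "sdm1"):
            raise ValidationError(f"unknown decision model {decision!r}")
        if self.donor_sample_size < 1:
            raise ValidationError("donor_sample_size must be >= 1")
        if self.waiting_time_from not in ("listing", "dialysis"):
            raise ValidationError(f"unknown waiting_time_from {self.waiting_time_from!r}")
        if self.replications < 1 or self.workers < 1:
            raise ValidationError("replications and workers must be >= 1")
        self.dynamics.validate()
        self.score.validate()
        self.eligibility.validate()
        self.acceptance.validate()
        return dataclasses.replace(self, decision_model=decision, dynamic_waitlist=dynamic)


def sample_donor_stream(donor_pool: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Sample ``n`` donors uniformly (without replacement while possible) and
    sort them chronologically by donation date."""
    if len(donor_pool) == 0:
        raise ValidationError("donor pool is empty")
    rng = substream(seed, "donor-stream")
    replace = n > len(donor_pool)
    if replace:
        warnings.warn(
            f"requested {n} donors from pool of {len(donor_pool)}; sampling with replacement",
            stacklevel=2,
        )
    idx = rng.choice(len(donor_pool), size=n, replace=replace)
    stream = donor_pool.iloc[idx].copy()
    stream["_ord"] = [d.toordinal() for d in stream["donation_date"]]
    stream = stream.sort_values(["_ord", "id"], kind="mergesort").drop(columns="_ord")
    return stream.reset_index(drop=True)


@dataclasses.dataclass
class SimulationResult:
    records: list
    waitlist: WaitlistState
    ledger: StateLedger

    @property
    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    @property
    def event_log(self) -> pd.DataFrame:
        return self.waitlist.event_log_frame()


class _CandidateArrays:
    """Column caches over the full candidate frame for fast per-donor maths."""

    def __init__(self, frame: pd.DataFrame):
        self.age = frame["age"].to_numpy(dtype=float)
        self.pra = frame["pra"].to_numpy(dtype=float)
        self.bg = frame["blood_group"].to_numpy(dtype=object)
        self.state = frame["state"].to_numpy(dtype=object)
        self.centre = np.array([geodesic_center(s) for s in self.state], dtype=object)
        self.prior = frame["prior_kidney_transplant"].to_numpy(dtype=bool)
        self.ids = frame["id"].to_numpy(dtype=object)
        self.dial_ord = np.array(
            [d.toordinal() if d is not None and not pd.isna(d) else -1
             for d in frame["dialysis_start_date"]],
            dtype=np.int64,
        )
        self.alleles = {
            locus: split_alleles(frame[f"hla_{locus}"]) for locus in ("a", "b", "dr")
        }

    def years_on_dialysis(self, positions: np.ndarray, day_ord: int) -> np.ndarray:
        dial = self.dial_ord[positions]
        return np.where(dial >= 0, np.maximum(day_ord - dial, 0) / 365.25, 0.0)

    def weighted_mismatch(self, donor: pd.Series, positions: np.ndarray) -> np.ndarray:
        from .cohort import hla_mismatch_counts

        total = np.zeros(len(positions), dtype=int)
        for locus, weight in (("dr", 2), ("a", 1), ("b", 1)):
            d1, d2 = str(donor[f"hla_{locus}"]).split(";")
            a1, a2 = self.alleles[locus]
            total += weight * hla_mismatch_counts((d1, d2), a1[positions], a2[positions])
        return total


def run_simulation(
    config: RunConfig,
    candidate_pool: pd.DataFrame,
    donor_pool: pd.DataFrame,
    exit_scorer: LogisticExitScorer | None = None,
) -> SimulationResult:
    """Run one full allocation simulation; deterministic given ``config.seed``."""
    config = config.resolved()
    seed = config.seed
    donors = sample_donor_stream(donor_pool, config.donor_sample_size, seed)

    first_day = donors["donation_date"].iloc[0]
    dynamics = dataclasses.replace(
        config.dynamics,
        seed=seed,
        start_date=config.dynamics.start_date or first_day,
    )
    state = initialize_waitlist(candidate_pool, dynamics)
    arrays = _CandidateArrays(state.frame)
    scorer = exit_scorer or default_exit_scorer()
    bound_scorer = scorer.bind(state.frame) if isinstance(scorer, LogisticExitScorer) else scorer

    kdri_ref = np.sort(donor_pool["kdri"].to_numpy(dtype=float))
    # EPTS reference pool: every candidate, dialysis exposure frozen at listing.
    listing_years = np.where(
        arrays.dial_ord >= 0,
        np.maximum(state._listing_ord - arrays.dial_ord, 0) / 365.25,
        0.0,
    )
    epts_ref = np.sort(raw_epts(arrays.age, arrays.prior, listing_years))

    ledger = StateLedger()
    records: list[MatchRecord] = []

    for _, donor in donors.iterrows():
        day = donor["donation_date"]
        if config.dynamic_waitlist and day > state.clock:
            advance_to(state, day, dynamics, bound_scorer)
        day_ord = day.toordinal()
        year = day.year
        own_centre = geodesic_center(donor["state"])
        ledger.record_donor(own_centre, year)

        active = state.active
        if len(active) == 0:
            records.append(MatchRecord(donor["id"], None, None, None, None, None, None, day, None))
            continue

        kdpi_pct = percentile_score(donor["kdri"], kdri_ref)
        years = arrays.years_on_dialysis(active, day_ord)
        epts_pct = percentile_score(raw_epts(arrays.age[active], arrays.prior[active], years), epts_ref)
        eligible = config.eligibility.mask(epts_pct, kdpi_pct)

        mismatch = arrays.weighted_mismatch(donor, active)
        days_waited = np.maximum(day_ord - state._listing_ord[active], 0)
        if config.score.scorer is not None:
            sub = state.frame.iloc[active]
            scores = np.array(
                [config.score.scorer(row, donor, day) for _, row in sub.iterrows()], dtype=float
            )
        else:
            scores = surrogate_scores(days_waited, mismatch, arrays.pra[active], config.score)
        national_mask = scores > config.score.national_threshold

        alpha1 = (arrays.age[active] < 18) & (np.abs(arrays.age[active] - donor["age"]) < 30)
        alpha2 = epts_pct >= kdpi_pct - config.acceptance.alpha2_threshold
        alpha3 = (arrays.bg[active] == "AB") & (donor["blood_group"] == "AB")
        alpha4 = arrays.state[active] == donor["state"]

        target_centre = state_balance_target(ledger, donor, config.state_balance)
        rng = substream(seed, "decision", donor["id"])
        record = None
        for tier, abo_mode in config.rounds:
            abo_ok = abo_compatible_mask(donor["blood_group"], arrays.bg[active], abo_mode)
            if tier == "national":
                mask = eligible & abo_ok & national_mask
            else:
                mask = eligible & abo_ok & ~national_mask & (arrays.centre[active] == target_centre)
            if not mask.any():
                continue
            offers = pd.DataFrame(
                {
                    "position": active[mask],
                    "id": arrays.ids[active][mask],
                    "score": scores[mask],
                    "days_waited": days_waited[mask],
                    "pra": arrays.pra[active][mask],
                    "hla_weighted": mismatch[mask],
                    "alpha1": alpha1[mask],
                    "alpha2": alpha2[mask],
                    "alpha3": alpha3[mask],
                    "alpha4": alpha4[mask],
                }
            )
            if config.decision_model == "sdm0":
                chosen, consideration = sdm0_select(offers), None
            else:
                chosen, consideration = sdm1_select(offers, config.acceptance, rng)
            if chosen is not None:
                pos = int(chosen["position"])
                if config.waiting_time_from == "dialysis" and arrays.dial_ord[pos] >= 0:
                    waited = int(day_ord - arrays.dial_ord[pos])
                else:
                    waited = int(day_ord - state._listing_ord[pos])
                record = MatchRecord(
                    donor_id=donor["id"],
                    recipient_id=str(chosen["id"]),
                    tier=tier,
                    abo_round=abo_mode,
                    consideration=consideration,
                    score=float(chosen["score"]),
                    waiting_time_days=max(waited, 0),
                    transplant_date=day,
                    centre=str(arrays.centre[pos]),
                )
                state.remove_transplanted(pos, day)
                ledger.record_transplant(arrays.centre[pos], year)
                break
        records.append(
            record
            or MatchRecord(donor["id"], None, None, None, None, None, None, day, None)
        )
    return SimulationResult(records, state, ledger)


def replicate(
    config: RunConfig,
    candidate_pool: pd.DataFrame,
    donor_pool: pd.DataFrame,
    n_reps: int | None = None,
    workers: int | None = None,
) -> list[SimulationResult]:
    """Run ``n_reps`` independent replicates, each on its own derived seed.

    Replicate r uses seed derived from (master seed, r), so outputs are
    identical element-wise regardless of worker count or scheduling order.
    """
    config = config.resolved()
    n_reps = n_reps if n_reps is not None else config.replications
    workers = workers if workers is not None else config.workers
    if n_reps < 1 or workers < 1:
        raise ValidationError("n_reps and workers must be >= 1")
    configs = [
        dataclasses.replace(config, seed=derive_seed(config.seed, r)) for r in range(n_reps)
    ]
    if workers == 1:
        return [run_simulation(c, candidate_pool, donor_pool) for c in configs]
    return Parallel(n_jobs=workers)(
        delayed(run_simulation)(c, candidate_pool, donor_pool) for c in configs
    )
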
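"""Allocation scoring, two-tier routing, eligibility filters and state balance.

The Australian deceased-donor system is two-tiered: candidates whose
allocation score exceeds 54,000,000 compete nationally; everyone else is
allocated within the donor's (geodesic) state centre.  The exact national and
five state scoring tables are defined by external guidelines; this module
ships a documented surrogate score with the same routing semantics behind a
pluggable interface (see :func:`surrogate_scores`).

Also here: ABO compatibility (strict and the compatible matrix), the raw EPTS
equation and midrank percentile conversion (EPTS%, KDPI), the CORisk/IRisk
longevity-matching eligibility filters, and the state-balance redirection of
donors from over-served to under-served centres.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .cohort import BLOOD_GROUPS, STATES
from .errors import ValidationError

# Donor -> recipient compatibility under the non-strict rule:
# O donates to all, A to A/AB, B to B/AB, AB to AB (9 compatible pairs).
ABO_COMPATIBLE_PAIRS = frozenset(
    [
        ("O", "O"), ("O", "A"), ("O", "B"), ("O", "AB"),
        ("A", "A"), ("A", "AB"),
        ("B", "B"), ("B", "AB"),
        ("AB", "AB"),
    ]
)

GEODESIC_CENTRE = {
    "NSW": "NSW/ACT",
    "ACT": "NSW/ACT",
    "VIC": "VIC/TAS",
    "TAS": "VIC/TAS",
    "WA": "WA",
    "SA": "SA/NT",
    "NT": "SA/NT",
    "QLD": "QLD",
}
CENTRES = ("NSW/ACT", "QLD", "SA/NT", "VIC/TAS", "WA")


def abo_compatible(donor_bg: str, recipient_bg: str, mode: str = "compatible") -> bool:
    """Blood-group match: ``strict`` requires identity; ``compatible`` follows
    the standard donation matrix (O universal donor, AB universal recipient)."""
    if donor_bg not in BLOOD_GROUPS or recipient_bg not in BLOOD_GROUPS:
        raise ValidationError(f"unknown blood group in ({donor_bg!r}, {recipient_bg!r})")
    if mode == "strict":
        return donor_bg == recipient_bg
    if mode == "compatible":
        return (donor_bg, recipient_bg) in ABO_COMPATIBLE_PAIRS
    raise ValidationError(f"unknown ABO mode {mode!r}")


def abo_compatible_mask(donor_bg: str, recipient_bgs: np.ndarray, mode: str) -> np.ndarray:
    """Vectorised :func:`abo_compatible` over an array of recipient groups."""
    if mode == "strict":
        return recipient_bgs == donor_bg
    ok = np.array([bg for d, bg in ABO_COMPATIBLE_PAIRS if d == donor_bg], dtype=object)
    return np.isin(recipient_bgs, ok)


def raw_epts(age, prior_transplant, years_on_dialysis):
    """Raw Estimated Post-Transplant Survival linear predictor.

    0.049*age*I(age>25) + 0.493*I(prior transplant)
    + 0.287*ln(years on dialysis + 1) + 0.598*I(years on dialysis = 0).

    Lower is better (longer expected survival).  Accepts scalars or arrays.
    """
    age = np.asarray(age, dtype=float)
    years = np.asarray(years_on_dialysis, dtype=float)
    prior = np.asarray(prior_transplant, dtype=bool)
    if (age < 0).any() or (years < 0).any():
        raise ValidationError("age and years_on_dialysis must be non-negative")
    value = (
        0.049 * age * (age > 25)
        + 0.493 * prior
        + 0.287 * np.log(years + 1.0)
        + 0.598 * (years == 0)
    )
    return float(value) if value.ndim == 0 else value


def percentile_score(value, reference) -> float | np.ndarray:
    """Midrank percentile of ``value`` within ``reference``:
    100 * (#strictly below + 0.5 * #equal) / n.  Vectorised over ``value``."""
    ref = np.sort(np.asarray(reference, dtype=float))
    n = ref.size
    if n == 0:
        raise ValidationError("reference sample must be non-empty")
    v = np.asarray(value, dtype=float)
    below = np.searchsorted(ref, v, side="left")
    upto = np.searchsorted(ref, v, side="right")
    pct = 100.0 * (below + 0.5 * (upto - below)) / n
    return float(pct) if pct.ndim == 0 else pct


@dataclasses.dataclass
class ScoreConfig:
    """Allocation-score settings: a pluggable scorer (None = packaged
    surrogate), the national routing threshold and the per-level score base."""

    scorer: Callable | None = None
    national_threshold: int = 54_000_000
    level_base: int = 10_000_000

    def validate(self) -> "ScoreConfig":
        if self.national_threshold <= 0 or self.level_base <= 0:
            raise ValidationError("score thresholds must be positive")
        return self


def match_level(hla_weighted, pra) -> np.ndarray:
    """Match level 0..6 of the surrogate score.

    Level 6 is reserved for zero weighted mismatch, or near-zero mismatch
    (<= 2) in a highly sensitised candidate (PRA >= 80).  Below that the level
    steps down with the weighted mismatch: <=1 -> 5, 2 -> 4, 3-4 -> 3,
    5-6 -> 2, 7 -> 1, 8 -> 0.
    """
    mm = np.asarray(hla_weighted, dtype=float)
    pra = np.asarray(pra, dtype=float)
    ladder = np.select(
        [mm <= 1, mm == 2, mm <= 4, mm <= 6, mm == 7],
        [5, 4, 3, 2, 1],
        default=0,
    )
    level = np.where((mm == 0) | ((mm <= 2) & (pra >= 80)), 6, ladder)
    return level if level.ndim else level[()]


def surrogate_scores(
    days_waited, hla_weighted, pra, config: ScoreConfig | None = None
) -> np.ndarray:
    """Surrogate allocation score: level * level_base + capped waiting days.

    Strictly increasing in waiting time within a level; level 6 clears the
    national threshold.  Plugged-in scorers must preserve that monotonicity.
    """
    config = (config or ScoreConfig()).validate()
    days = np.asarray(days_waited, dtype=float)
    if (days < 0).any():
        raise ValidationError("days_waited must be non-negative")
    level = match_level(hla_weighted, pra)
    score = level * config.level_base + np.minimum(days, config.level_base - 1)
    return score if score.ndim else float(score)


def allocation_score(
    candidate: Mapping,
    donor: Mapping,
    today: datetime.date,
    config: ScoreConfig | None = None,
) -> float:
    """Score one candidate against one donor on ``today``.

    Computes the weighted HLA mismatch from the two tables' typing columns and
    applies the configured scorer (surrogate by default).
    """
    from .cohort import hla_mismatch_counts
    from .decisions import weighted_hla_mismatch

    config = (config or ScoreConfig()).validate()
    listing = candidate["listing_date"]
    if listing > today:
        raise ValidationError(f"candidate listed {listing}, after {today}")
    counts = {}
    for locus, col in (("dr", "hla_dr"), ("a", "hla_a"), ("b", "hla_b")):
        d1, d2 = str(donor[col]).split(";")
        c1, c2 = str(candidate[col]).split(";")
        counts[locus] = int(
            hla_mismatch_counts((d1, d2), np.array([c1], object), np.array([c2], object))[0]
        )
    mm = weighted_hla_mismatch(counts["dr"], counts["a"], counts["b"])
    days = (today - listing).days
    if config.scorer is not None:
        return float(config.scorer(candidate, donor, today))
    return float(surrogate_scores(days, mm, candidate["pra"], config))


def route_tier(score: float, config: ScoreConfig | None = None) -> str:
    """National tier iff score strictly exceeds the threshold; else state."""
    config = (config or ScoreConfig()).validate()
    if score < 0:
        raise ValidationError("score must be non-negative")
    return "national" if score > config.national_threshold else "state"


def geodesic_center(state: str) -> str:
    """Allocation centre of a state; ACT, TAS and NT are served by the
    neighbouring NSW, VIC and SA centres respectively."""
    try:
        return GEODESIC_CENTRE[state]
    except KeyError:
        raise ValidationError(f"unknown state {state!r}") from None


@dataclasses.dataclass
class EligibilityConfig:
    """Eligibility filter: ``default`` (none), ``corisk`` (shared cut-off c%)
    or ``irisk`` (bandwidth s% around the donor's KDPI percentile)."""

    mode: str = "default"
    c: float = 40.0
    s: float = 20.0

    def validate(self) -> "EligibilityConfig":
        if self.mode not in ("default", "corisk", "irisk"):
            raise ValidationError(f"unknown eligibility mode {self.mode!r}")
        if self.mode == "corisk" and not 0 <= self.c <= 100:
            raise ValidationError("eligibility.c must be in [0, 100]")
        if self.mode == "irisk" and not 0 <= self.s <= 100:
            raise ValidationError("eligibility.s must be in [0, 100]")
        return self

    def mask(self, epts_pct: np.ndarray, kdpi_pct: float) -> np.ndarray:
        epts_pct = np.asarray(epts_pct, dtype=float)
        if self.mode == "corisk":
            return corisk_eligible(epts_pct, kdpi_pct, self.c)
        if self.mode == "irisk":
            return irisk_eligible(epts_pct, kdpi_pct, self.s)
        return np.ones_like(epts_pct, dtype=bool)


def corisk_eligible(epts_pct, kdpi_pct, c: float):
    """Cut-off risk matching: low-EPTS candidates (<= c%) pair only with
    low-KDPI donors (<= c%), high with high; boundaries inclusive."""
    e = np.asarray(epts_pct, dtype=float)
    k = np.asarray(kdpi_pct, dtype=float)
    ok = ((e <= c) & (k <= c)) | ((e >= c) & (k >= c))
    return bool(ok) if ok.ndim == 0 else ok


def irisk_eligible(epts_pct, kdpi_pct, s: float):
    """Interval risk matching: eligible iff EPTS% lies in [KDPI%-s, KDPI%+s]."""
    e = np.asarray(epts_pct, dtype=float)
    k = np.asarray(kdpi_pct, dtype=float)
    ok = (e >= k - s) & (e <= k + s)
    return bool(ok) if ok.ndim == 0 else ok


class StateLedger:
    """Per-centre, per-calendar-year counts of donors contributed and
    transplants received, backing the state-balance mechanism."""

    def __init__(self):
        self._donors: dict[tuple[str, int], int] = {}
        self._transplants: dict[tuple[str, int], int] = {}

    def record_donor(self, centre: str, year: int) -> None:
        self._donors[(centre, year)] = self._donors.get((centre, year), 0) + 1

    def record_transplant(self, centre: str, year: int) -> None:
        self._transplants[(centre, year)] = self._transplants.get((centre, year), 0) + 1

    def ratio(self, centre: str, year: int) -> float:
        donors = self._donors.get((centre, year), 0)
        transplants = self._transplants.get((centre, year), 0)
        if transplants == 0:
            return 1.0 if donors == 0 else math.inf
        return donors / transplants

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(set(self._donors) | set(self._transplants))
        rows = [
            {
                "centre": c,
                "year": y,
                "donors": self._donors.get((c, y), 0),
                "transplants": self._transplants.get((c, y), 0),
                "ratio": self.ratio(c, y),
            }
            for c, y in keys
        ]
        return pd.DataFrame(rows, columns=["centre", "year", "donors", "transplants", "ratio"])


def state_balance_target(ledger: StateLedger, donor: Mapping, enabled: bool) -> str:
    """Centre whose state round serves this donor.

    Disabled: the donor's own geodesic centre.  Enabled: if the donor's centre
    has received more donors than transplants this year (ratio > 1), redirect
    to the centre with the smallest donors/transplants ratio (a deficit centre
    if one exists), ties broken alphabetically.
    """
    own = geodesic_center(donor["state"])
    if not enabled:
        return own
    year = donor["donation_date"].year
    if ledger.ratio(own, year) <= 1:
        return own
    return min(CENTRES, key=lambda c: (ledger.ratio(c, year), c))
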
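"""Shared decision-making: recipient selection from a scored candidate list.

Two models of the clinician-patient acceptance step:

* ``sdm0`` deterministically takes the highest-scoring candidate;
* ``sdm1`` walks the candidates in descending score order and, for each, runs
  a nested consideration tree: the four consideration variables (pediatric
  status, donor/recipient quality gap, AB-to-AB blood type, same state) are
  tried in fixed order, and each applicable one triggers a Bernoulli
  acceptance draw with probability

      p_j = (1 - PRA_j / 100) * (1 - HLA_j / z),

  where HLA_j = 2*DR + A + B is the weighted mismatch and z (default 50)
  tunes the mismatch penalty.  The first success matches the donor; if every
  candidate exhausts all four considerations, the kidney goes unallocated.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Columns sdm0/sdm1 expect in the offers table.
OFFER_COLUMNS = (
    "position", "id", "score", "days_waited", "pra", "hla_weighted",
    "alpha1", "alpha2", "alpha3", "alpha4",
)


@dataclasses.dataclass
class AcceptanceConfig:
    """Tunables of the acceptance model.

    ``z``: HLA scaling divisor in p_j (> 0, default 50).  ``alpha2_threshold``
    is the slack in the quality-gap consideration and ``alpha2_mode`` picks
    its scale: ``percentile`` compares EPTS% against KDPI% (applicable when
    EPTS% >= KDPI% - threshold, i.e. the donor is at least as good as the
    candidate's standing); ``raw`` uses raw EPTS minus KDRI.
    """

    z: float = 50.0
    alpha2_threshold: float = 0.0
    alpha2_mode: str = "percentile"

    def validate(self) -> "AcceptanceConfig":
        if self.z <= 0:
            raise ValidationError("acceptance.z must be positive")
        if self.alpha2_mode not in ("percentile", "raw"):
            raise ValidationError(f"unknown alpha2_mode {self.alpha2_mode!r}")
        return self


@dataclasses.dataclass
class ConsiderationFlags:
    """Applicability of the four considerations, evaluated in order 1 -> 4."""

    alpha1: bool  # pediatric candidate with a donor within 30 years of age
    alpha2: bool  # donor quality at least matches the candidate's standing
    alpha3: bool  # AB candidate offered an AB kidney
    alpha4: bool  # donor and candidate reside in the same state
    alpha2_value: float = 0.0  # the underlying quality gap

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.alpha1, self.alpha2, self.alpha3, self.alpha4)


def weighted_hla_mismatch(dr: int, a: int, b: int) -> int:
    """Weighted mismatch 2*DR + A + B; each locus count must be 0, 1 or 2."""
    for name, count in (("dr", dr), ("a", a), ("b", b)):
        if count not in (0, 1, 2):
            raise ValidationError(f"HLA {name} mismatch count {count!r} not in {{0, 1, 2}}")
    return 2 * dr + a + b


def acceptance_probability(pra: float, hla_weighted: float, z: float = 50.0) -> float:
    """p_j = (1 - PRA/100) * (1 - HLA/z), with the mismatch factor clamped at
    zero so the product stays a probability."""
    if not 0 <= pra <= 100:
        raise ValidationError("pra must be in [0, 100]")
    if hla_weighted < 0:
        raise ValidationError("hla_weighted must be non-negative")
    if z <= 0:
        raise ValidationError("z must be positive")
    return (1.0 - pra / 100.0) * max(0.0, 1.0 - hla_weighted / z)


def consideration_flags(
    candidate: Mapping,
    donor: Mapping,
    epts_pct: float,
    kdpi_pct: float,
    config: AcceptanceConfig | None = None,
) -> ConsiderationFlags:
    """Evaluate the four consideration variables for one candidate-donor pair."""
    config = (config or AcceptanceConfig()).validate()
    alpha1 = candidate["age"] < 18 and abs(candidate["age"] - donor["age"]) < 30
    if config.alpha2_mode == "percentile":
        gap = epts_pct - kdpi_pct
    else:
        from .rules import raw_epts

        years = candidate.get("years_on_dialysis", 0.0)
        gap = raw_epts(candidate["age"], candidate["prior_kidney_transplant"], years) - donor["kdri"]
    alpha2 = gap >= -config.alpha2_threshold
    alpha3 = candidate["blood_group"] == "AB" and donor["blood_group"] == "AB"
    alpha4 = candidate["state"] == donor["state"]
    return ConsiderationFlags(bool(alpha1), bool(alpha2), bool(alpha3), bool(alpha4), float(gap))


def _order(offers: pd.DataFrame) -> pd.DataFrame:
    """Descending score; ties broken by longer waiting time, then id."""
    return offers.sort_values(
        ["score", "days_waited", "id"], ascending=[False, False, True], kind="mergesort"
    )


def sdm0_select(offers: pd.DataFrame):
    """Maximum-score selection: the top candidate, or None on an empty list."""
    if len(offers) == 0:
        return None
    return _order(offers).iloc[0]


def sdm1_select(
    offers: pd.DataFrame,
    config: AcceptanceConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Nested-tree selection with Bernoulli acceptance.

    Candidates are visited in descending score order.  For candidate j with
    acceptance probability p_j, each applicable consideration (order 1 -> 4)
    triggers one Bernoulli(p_j) draw; the first success returns
    ``(candidate row, firing consideration index)``.  Returns ``(None, None)``
    if no candidate accepts.  Non-applicable considerations consume no
    randomness, so draw counts are reproducible for a given rng stream.
    """
    config = (config or AcceptanceConfig()).validate()
    if rng is None:
        rng = np.random.default_rng(0)
    for _, row in _order(offers).iterrows():
        p = acceptance_probability(row["pra"], row["hla_weighted"], config.z)
        for i, applicable in enumerate(
            (row["alpha1"], row["alpha2"], row["alpha3"], row["alpha4"]), start=1
        ):
            if applicable and rng.random() < p:
                return row, i
    return None, None
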
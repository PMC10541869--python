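"""Synthetic cohort generation and delimited-text I/O.

The simulator consumes two tables: a candidate table (one row per potential
transplant recipient) and a donor table (one row per deceased donor).  The
registry data the method was developed on is access-restricted, so this module
generates cohorts with the same schema from configurable marginal
distributions; every field a downstream module consumes (EPTS inputs, HLA
typing, comorbidity flags) is producible here.

Fields are sampled independently from their marginals.  HLA typing is stored
as two antigen labels per locus (A, B, DR), semicolon-joined in CSV.  Dates
are ISO-8601 calendar dates; simulation time advances in whole days.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import SchemaError, ValidationError

BLOOD_GROUPS = ("O", "A", "B", "AB")
STATES = ("NSW", "ACT", "VIC", "TAS", "WA", "SA", "NT", "QLD")
HLA_LOCI = ("A", "B", "DR")
COMORBIDITIES = (
    "lung_disease",
    "smoking",
    "diabetes",
    "cardiovascular_disease",
    "cancer",
)

CANDIDATE_COLUMNS = (
    "id",
    "age",
    "sex",
    "blood_group",
    "state",
    "pra",
    "hla_a",
    "hla_b",
    "hla_dr",
    "listing_date",
    "dialysis_start_date",
    "prior_kidney_transplant",
) + COMORBIDITIES

DONOR_COLUMNS = (
    "id",
    "age",
    "blood_group",
    "state",
    "kdri",
    "donation_date",
    "hla_a",
    "hla_b",
    "hla_dr",
)

# Stratification bands shared by the waiting-list sampler and the comparison
# report.  Upper edges are exclusive except the last.
AGE_BAND_EDGES = (0, 18, 45, 65, 200)
AGE_BAND_LABELS = ("<18", "18-44", "45-64", "65+")
PRA_BAND_EDGES = (0, 10, 50, 80, 101)
PRA_BAND_LABELS = ("0-9", "10-49", "50-79", "80-100")


def age_band(ages) -> np.ndarray:
    """Label ages with the standard bands (<18, 18-44, 45-64, 65+)."""
    idx = np.digitize(np.asarray(ages, dtype=float), AGE_BAND_EDGES[1:-1])
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def pra_band(pras) -> np.ndarray:
    """Label PRA percentages with the sensitisation bands."""
    idx = np.digitize(np.asarray(pras, dtype=float), PRA_BAND_EDGES[1:-1])
    return np.asarray(PRA_BAND_LABELS, dtype=object)[idx]


def _check_distribution(name: str, dist: Mapping[str, float]) -> None:
    total = 0.0
    for key, p in dist.items():
        if p < 0:
            raise ValidationError(f"marginals.{name}: negative frequency for {key!r}")
        total += float(p)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"marginals.{name}: frequencies sum to {total}, not 1")


def _check_bands(name: str, bands: Sequence[Sequence[float]]) -> None:
    total = 0.0
    for band in bands:
        if len(band) != 3:
            raise ValidationError(f"marginals.{name}: bands must be [low, high, p]")
        lo, hi, p = band
        if hi < lo:
            raise ValidationError(f"marginals.{name}: band {band} has high < low")
        if p < 0:
            raise ValidationError(f"marginals.{name}: negative band probability")
        total += float(p)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"marginals.{name}: band probabilities sum to {total}, not 1")


@dataclasses.dataclass
class CohortMarginals:
    """Target marginal distributions for the synthetic cohort.

    Categorical distributions must sum to one (within 1e-9) with non-negative
    frequencies; band lists are ``[low, high, probability]`` triples with the
    value drawn uniformly inside its band.
    """

    age_bands: Sequence[Sequence[float]]
    sex: Mapping[str, float]
    blood_group: Mapping[str, float]
    state: Mapping[str, float]
    pra_bands: Sequence[Sequence[float]]
    comorbidities: Mapping[str, float]
    prior_transplant_rate: float
    dialysis_fraction: float
    dialysis_years_mean: float
    kdri_log_mu: float
    kdri_log_sigma: float
    donor_age_mean: float
    donor_age_sd: float
    donor_age_range: Sequence[float]
    hla_pools: Mapping[str, Mapping[str, float]]

    def validate(self) -> "CohortMarginals":
        _check_bands("age_bands", self.age_bands)
        _check_bands("pra_bands", self.pra_bands)
        _check_distribution("sex", self.sex)
        _check_distribution("blood_group", self.blood_group)
        _check_distribution("state", self.state)
        for bg in self.blood_group:
            if bg not in BLOOD_GROUPS:
                raise ValidationError(f"marginals.blood_group: unknown group {bg!r}")
        for st in self.state:
            if st not in STATES:
                raise ValidationError(f"marginals.state: unknown state {st!r}")
        for name, prev in self.comorbidities.items():
            if not 0 <= prev <= 1:
                raise ValidationError(f"marginals.comorbidities.{name}: prevalence outside [0, 1]")
        for rate_name in ("prior_transplant_rate", "dialysis_fraction"):
            rate = getattr(self, rate_name)
            if not 0 <= rate <= 1:
                raise ValidationError(f"marginals.{rate_name}: outside [0, 1]")
        if self.dialysis_years_mean < 0:
            raise ValidationError("marginals.dialysis_years_mean: negative")
        if self.kdri_log_sigma < 0:
            raise ValidationError("marginals.kdri_log_sigma: negative")
        for locus in HLA_LOCI:
            if locus not in self.hla_pools:
                raise ValidationError(f"marginals.hla_pools: missing locus {locus!r}")
            _check_distribution(f"hla_pools.{locus}", self.hla_pools[locus])
        return self

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortMarginals":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValidationError(f"marginals: unknown keys {sorted(unknown)}")
        missing = fields - set(data)
        if missing:
            raise ValidationError(f"marginals: missing keys {sorted(missing)}")
        return cls(**{k: data[k] for k in fields}).validate()

    @classmethod
    def default(cls) -> "CohortMarginals":
        from .config import packaged_defaults

        return cls.from_dict(packaged_defaults()["marginals"])


def _sample_banded(rng: np.random.Generator, bands, n: int) -> np.ndarray:
    """Draw n values: pick a band by probability, then uniform within it."""
    bands = [(float(lo), float(hi), float(p)) for lo, hi, p in bands]
    probs = np.array([b[2] for b in bands])
    idx = rng.choice(len(bands), size=n, p=probs / probs.sum())
    lows = np.array([b[0] for b in bands])[idx]
    highs = np.array([b[1] for b in bands])[idx]
    return lows + rng.random(n) * (highs - lows)


def _sample_categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    cats = np.asarray(list(dist.keys()), dtype=object)
    probs = np.array([float(p) for p in dist.values()])
    return cats[rng.choice(len(cats), size=n, p=probs / probs.sum())]


def _sample_hla(rng: np.random.Generator, pool: Mapping[str, float], n: int) -> np.ndarray:
    """Two alleles per person, semicolon-joined in a stable (sorted) order."""
    a1 = _sample_categorical(rng, pool, n)
    a2 = _sample_categorical(rng, pool, n)
    return np.array([";".join(sorted((x, y))) for x, y in zip(a1, a2)], dtype=object)


def _uniform_dates(
    rng: np.random.Generator, start: datetime.date, end: datetime.date, n: int
) -> np.ndarray:
    ords = rng.integers(start.toordinal(), end.toordinal() + 1, size=n)
    return np.array([datetime.date.fromordinal(int(o)) for o in ords], dtype=object)


def generate_candidates(
    n: int,
    marginals: CohortMarginals | None = None,
    seed: int = 0,
    listing_start: datetime.date = datetime.date(2008, 1, 1),
    listing_end: datetime.date = datetime.date(2009, 12, 31),
) -> pd.DataFrame:
    """Generate ``n`` synthetic waiting-list candidates.

    Each field is drawn independently from its marginal; HLA alleles come from
    the per-locus pools.  Deterministic given (n, marginals, seed).  Listing
    dates are uniform over [listing_start, listing_end]; the waiting-list
    module overwrites them when a candidate actually arrives.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    marginals = (marginals or CohortMarginals.default()).validate()
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in CANDIDATE_COLUMNS})
    rng = substream(seed, "candidates")

    age = np.round(_sample_banded(rng, marginals.age_bands, n), 1)
    pra = np.round(np.clip(_sample_banded(rng, marginals.pra_bands, n), 0, 100), 1)
    listing = _uniform_dates(rng, listing_start, listing_end, n)

    on_dialysis = rng.random(n) < marginals.dialysis_fraction
    years = rng.exponential(marginals.dialysis_years_mean, size=n)
    dialysis_start = np.array(
        [
            ld - datetime.timedelta(days=int(round(y * 365.25))) if on else None
            for ld, y, on in zip(listing, years, on_dialysis)
        ],
        dtype=object,
    )

    frame = pd.DataFrame(
        {
            "id": [f"C{i:06d}" for i in range(n)],
            "age": age,
            "sex": _sample_categorical(rng, marginals.sex, n),
            "blood_group": _sample_categorical(rng, marginals.blood_group, n),
            "state": _sample_categorical(rng, marginals.state, n),
            "pra": pra,
            "hla_a": _sample_hla(rng, marginals.hla_pools["A"], n),
            "hla_b": _sample_hla(rng, marginals.hla_pools["B"], n),
            "hla_dr": _sample_hla(rng, marginals.hla_pools["DR"], n),
            "listing_date": listing,
            "dialysis_start_date": dialysis_start,
            "prior_kidney_transplant": rng.random(n) < marginals.prior_transplant_rate,
        }
    )
    for name in COMORBIDITIES:
        frame[name] = rng.random(n) < marginals.comorbidities[name]
    return frame[list(CANDIDATE_COLUMNS)]


def generate_donors(
    n: int,
    marginals: CohortMarginals | None = None,
    seed: int = 0,
    start_date: datetime.date = datetime.date(2010, 1, 1),
    end_date: datetime.date = datetime.date(2012, 12, 31),
) -> pd.DataFrame:
    """Generate ``n`` synthetic deceased donors with donation dates uniform
    over [start_date, end_date] and lognormal KDRI (1.0 = reference donor)."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    if end_date < start_date:
        raise ValidationError("start_date must be on or before end_date")
    marginals = (marginals or CohortMarginals.default()).validate()
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in DONOR_COLUMNS})
    rng = substream(seed, "donors")

    lo, hi = marginals.donor_age_range
    age = np.round(
        np.clip(rng.normal(marginals.donor_age_mean, marginals.donor_age_sd, n), lo, hi), 1
    )
    kdri = np.exp(rng.normal(marginals.kdri_log_mu, marginals.kdri_log_sigma, n))
    frame = pd.DataFrame(
        {
            "id": [f"D{i:06d}" for i in range(n)],
            "age": age,
            "blood_group": _sample_categorical(rng, marginals.blood_group, n),
            "state": _sample_categorical(rng, marginals.state, n),
            "kdri": kdri,
            "donation_date": _uniform_dates(rng, start_date, end_date, n),
            "hla_a": _sample_hla(rng, marginals.hla_pools["A"], n),
            "hla_b": _sample_hla(rng, marginals.hla_pools["B"], n),
            "hla_dr": _sample_hla(rng, marginals.hla_pools["DR"], n),
        }
    )
    return frame[list(DONOR_COLUMNS)]


_DATE_COLUMNS = ("listing_date", "dialysis_start_date", "donation_date")
_BOOL_COLUMNS = ("prior_kidney_transplant",) + COMORBIDITIES


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a candidate or donor table as UTF-8 CSV (dates ISO-8601)."""
    out = table.copy()
    for col in _DATE_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda d: "" if d is None or pd.isna(d) else d.isoformat())
    out.to_csv(path, index=False)


def _parse_date_column(series: pd.Series, col: str, required: bool) -> pd.Series:
    parsed = []
    for row, value in enumerate(series):
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            if required:
                raise SchemaError(f"column {col!r}, row {row}: missing date")
            parsed.append(None)
            continue
        try:
            parsed.append(datetime.date.fromisoformat(str(value)))
        except ValueError as exc:
            raise SchemaError(f"column {col!r}, row {row}: unparseable date {value!r}") from exc
    return pd.Series(parsed, index=series.index, dtype=object)


def read_cohort(path) -> pd.DataFrame:
    """Read a candidate or donor CSV, validating schema and domains.

    The table kind is inferred from its columns.  Raises :class:`SchemaError`
    for a missing column or an unparseable date (naming the row), and
    :class:`ValidationError` for out-of-domain values (PRA outside [0, 100],
    unknown blood group or state, non-positive KDRI).
    """
    frame = pd.read_csv(path, dtype={"id": str})
    is_donor = "donation_date" in frame.columns or "kdri" in frame.columns
    required = DONOR_COLUMNS if is_donor else CANDIDATE_COLUMNS
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    for col in _DATE_COLUMNS:
        if col in frame.columns:
            frame[col] = _parse_date_column(
                frame[col], col, required=(col != "dialysis_start_date")
            )
    for col in _BOOL_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].map(
                lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip() == "True"
            )
    bad_bg = set(frame["blood_group"]) - set(BLOOD_GROUPS)
    if bad_bg:
        raise ValidationError(f"unknown blood group(s) {sorted(bad_bg)}")
    bad_state = set(frame["state"]) - set(STATES)
    if bad_state:
        raise ValidationError(f"unknown state(s) {sorted(bad_state)}")
    if not is_donor:
        pra = frame["pra"].astype(float)
        if ((pra < 0) | (pra > 100)).any():
            row = int(np.argmax((pra < 0) | (pra > 100)))
            raise ValidationError(f"pra out of range [0, 100] at row {row}")
    else:
        kdri = frame["kdri"].astype(float)
        if (kdri <= 0).any():
            row = int(np.argmax((kdri <= 0).to_numpy()))
            raise ValidationError(f"kdri must be positive; violated at row {row}")
    return frame[list(required)]


def split_alleles(column: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Split a semicolon-joined HLA column into two allele arrays."""
    parts = column.str.split(";", expand=True)
    return parts[0].to_numpy(dtype=object), parts[1].to_numpy(dtype=object)


def hla_mismatch_counts(
    donor_alleles: tuple[str, str], cand_a1: np.ndarray, cand_a2: np.ndarray
) -> np.ndarray:
    """Donor->recipient mismatch at one locus, vectorised over candidates.

    The count is the number of donor alleles (with multiplicity, max 2) absent
    from the recipient's two alleles at that locus.
    """
    d1, d2 = donor_alleles
    miss1 = (cand_a1 != d1) & (cand_a2 != d1)
    miss2 = (cand_a1 != d2) & (cand_a2 != d2)
    return miss1.astype(int) + miss2.astype(int)
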
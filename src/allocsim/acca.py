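"""Allocation Characteristics Comparison Analysis (ACCA).

Compares two sets of allocation records — typically simulated against actual
— on three characteristics: the national:state allocation ratio, recipient
waiting times, and the distribution of transplants across state centres.  Per
characteristic it reports raw differences, the Hellinger distance between
categorical distributions, the two-sample Kolmogorov-Smirnov statistic, the
absolute difference in Pearson (non-excess) kurtosis, and stratified median
|log(actual/simulated)| waiting-time tables by state centre, age band, EPTS
band, PRA band and blood group.  An aggregate dissimilarity score in [0, 1]
averages the normalised components (smaller = closer agreement).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import age_band, pra_band
from .errors import ValidationError
from .rules import percentile_score, raw_epts

STRATA = ("centre", "age_band", "epts_band", "pra_band", "blood_group")


def hellinger(p, q) -> float:
    """Hellinger distance between two categorical distributions on a shared
    support: (1/sqrt(2)) * sqrt(sum (sqrt(p_i) - sqrt(q_i))^2), in [0, 1].

    Accepts aligned arrays or dicts keyed by category (keys must coincide).
    """
    if isinstance(p, Mapping) or isinstance(q, Mapping):
        if not (isinstance(p, Mapping) and isinstance(q, Mapping)):
            raise ValidationError("p and q must both be mappings or both arrays")
        if set(p) != set(q):
            raise ValidationError("mismatched supports")
        keys = sorted(p)
        p = np.array([p[k] for k in keys], dtype=float)
        q = np.array([q[k] for k in keys], dtype=float)
    else:
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        if p.shape != q.shape:
            raise ValidationError("mismatched supports")
    for name, vec in (("p", p), ("q", q)):
        if (vec < 0).any():
            raise ValidationError(f"{name} has negative mass")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} sums to {vec.sum()}, not 1")
    return float(np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)) / np.sqrt(2.0))


def ks_stat(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_t |ECDF_x(t) - ECDF_y(t)|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("samples must be non-empty")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def kurtosis_diff(x, y) -> float:
    """|k(x) - k(y)| with k the Pearson (non-excess) sample kurtosis m4/m2^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, s in (("x", x), ("y", y)):
        if s.size < 4:
            raise ValidationError(f"{name} needs >= 4 points")
        if np.var(s) == 0:
            raise ValidationError(f"{name} has zero variance; kurtosis undefined")
    kx = stats.kurtosis(x, fisher=False, bias=True)
    ky = stats.kurtosis(y, fisher=False, bias=True)
    return float(abs(kx - ky))


def national_state_ratio(records: pd.DataFrame) -> tuple[float, float]:
    """(national, state) proportions over matched records only."""
    matched = records[records["recipient_id"].notna()]
    if len(matched) == 0:
        raise ValidationError("no matched records")
    national = float((matched["tier"] == "national").mean())
    return national, 1.0 - national


def median_log_ratio(actual_median: float, simulated_median: float) -> float:
    """|ln(actual/simulated)|; zero iff the medians agree."""
    if actual_median <= 0 or simulated_median <= 0:
        raise ValidationError("medians must be positive")
    return float(abs(np.log(actual_median / simulated_median)))


def dissimilarity_score(bounded: Sequence[float] = (), unbounded: Sequence[float] = ()) -> float:
    """Unweighted mean of normalised components.

    ``bounded`` components (Hellinger, KS) already live in [0, 1];
    ``unbounded`` non-negative components (log-ratios, kurtosis differences)
    are squashed through 1 - exp(-x).  This aggregation is a declared design
    choice and deliberately isolated so alternatives can be swapped in.
    """
    parts = [float(v) for v in bounded]
    parts += [1.0 - float(np.exp(-float(v))) for v in unbounded]
    if not parts:
        raise ValidationError("at least one component required")
    return float(np.mean(parts))


def _category_distributions(a: pd.Series, b: pd.Series) -> tuple[dict, dict]:
    support = sorted(set(a) | set(b))
    pa = a.value_counts(normalize=True)
    pb = b.value_counts(normalize=True)
    return (
        {k: float(pa.get(k, 0.0)) for k in support},
        {k: float(pb.get(k, 0.0)) for k in support},
    )


def _strata_labels(records: pd.DataFrame, candidates: pd.DataFrame) -> pd.DataFrame:
    """Attach the five stratification variables to matched records."""
    cand = candidates.set_index("id")
    merged = records[records["recipient_id"].notna()].copy()
    attrs = cand.loc[merged["recipient_id"]]
    years = np.array(
        [
            max((ld - dd).days, 0) / 365.25 if dd is not None and not pd.isna(dd) else 0.0
            for ld, dd in zip(attrs["listing_date"], attrs["dialysis_start_date"])
        ]
    )
    epts_raw = raw_epts(
        attrs["age"].to_numpy(dtype=float),
        attrs["prior_kidney_transplant"].to_numpy(dtype=bool),
        years,
    )
    ref_years = np.array(
        [
            max((ld - dd).days, 0) / 365.25 if dd is not None and not pd.isna(dd) else 0.0
            for ld, dd in zip(candidates["listing_date"], candidates["dialysis_start_date"])
        ]
    )
    ref = np.sort(
        raw_epts(
            candidates["age"].to_numpy(dtype=float),
            candidates["prior_kidney_transplant"].to_numpy(dtype=bool),
            ref_years,
        )
    )
    epts_pct = percentile_score(epts_raw, ref)
    merged["age_band"] = age_band(attrs["age"].to_numpy(dtype=float))
    merged["pra_band"] = pra_band(attrs["pra"].to_numpy(dtype=float))
    merged["blood_group"] = attrs["blood_group"].to_numpy(dtype=object)
    merged["epts_band"] = pd.cut(
        epts_pct, bins=[0, 20, 40, 60, 80, 100.0001], include_lowest=True,
        labels=["0-20", "20-40", "40-60", "60-80", "80-100"],
    ).astype(object)
    return merged


def _stratified_table(actual: pd.DataFrame, simulated: pd.DataFrame, var: str) -> pd.DataFrame:
    med_a = actual.groupby(var)["waiting_time_days"].median()
    med_s = simulated.groupby(var)["waiting_time_days"].median()
    rows = []
    for cat in sorted(set(med_a.index) | set(med_s.index), key=str):
        ma = med_a.get(cat, np.nan)
        ms = med_s.get(cat, np.nan)
        ok = ma > 0 and ms > 0
        rows.append(
            {
                "category": cat,
                "actual_median": float(ma) if not pd.isna(ma) else np.nan,
                "simulated_median": float(ms) if not pd.isna(ms) else np.nan,
                "abs_log_ratio": median_log_ratio(ma, ms) if ok else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ComparisonReport:
    """ACCA output: per-characteristic metrics, optional stratified tables,
    and the aggregate dissimilarity score (kurtosis convention: Pearson)."""

    characteristics: dict
    stratified: dict
    aggregate: float

    def to_dict(self) -> dict:
        return {
            "kurtosis_convention": "pearson (non-excess)",
            "characteristics": self.characteristics,
            "stratified": {
                var: table.to_dict(orient="records") for var, table in self.stratified.items()
            },
            "aggregate_dissimilarity": self.aggregate,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=str, **kwargs)


def compare_records(
    actual: pd.DataFrame,
    simulated: pd.DataFrame,
    candidates: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Build the full ACCA report for two MatchRecord tables.

    ``candidates`` (a candidate table covering the recipients) enables the
    stratified waiting-time tables; without it only the three top-level
    characteristics are compared.
    """
    nat_a, _ = national_state_ratio(actual)
    nat_s, _ = national_state_ratio(simulated)
    wait_a = actual.loc[actual["recipient_id"].notna(), "waiting_time_days"].to_numpy(dtype=float)
    wait_s = simulated.loc[simulated["recipient_id"].notna(), "waiting_time_days"].to_numpy(dtype=float)
    med_a, med_s = float(np.median(wait_a)), float(np.median(wait_s))
    centre_a, centre_s = _category_distributions(
        actual.loc[actual["recipient_id"].notna(), "centre"],
        simulated.loc[simulated["recipient_id"].notna(), "centre"],
    )

    characteristics = {
        "national_state": {
            "actual_national": nat_a,
            "simulated_national": nat_s,
            "difference": abs(nat_a - nat_s),
            "hellinger": hellinger([nat_a, 1 - nat_a], [nat_s, 1 - nat_s]),
        },
        "waiting_time": {
            "actual_median": med_a,
            "simulated_median": med_s,
            "difference": abs(med_a - med_s),
            "median_abs_log_ratio": (
                median_log_ratio(med_a, med_s) if med_a > 0 and med_s > 0 else np.nan
            ),
            "ks": ks_stat(wait_a, wait_s),
            "kurtosis_diff": (
                kurtosis_diff(wait_a, wait_s)
                if min(wait_a.size, wait_s.size) >= 4
                and np.var(wait_a) > 0
                and np.var(wait_s) > 0
                else np.nan
            ),
        },
        "state_percentages": {
            "actual": centre_a,
            "simulated": centre_s,
            "difference_tv": 0.5
            * float(sum(abs(centre_a[k] - centre_s[k]) for k in centre_a)),
            "hellinger": hellinger(centre_a, centre_s),
        },
    }

    stratified = {}
    if candidates is not None:
        lab_a = _strata_labels(actual, candidates)
        lab_s = _strata_labels(simulated, candidates)
        for var in STRATA:
            stratified[var] = _stratified_table(lab_a, lab_s, var)

    bounded = [
        characteristics["national_state"]["hellinger"],
        characteristics["waiting_time"]["ks"],
        characteristics["state_percentages"]["hellinger"],
    ]
    unbounded = []
    for key in ("median_abs_log_ratio", "kurtosis_diff"):
        v = characteristics["waiting_time"][key]
        if not pd.isna(v):
            unbounded.append(v)
    aggregate = dissimilarity_score(bounded, unbounded)
    return ComparisonReport(characteristics, stratified, aggregate)
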
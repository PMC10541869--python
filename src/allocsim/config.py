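"""Configuration loading: packaged defaults, YAML/JSON files, overrides.

One packaged file (``data/defaults.yaml``) is the single source of truth for
every default — the queueing rates, list sizes, the national threshold, the
acceptance divisor z, the synthetic-cohort marginals and the exit-risk
coefficients.  User files and programmatic overrides are deep-merged over it
(override > file > default); unknown keys are rejected by name.
"""

from __future__ import annotations

import copy
import dataclasses
import datetime
import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .cohort import CohortMarginals
from .decisions import AcceptanceConfig
from .engine import RunConfig
from .errors import ConfigError
from .rules import EligibilityConfig, ScoreConfig
from .waitlist import DynamicsConfig

# Sections whose sub-keys form a closed set (checked against the defaults).
_CLOSED_SECTIONS = ("dynamics", "score", "eligibility", "acceptance", "engine", "cohort")
# Sections with free-form sub-keys (validated downstream by their own types).
_OPEN_SECTIONS = ("marginals", "exit_scorer")


@lru_cache(maxsize=1)
def _defaults_raw() -> dict:
    text = resources.files("allocsim").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def packaged_defaults() -> dict:
    """A fresh copy of the packaged default configuration tree."""
    return copy.deepcopy(_defaults_raw())


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _check_keys(merged: Mapping, defaults: Mapping) -> None:
    unknown = set(merged) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    for section in _CLOSED_SECTIONS:
        sub = merged.get(section) or {}
        if not isinstance(sub, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        extra = set(sub) - set(defaults[section])
        if extra:
            raise ConfigError(f"unknown key(s) in {section!r}: {sorted(extra)}")
    for section in _OPEN_SECTIONS:
        if section in merged and not isinstance(merged[section], Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")


def _as_date(value, name: str):
    if value is None or isinstance(value, datetime.date):
        return value
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigError(f"{name}: unparseable date {value!r}") from exc


@dataclasses.dataclass
class CohortSettings:
    """Sizes and calendar window of the generated cohort."""

    n_candidates: int
    n_donors: int
    start_date: datetime.date
    end_date: datetime.date


@dataclasses.dataclass
class FullConfig:
    """A fully resolved configuration: run settings plus cohort generation."""

    run: RunConfig
    cohort: CohortSettings
    marginals: CohortMarginals
    exit_coefficients: dict
    raw: dict  # the merged tree the config was built from (manifest snapshot)

    @property
    def seed(self) -> int:
        return self.run.seed


def _build(merged: dict) -> FullConfig:
    from .errors import ValidationError

    dyn = merged["dynamics"]
    eng = merged["engine"]
    coh = merged["cohort"]
    try:
        dynamics = DynamicsConfig(
            n0=int(dyn["n0"]),
            lambda_in=float(dyn["lambda_in"]),
            lambda_out=float(dyn["lambda_out"]),
            k_in={int(y): float(v) for y, v in (dyn["k_in"] or {}).items()},
            k_out={int(y): float(v) for y, v in (dyn["k_out"] or {}).items()},
            strata_targets=dyn["strata_targets"],
            reentry_prob=float(dyn["reentry_prob"]),
            start_date=_as_date(dyn["start_date"], "dynamics.start_date"),
        ).validate()
        score = ScoreConfig(
            national_threshold=int(merged["score"]["national_threshold"]),
            level_base=int(merged["score"]["level_base"]),
        ).validate()
        eligibility = EligibilityConfig(
            mode=str(merged["eligibility"]["mode"]),
            c=float(merged["eligibility"]["c"]),
            s=float(merged["eligibility"]["s"]),
        ).validate()
        acceptance = AcceptanceConfig(
            z=float(merged["acceptance"]["z"]),
            alpha2_threshold=float(merged["acceptance"]["alpha2_threshold"]),
            alpha2_mode=str(merged["acceptance"]["alpha2_mode"]),
        ).validate()
        rounds = tuple(tuple(r) for r in eng["rounds"])
        run = RunConfig(
            process=str(eng["process"]),
            donor_sample_size=int(eng["donor_sample_size"]),
            dynamics=dynamics,
            score=score,
            eligibility=eligibility,
            acceptance=acceptance,
            decision_model=eng["decision_model"],
            dynamic_waitlist=eng["dynamic_waitlist"],
            state_balance=bool(eng["state_balance"]),
            waiting_time_from=str(eng["waiting_time_from"]),
            rounds=rounds,
            seed=int(merged["seed"]),
            replications=int(eng["replications"]),
            workers=int(eng["workers"]),
        ).resolved()
        cohort = CohortSettings(
            n_candidates=int(coh["n_candidates"]),
            n_donors=int(coh["n_donors"]),
            start_date=_as_date(coh["start_date"], "cohort.start_date"),
            end_date=_as_date(coh["end_date"], "cohort.end_date"),
        )
        if cohort.end_date < cohort.start_date:
            raise ConfigError("cohort.start_date must be on or before cohort.end_date")
        marginals = CohortMarginals.from_dict(merged["marginals"])
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    return FullConfig(
        run=run,
        cohort=cohort,
        marginals=marginals,
        exit_coefficients=dict(merged["exit_scorer"]["coefficients"]),
        raw=merged,
    )


def parse_config(path=None, overrides: Mapping | None = None) -> FullConfig:
    """Resolve a configuration from the packaged defaults, an optional YAML or
    JSON file, and an optional override mapping (highest precedence)."""
    merged = packaged_defaults()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"configuration root must be a mapping: {path}")
        _check_keys(_deep_merge(merged, data), _defaults_raw())
        merged = _deep_merge(merged, data)
    if overrides:
        _check_keys(_deep_merge(merged, overrides), _defaults_raw())
        merged = _deep_merge(merged, overrides)
    return _build(merged)
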
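# Methods

This note documents the models implemented in `allocsim`, the defaults and
their rationale, the numerical conventions, and what the synthetic-data tests
do and do not establish about real allocation data.

## Waiting-list model (Phase A)

The waiting list is a continuous-admission queue advanced in whole days.

* **Initialisation.** `n0` candidates (default 300) are drawn from a
  reservoir pool without replacement. Stratified sampling uses importance
  weights `target(stratum) / pool(stratum)` over four variables — age band
  (<18, 18–44, 45–64, 65+), blood group, state, PRA band (0–9, 10–49, 50–79,
  80–100) — so realised list composition approximates the configured
  targets. Target mass on strata absent from the pool is renormalised over
  the non-empty strata with a warning.
* **Arrivals.** Daily count ~ Poisson(`k_in(t)·λ_in`), default `λ_in = 0.7`
  per day. Arriving candidates are drawn from the pool with the same
  importance weights; their listing date is set to the arrival day.
* **Departures.** Daily count ~ Poisson(`k_out(t)·λ_out`), default
  `λ_out = 0.4` per day. Every active candidate is scored by the exit-risk
  scorer and the highest-risk `n_out` are removed. Ties break by earlier
  listing date, then id — a deterministic total order.
* **Rate schedules.** `k_in`, `k_out` are piecewise-constant multipliers
  keyed by calendar year (missing years = 1), capturing yearly flux in
  arrival and departure pressure.
* **Interim-list semantics.** Departure is permanent by default. Because
  exits are often temporary in practice (acute illness, hospitalisation), a
  per-day re-entry probability (`reentry_prob`, default 0) can return
  departed candidates to the pool.

**Exit-risk scorer.** The departure mechanism needs only a ranking, so the
scorer is a contract: any callable mapping a candidate frame and a date to
finite scores (higher = leaves sooner). The default is a logistic-linear
model over age, sex, five comorbidity flags, PRA, years on dialysis at the
scoring date, and blood-group/state category effects. The packaged
coefficients are a documented, order-of-magnitude clinical prior (e.g.
cancer > cardiovascular disease > smoking), not estimates; they are expected
to be replaced when fitting data exist. Only seven of the intended features
have an external provenance; the remainder (PRA band, blood group, state,
dialysis years) are configurable choices, not canonical.

**Seeding.** Every day draws from a substream keyed by (master seed,
purpose, date). Consequences: advancing 40 days in one call or in two is
*bit-identical*, not merely equal in distribution; and fixed seeds reproduce
event logs exactly.

## Allocation rule (Phase B)

* **Two tiers.** Scores strictly above 54,000,000 route to the national
  tier; all others to the state tier of the donor's geodesic centre
  (ACT→NSW, TAS→VIC, NT→SA; the five centres are NSW/ACT, VIC/TAS, WA,
  SA/NT, QLD).
* **Surrogate score.** The guideline national/state scoring tables are
  external and not published in closed form; the shipped surrogate is
  `level · 10⁷ + min(days waited, 10⁷ − 1)`, where level ∈ {0..6} is a
  function of the weighted HLA mismatch `m = 2·DR + A + B` and PRA:
  level 6 iff `m = 0` or (`m ≤ 2` and PRA ≥ 80); otherwise
  `m ≤ 1 → 5`, `m = 2 → 4`, `m ≤ 4 → 3`, `m ≤ 6 → 2`, `m = 7 → 1`,
  `m = 8 → 0`. The surrogate preserves the two properties the architecture
  needs — strict monotonicity in waiting time within a level, and top-level
  scores clearing the national threshold — and sits behind a pluggable
  interface (`ScoreConfig.scorer`) so real formulas can be supplied.
* **Rounds.** Default sequence: national/ABO-strict, state/ABO-strict,
  national/ABO-compatible (configurable). The second national round reuses
  the scores of the first and is restricted to nationally routed candidates,
  keeping the record invariant "national tier ⇒ score > threshold". ABO
  compatibility: strict = identical groups; compatible = the standard
  9-cell donation matrix (O to all; A to A/AB; B to B/AB; AB to AB).
* **HLA mismatch.** Typing is two antigen labels per locus (A, B, DR). The
  donor→recipient mismatch at a locus counts donor alleles (with
  multiplicity, max 2) absent from the recipient's pair. Donor tables carry
  HLA typing because both the mismatch-driven score and the acceptance
  probability require it.
* **Percentile scores.** KDPI is the midrank percentile
  `100·(#below + ½·#equal)/n` of the donor's KDRI in the donor pool; EPTS
  percent is the same transform of the raw EPTS

      0.049·age·I(age>25) + 0.493·I(prior transplant)
      + 0.287·ln(years on dialysis + 1) + 0.598·I(years = 0)

  against a reference of all candidates with dialysis exposure frozen at
  listing. The candidate's own EPTS is evaluated at the donation date. The
  midrank convention makes degenerate references well-behaved (a constant
  reference maps everything to 50).
* **CORisk / IRisk.** CORisk with cut-off `c`: eligible iff EPTS% and KDPI%
  are both ≤ `c` or both ≥ `c` (boundaries inclusive on both sides, since
  the defining phrases are "or less"/"or more"). IRisk with bandwidth `s`:
  eligible iff `KDPI% − s ≤ EPTS% ≤ KDPI% + s`.
* **State balance.** A ledger tracks per-centre, per-calendar-year donors
  contributed and transplants received (cumulative within the year; donors
  count whether or not the kidney is placed). When enabled and the donor's
  centre has ratio > 1, the state round is redirected to the centre with the
  smallest ratio (alphabetical tie-break); centres with no activity count as
  balanced (ratio 1).

## Shared decision-making (Phase C)

`sdm0` returns the maximum-score candidate (ties: longer waiting time, then
id). `sdm1` visits candidates in that order and evaluates the four
considerations in fixed order 1→4:

1. pediatric: candidate age < 18 and |age − donor age| < 30;
2. quality gap: by default applicable when EPTS% ≥ KDPI% −
   `alpha2_threshold` (donor at least as good as the candidate's standing;
   threshold in percentile points, default 0). The raw-scale form
   (raw EPTS − KDRI) is retained as a config option (`alpha2_mode: raw`)
   because the two quantities live on different scales and the percentile
   comparison is the defensible default;
3. AB-to-AB: both candidate and donor blood group AB;
4. same state.

Each *applicable* consideration consumes exactly one Bernoulli(p_j) draw;
non-applicable ones consume none, which keeps draw counts (and hence
downstream randomness) reproducible. The first success matches the donor; a
candidate who fails all applicable considerations is passed over, and the
walk tries every candidate before declaring a discard. If the weighted
mismatch exceeds `z` the factor `(1 − HLA/z)` is clamped at 0 so p_j remains
a probability. Discarded kidneys are not re-offered.

Per-donor decision randomness is keyed by (master seed, donor id), so donor
processing order cannot perturb individual decisions.

## Engine and replication

Donor streams are uniform samples (default 800; with replacement only when
the request exceeds the pool, with a warning), sorted by donation date.
Processes I/II build the list once and deplete it only by transplants;
process III advances the dynamic list to each donation date first. Waiting
time is listing-to-transplant in days by default, with a config switch to
measure from dialysis start. Replicate `r` of a replication runs on a seed
derived from (master seed, r); results are therefore element-wise identical
whatever the worker count (parallelism via joblib).

One deliberate combination outside the three presets: the policy-comparison
strategies (NationalCurrent, CoRisk_20/40, IRisk_20/40) share the dynamic
waiting list and `sdm0` selection, varying only the eligibility filter, so
that differences between record sets are attributable to the filter alone.

## ACCA

All distances are computed on matched records only. Hellinger
`(1/√2)·√Σ(√pᵢ−√qᵢ)²` for categorical characteristics (national:state,
centre shares); two-sample KS and the absolute difference of Pearson
(non-excess, biased-moment) kurtosis for waiting-time distributions;
stratified tables give median waiting |log(actual/simulated)| by centre, age
band, EPTS band (quintile edges 0/20/40/60/80/100 of the percentile), PRA
band and blood group. The aggregate dissimilarity is the unweighted mean of
the normalised components — Hellinger and KS pass through, unbounded
components map through `1 − e^(−x)`. The aggregation formula is a design
choice of this package (no canonical form exists); it is isolated in
`dissimilarity_score` so alternatives can be swapped, and its absolute
values are not comparable to other implementations' dissimilarity numbers.

## Synthetic cohorts: what they are and are not

The generator draws every field independently from configurable marginals
(banded age and PRA with uniform within-band values, categorical blood
group/state/sex, Bernoulli comorbidity and prior-transplant flags,
exponential dialysis exposure, lognormal KDRI with μ=0, σ=0.3 so the
reference donor sits at the median, per-locus HLA allele pools with rough
population-scale frequencies). The packaged marginals are plausible for an
Australian-scale setting but are *not* registry estimates; no correlation
structure (e.g. age–comorbidity, PRA–prior-transplant) is modelled.
Consequently, passing tests establish the *mechanics* — queueing rates,
routing boundaries, decision-tree calibration, conservation, determinism —
not the realism of any particular national:state split or waiting-time
distribution, which depend on registry-calibrated inputs the package cannot
ship. With the default surrogate score, national-tier shares are small
(~2%), since level 6 requires rare zero-mismatch or sensitised-low-mismatch
offers; observed two-tier shares can only be matched by plugging in the real
scoring tables.

## Numerical conventions and edge cases

* Dates are ISO-8601 calendar dates; time advances in whole days; all CSV
  I/O round-trips exactly (booleans as True/False, HLA as `label;label`).
* Strict inequalities: national routing (`> 54,000,000`), the EPTS age
  indicator (`age > 25`), the pediatric age gap (`< 30`). Inclusive:
  CORisk/IRisk boundaries, the quality-gap threshold.
* Degenerate inputs: empty cohorts keep full schema; `n_out` larger than
  the active list removes everyone with a warning; an exhausted pool admits
  what remains (warning emitted once per run); an empty offer list yields a
  discard, and the run continues.
* Problem sizes used by the shipped tests — 10,000-day rate recovery,
  10,000-draw calibration, 800-donor default runs, 2,000-candidate shared
  pools — were chosen as the smallest sizes at which the CLT bounds quoted
  in the tests are sharp.

## Known limitations

Single-organ offers only; no re-offer of declined kidneys beyond the three
rounds; no competing-risks distinction between death and other exits; no
copula/stratified correlation in the generator; the exit-risk default is a
prior, not a fit; absolute dissimilarity values are implementation-specific.
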
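# Methods

This note documents the models implemented in `careflow`, the provenance
and defaults of every parameter that matters, what the synthetic
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Process-map data model

A workflow is a list of steps grouped into ordered stages. The packaged
default stage sequence is the six-stage external-beam course —
consultation, simulation, planning, treatment, on-treatment visit,
follow-up — but the stage list is data, not code: any workflow may
declare its own. Each step records the resources it consumes
(person-minutes per head for personnel, minutes for machines and rooms),
an occurrence probability in [0, 1] (default 1; used for tasks that apply
only to some patients), and a per-fraction flag (the step repeats every
treatment session of an `n_fractions`-session course).

Minutes and probabilities accept exact `fractions.Fraction` values, and
the YAML serialization round-trips them as `p/q` strings. This is what
lets tables back-derived from published dollar figures reproduce those
figures to the cent: the fixture stores minutes as the exact rational
`cost / CCR`, and the engine — not the fixture — recomputes the cost.

Headcount is modelled explicitly rather than folded into minutes so
reports can separate staffing from duration; validation rejects
headcounts above 1 on non-personnel resources.

## TDABC

The costing follows the standard time-driven activity-based costing
recipe: capacity cost rate (CCR) = annual cost / practical capacity in
minutes; step cost = CCR × minutes × headcount × occurrence probability
× (fractions, if per-fraction); course cost = sum over steps, held in a
(resource × stage) grid whose stage, resource, and category marginals
all sum to the same grand total (asserted to 1e-6 USD in tests).

Two conventions matter:

- **Supplied CCRs win.** When a rate table prints the CCR but not the
  salary behind it, the printed rate is the reproducible quantity, so a
  supplied `ccr` takes precedence over recomputation from `annual_cost`;
  if both are present they must agree to 0.5% relative.
- **Round late.** All arithmetic is full floating point (or exact
  rational, where inputs are rational); rounding to cents happens only in
  the report emitters. Published totals are only consistent if summation
  precedes rounding.

Difference grids are element-wise subtractions over the union of cells.
The packaged difference table is oriented CT-guided minus MR-guided,
matching the convention of the source study, so negative numbers mean
the MR-guided course is more expensive.

## Packaged study fixtures

The fixtures reproduce a published five-fraction SBRT costing and risk
study of an MR-guided (0.35 T MR-linac, online adaptive) versus a
CT-guided (conventional linac + CBCT) workflow.

- **Rate card** (printed): 7 personnel categories at 260 days × 8 h/yr
  (2080 h), e.g. radiation therapist 0.71, medical physicist 2.34,
  attending physician 4.40 USD/min; machines and vaults at 260 × 10 h
  (PET/CT at 260 × 8 h), e.g. MR-linac 8.01 USD/min, its vault 0.36;
  useful lives 10 y (equipment) and 25 y (space), informational.
- **Personnel grid** (printed costs, derived minutes): the study prints
  the full (personnel × stage) cost grid per modality; per-step minutes
  exist only in a figure image. The process maps therefore work at
  (personnel × stage) granularity, one aggregated step per non-zero
  cell, minutes = exact `cost / CCR`. This granularity is sufficient for
  every downstream quantity the package reports.
- **Equipment/space overheads** (printed totals, assumed split): only
  modality-level totals are published (MRgRT 4,471.15 / 199.04; CTgRT
  1,343.97 / 74.85). The fixture attaches a one-off CT-simulation block
  (20 min on the MR-guided course — consistent with the synthetic-CT
  scenario's arithmetic — 30 min on the CT-guided course) to the
  simulation stage and puts the remaining machine and vault minutes,
  back-derived by division, in the treatment stage; for the CT-guided
  course the delivery machine, surface-imaging system, and immobilization
  hardware are assumed engaged concurrently for equal minutes. Only the
  modality totals are asserted; the split is documented, not claimed.

## FMEA

Scores live on the TG-100 1–10 scales for occurrence, severity, and
detectability. Two consensus paths are supported, mirroring common team
practice: `mean_exact` (independent raters, exact rational mean) and
`agreed_value` (discussion consensus, a single value). RPN = O × S × D is
computed on unrounded rationals; display rounding is half-away-from-zero
to 2 decimals.

**Thirds interpretation.** Printed fractional scores such as 5.33, 2.67,
7.67 are read as exact thirds (16/3, 8/3, 23/3) by default, because they
arise from averaging three raters and because only that reading
reproduces the published RPNs (92.44, 88.89, 69.33, 40.3, 34.67)
exactly. Taking the decimals literally is available as an explicit
`score_mode="decimal"` opt-in; it does not reproduce (92.32 ≠ 92.44).

**Risk matrix.** Classification uses a 10 × 10 (S, O) → {low, medium,
high} grid, validated at load to be monotone (the level never decreases
as S or O rises) and to satisfy the severity override (rows S = 9, 10
entirely high). The packaged default — high iff S ≥ 9, or S ≥ 7 and
O ≥ 6, or S ≥ 5 and O ≥ 8; low iff S ≤ 2, or S ≤ 4 and O ≤ 3 — is an
institutional assumption chosen to be monotone and TG-100-compatible,
not a published fact; any grid satisfying the invariants can be supplied
as a 10-line L/M/H text file. Non-integer consensus scores are
ceiling-rounded for lookup, which never understates risk.

**Top-fraction selection** ranks descending by RPN (or severity), takes
k = ⌈fraction × group size⌉, and includes every mode tied with the k-th
value; grouping by role ranks each responsible-personnel group
independently. The published count of 52 top-RPN modes out of 279
(18.6%) is not exactly 20% and is not used for calibration.

**Audit.** `audit_register` compares each published RPN against the
display rounding of the exact recomputation. On the packaged 47-mode
register it flags exactly two rows at tolerance 0.1 — printed 51.13
versus exact (11/3)(14/3)(3) = 51.33, and printed 52.33 versus exact
(11/3)(16/3)(8/3) = 52.15 — which the fixture metadata records as
publication errata. The register's printed "top 20% severity" flags are
kept as data, not treated as algorithmic ground truth, because they are
not internally consistent (some S = 8 rows are unflagged while an S = 3
row is flagged). The source's abstract and results disagree on the
high-risk count (31 vs 30); the metadata records both.

## Scenario engine

Interventions are edit lists: `remove_step`, `reduce_minutes` (a delta
per occurrence, per head, optionally per fraction, applied to the steps
engaging a stated resource set within a stage), `scale_minutes`, and the
`dose_rate` convenience edit, which converts a rate upgrade into a
minutes reduction via `beam_on × (1 − old/new)`. Reductions clamp at
zero with a warning; an intervention may `require` others (applied
suites resolve the dependency order).

Savings are never bookkept: the edited workflow is re-costed and
subtracted from the baseline, so the category decomposition and the
consistency invariant (savings total = baseline − edited grand total)
hold by construction. Time saved is counted as elapsed course minutes
removed — one 25-minute task shortened by 25 minutes saves 25 minutes of
wall clock regardless of how many staff attended it — which is the
convention under which the packaged suite's savings sum to the published
270.55 min (~20% of the 1,346-min course).

The five packaged interventions and their derivations:

- **Auto-segmentation**: removes 25 min/fraction of online re-contouring
  from the delivery resource set (3 therapists, physicist, dosimetrist,
  machine, vault; combined 13.98 USD/min, a set back-derived from the
  published per-category savings divided by the published minutes) plus
  45 min of resident contouring at planning (0.59 USD/min). Personnel
  component reproduces the published 727.80 exactly; the recomputed
  total, 1,774.05, sits within the cent-rounding residue of the
  published 1,774.27.
- **MLC tracking**: 3.56 min/fraction off the delivery set (published
  per-fraction delta from a 40-patient delivery-report cohort; the
  reports themselves are out of scope and enter as this parameter).
  Recomputed 248.84 vs published 248.88.
- **VMAT delivery**: a further 8.53 min/fraction, modelled as
  *incremental* on MLC tracking (`requires: [mlc_tracking]`). The
  published combined figure 845.20 = 339.12 + 484.38 + 21.70 only
  reproduces under the combined 12.09 min/fraction reading
  (recomputed 845.09); the prose reading of 8.53 as a total does not.
- **Dose-rate upgrade** 600 → 1400 MU/min: the affected beam-limited
  time, 35.18 min/course, is not published and is back-derived from the
  published saving (281.03 / 13.98 × 7/4); recomputed 281.04.
- **Synthetic CT**: removes the one-off 20-min CT simulation
  (2 therapists + PET/CT simulator + room, 4.71 USD/min → 94.20;
  published 94.11, a 0.09 residual accepted and documented).

Combining all five reduces the course from 9,348.32 to a recomputed
6,353.94 (published chain: 6,353.71; the gap is the accumulated sub-cent
rounding embedded in the published component figures).

## Synthetic generators

The workflow generator emulates the *structure* of such studies —
multi-stage maps, log-normal task durations (default median 15 min,
σ_log 0.5), staffing headcounts (P(1,2,3) = 0.8/0.15/0.05 on personnel),
occurrence probabilities (1 with probability 0.8, else uniform on
[0.2, 0.9]), per-fraction flags (p = 0.3), CCRs uniform on [0.3, 8.0]
USD/min, five fractions — with a structure seed separated from the noise
seed so the expected course cost is analytic
(E[lognormal] = median·e^{σ²/2}) and Monte-Carlo recovery over many
noise seeds genuinely tests the costing engine. Defaults were chosen
once, to be plausible for a radiotherapy clinic and to exercise every
code path; no empirical claim attaches to them.

The register generator draws rater scores from a discrete triangular
distribution on 1–10 (default peak 3, the shape of most-failures-are-
benign registers) and records its own ground truth — consensus scores,
RPNs, levels, top-fraction membership — with independent inline
arithmetic, serving as the oracle for the FMEA engine.

What the synthetic data does **not** emulate: correlations between O, S,
and D (real registers show severity–detectability structure), stage-
dependent duration distributions, resource contention or scheduling, and
inter-rater disagreement patterns. Passing the synthetic suites
therefore demonstrates engine correctness (conservation, oracle
equivalence, planted-truth recovery), not fidelity of any clinical
claim; the clinical numbers rest on the packaged fixtures.

## Numerical choices and problem sizes

- Display rounding is half-away-from-zero (832/9 → 92.44); exact for
  rationals, via a 10⁻⁹-denominator rational lift for floats.
- Marginal-sum conservation is asserted to 1e-6 USD; fixture
  reproduction to the cent (|Δ| ≤ 0.005 before rounding).
- Scenario reductions keep Fraction arithmetic when the delta is exactly
  representable (denominator ≤ 10⁶), so untouched fixture cells stay
  exact after edits.
- Ties in top-fraction selection are kept (never arbitrarily broken);
  the cutoff uses ceiling so a 20% fraction of 47 modes flags 10.
- Property suites run 200 random synthetic workflows and 200 Monte-Carlo
  seeds for expected-cost recovery (3-standard-error band); registers up
  to 50 modes for ranking oracles. These sizes give stable statistics
  while keeping the full test suite in the seconds range.

## Known limitations

- No scheduling/queueing semantics: steps carry durations, not calendar
  times; throughput and revenue are out of scope, as are overhead
  allocation beyond CCRs, depreciation schedules beyond the annualized
  cost, and billing/reimbursement.
- The equipment/space stage split and the CT-guided concurrency
  assumption are under-determined by the published totals; only modality
  totals should be quoted from those cells.
- The packaged register is the published top-RPN subset (47 modes), not
  the full 279-mode register; level counts computed on it are not the
  study-wide counts.
- No fault-tree analysis, mitigation recommendation, or inter-rater
  reliability statistics.
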
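# Methods

## Model structure

A cohort of HER2-positive early breast cancer patients enters a 4-state
Markov model (stable, remission, relapse, death) entirely in the stable
state and transitions once per annual cycle for five cycles. Death is
absorbing and, in the base structure, reachable only from relapse —
stable→death and remission→death are structurally zero. The initial
distribution is configurable; 100% stable is the default because patients
enter adjuvant therapy with disease present.

Costs and QALYs accrue per cycle as the occupancy-weighted sum of
per-state values, half-cycle corrected (membership credited to cycle *t*
is the mean of the boundary occupancies at *t−1* and *t*, the trapezoidal
reading of "half-cycle corrected"), and discounted at 5%/year with the
convention `1/(1+r)^(t−1)` — cycle 1 undiscounted. That convention is the
natural partner of charging the one-off chemotherapy cost at cycle 1:
an up-front payment is neither discounted nor half-cycle corrected.

## Parameter derivation

Each arm is summarised by (RR, OS, TTP, DOR). Annual probabilities:

| transition | formula | AC-TH | TCH |
|---|---|---|---|
| remission→relapse | `1 − exp(−0.75·ln2/DOR)` | 0.089 | 0.12 |
| relapse→death | `1 − exp(−0.75·ln2/(OS−TTP))` | 0.014 | 0.021 |
| stable→remission | `1 − exp(−RR/3)` | 0.243 | 0.209 |
| stable→relapse | `4 × (remission→relapse)` | 0.356 | 0.48 |

Stay probabilities are complements. The constants 0.75 and 3 are model
constants of the source analysis carried as named configuration
(`DerivationConstants`); no derivation for them is attempted. The
exponential expression itself is the annual *stay* probability — its
complement is the transition probability; this is the only reading under
which all published cells are mutually consistent (e.g.
`exp(−0.75·ln2/5.6) = 0.911` is remission→remission, and 0.089 its
complement). TCH's DOR is taken as 4 months (the published input value;
an alternative 4.2 appears once in a formula string and can be set in
config).

Two rounding modes exist because the published table chains *rounded*
values: `printed_precision` rounds each derived probability to its table
precision (3 dp, except TCH remission→relapse at 2 dp) before the next
step uses it — this reproduces every published cell exactly — while
`full_precision` never rounds and keeps rows summing to 1 exactly. The
base-case analysis uses printed precision to stay on the published
numbers; the difference is below 5e-3 everywhere.

## Costs, utilities and the reconstructed fixture

Utilities: stable 0.74 (no recurrence, chemotherapy period), remission
0.85, relapse 0.5, death 0. The source table lists five utilities for
four states; this mapping is the only unambiguous one-to-one assignment,
and the alternatives (0.94 after chemotherapy; 0.74 local recurrence) can
be substituted through the config's utilities block.

Per-state costs are **reconstructed (synthetic)**: only per-strategy
totals are published. Remission ($1,500/yr follow-up) and relapse
($15,000/yr recurrence management) were fixed at round plausible values
shared by both arms, and each arm's stable-state cost solved so the
discounted half-cycle-corrected health-system total matches the published
figures ($56,425 AC-TH, $45,043 TCH) to under a cent: $19,696.75 (AC-TH)
and $4,673.75 (TCH) per stable year. A relapse cost of $18,000 was
rejected because it forces a negative TCH stable cost. One-off
intervention costs are the published $3,112 / $1,352. The asymmetry in
stable-state cost absorbs everything the published totals do not itemise;
inference about cost *components* should not be read into it.

With these inputs the engine reproduces the published totals and
Δcost = $13,142 exactly. The published per-strategy QALYs (3.4 / 3.65)
and 5-year state-occupancy percentages are **not** reproducible from the
published transition matrices under any initial distribution or utility
mapping tried (the model yields 2.94 / 2.77 QALYs with the relapse share
around 2/3 of the cohort at year 5); they are treated as documentation,
and the engine is instead held to structural properties (mass
conservation, death monotonicity, half-cycle bracketing) and to agreement
with an independent microsimulation. The published incremental
arithmetic (ΔE = −0.25, |ICER| = $52,568 = 13,142/0.25) is validated by
feeding the published totals directly to the incremental routine.

## Sensitivity analysis

**Ranges.** Every probability, utility and cost carries a ±20% range,
clamped to [0, 1] for probabilities/utilities.

**One-way / tornado.** All 14 per-arm transition probabilities are
one-way parameters, each over its own range. Varying an exit probability
rebalances the row through the stay complement; varying a stay
probability (ss, rr, pp) rescales that row's exits proportionally —
without this, stay-probability parameters (which the source narrative
ranks as most influential) could not be varied at all. A scenario that
pushes the stable row's exits past 1 raises an error rather than being
silently repaired. The default tornado output is the NMB difference
between arms at λ = $20,000/QALY (the source does not state its output
metric; NMB is used because negative ICERs make ratio swings
uninterpretable). Ties in swing break by parameter name, making the
ordering deterministic and input-order invariant.

**PSA.** Probabilities and utilities get beta distributions, costs gamma,
fitted by the method of moments with the range read as a central 95%
interval (sd = (hi−lo)/3.92) — the most common convention when only
ranges are published. Degenerate ranges fall back to point masses. Only
the free exit probabilities (sr, sp, rp, pd per arm) are sampled; stay
probabilities are complements, and a sampled stable row exceeding 1 is
rescaled proportionally and counted (`n_rescaled`; zero at the default
±20% ranges). Each of the default 1000 draws re-evaluates the
deterministic cohort model for both arms — the standard second-order
design; first-order (patient-level) noise is deliberately excluded from
the PSA and confined to the validation microsimulation. Intervals are
the 2.5th/97.5th percentile ranks. A single seed governs all draws.

**CEAC / CE plane.** Acceptability at λ is the fraction of draws in which
a strategy's NMB is maximal; exact ties go to the first arm, the same
"≤ counts as cost-effective" convention used for points on the WTP ray,
so the curves sum to 1 at every threshold.

## Synthetic data and validation

`generate_cohort` draws patient records from the published arm-level
summaries: response multinomials (AC-TH: PR 0.60, SD 0.12, PD 0.28 of
25; TCH: CR/SD/PD 0.0625 each, PR 0.8125 of 16) and per-event
adverse-event grade incidences. These emulate marginal frequencies only —
no within-patient correlation between events, no response–transition
link, no time structure — so tests passing on them show the pipeline's
arithmetic and plumbing, not clinical realism.

`microsimulate` samples individual annual state paths from the same
transition matrix and is the engine's independent oracle: occupancy
fractions converge to the cohort trace (checked at n = 10³–10⁵, and
within 4 binomial standard errors at the 10,000-person validation size).

Internal validation compares microsimulated and model survival with a
Pearson chi-squared test. Two constructions are provided.
`chi_square_validation` compares cumulative per-year alive/dead counts
(dof = years − 1) — the face-value reading of "compare annual survival" —
but its yearly cells share surviving individuals, the terms are
positively correlated, and it over-rejects a true null (empirically ~13%
at the 5% level). `validate_microsim`, the recommended routine,
decomposes each path into disjoint year-of-death cells (plus survival to
the horizon), a proper multinomial whose Pearson statistic is
asymptotically exact chi-squared; its p-values are uniform under the
null and it is what the validation CLI and the calibration tests use.
Structurally empty cells (years the model assigns zero death probability)
are dropped from the statistic.

## Numerical choices

- Row-sum tolerance 1e−12 at matrix construction, 1e−10 during cohort
  iteration; probabilities validated to [0, 1].
- Problem sizes: 5-cycle cohort (published horizon); 1000 PSA draws
  (published count); 10,000-person microsimulation (published cohort
  size); 100,000-record synthetic cohorts for law-of-large-numbers
  checks; 100 replicates for validation calibration.
- ICER is undefined (None) at ΔE = 0; dominance requires one strict
  inequality, so identical strategies are "none".
- Beta fits reject ranges whose implied variance exceeds mean(1−mean);
  gamma fits reject degenerate ranges (point mass instead).

## Limitations

Transition probabilities are time-homogeneous (no tunnel states, no
cycle-dependent hazards) and adverse events do not feed costs or
utilities — both acknowledged simplifications of the source analysis.
The reconstructed cost split is one of infinitely many consistent with
the published totals; results that depend on the split (e.g. the ranking
of cost parameters in a full tornado) inherit that arbitrariness, while
anything driven by totals does not. The published QALY totals are not
recoverable from the published inputs, so decision outputs computed from
the model (as opposed to from the published totals) differ from the
published ICER in sign of ΔE.
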
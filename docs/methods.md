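# Methods

## Model structure

The model is a discrete-time Markov cohort simulation of men aged ≥50 with
moderate-to-severe BPH, with six states — mild, moderate, severe (IPSS
bands 0–7, 8–19, 20–35), AUR, post-surgery, death — advanced over sixteen
3-month cycles. The cohort is propagated in expected counts, the standard
spreadsheet-Markov convention: occupancy is a real number, fractional
persons are kept internally, and rounding to whole patients/euros happens
only when report tables are written (`--full-precision` disables it).

Within-cycle order is fixed and documented, because the published
description pins only two points (mortality at cycle start; AUR mid-cycle):

1. all-cause mortality on every alive state;
2. incident entrants arrive, distributed 7/63/30% over mild/moderate/severe
   (the baseline severity mix; the entrant mix is not separately published
   and the baseline mix is the least-assumption choice);
3. severity transitions;
4. AUR resolution: TWOC succeeds with probability 0.5 and returns the
   patient to the exact severity state they left (origin is tracked per
   state within the cycle); failures undergo TURP in the same cycle;
5. direct TURP exits from moderate/severe (structurally zero from mild);
6. post-surgery pathway update.

AUR is a tunnel: boundary occupancy is identically zero and nobody dies
during AUR treatment. Conservation (alive + cumulative deaths = initial +
cumulative entrants) is asserted every cycle at 10⁻⁶ relative tolerance; a
violation aborts the run.

### Post-surgery pathway

At most two TURPs per patient. A first procedure succeeds (>50% IPSS
reduction) with probability `turp_success` (default 0.77, back-derived from
the sensitivity anchors 88% = base+11 and 99% = base+22 points; flagged
assumed and overridable). Failures await the second procedure, performed
the following cycle; a per-cycle `relapse_prob` (default 0 — no published
value) also routes stable first-TURP successes to the second procedure.
After the second TURP the patient stays post-surgery regardless of outcome.
`complication_prob` (no shipped default in the config schema — the value
derives from clinical guidelines, not a published model input, and must be
chosen explicitly; 0.20 in the emitted default document) prices procedures
at the with-complications tariff mixture and adds 3.44 follow-up visits per
complicated procedure. `incontinence_prob` (default 0.01, a realistic
permanent-incontinence risk after TURP; assumed) diverts a share of each
group settling into a stable substate to permanent incontinence with its
own 4.56 visits/year schedule; patients routed by the failure branch are
assessed for incontinence after their second procedure. Post-surgery
patients receive no BPH drug therapy (surgery replaces medical management;
flagged assumption).

## Population and mortality

Eligible cohort = census × prevalence × moderate/severe fraction
(1,724,867 × 0.30 × 0.63 → 326,000 when rounded for reporting; the pipeline
uses the unrounded product). Incidence, 2,090 events / 110,321 man-years =
18.94 per 1,000 man-years, applies to the **full census** (the rate is
quoted for the general older-male population), from year 2 onward — year-1
patients are prevalent and have already had their initial urologist
consultation, which is why every year-1 output is exactly proportional to
prevalence. Mortality is a single age-aggregated annual risk for men >50;
the interim life-table value is not printed anywhere usable, so the config
ships 0.02/yr as a flagged assumption, converted to a quarterly probability
by the constant-hazard formula.

## Market dynamics

Uptake shares (2.0/4.0/4.5/11.0% by year) apply to the year-1 initial
cohort and to each year's entrants; year-end switching (3.0/4.0/5.5% at the
ends of years 1–3) moves prevalent SoC moderate/severe patients — only
those states — into the FDC arm with state preserved, instantaneously
between cycles 4k and 4k+1 before the next cycle's mortality. The two
mechanisms never double-count. FDC patients never switch back and stay on
the combination after regressing to mild.

## Costing

Two sectors (public reimbursement tariffs vs private out-of-pocket rates)
are complete, independent scenarios; no weighted average exists because the
patient split between sectors is unpublished. Four components, exactly
additive:

- **Consultations** — severity-state urologist/GP visits (first-year vs
  subsequent-year profiles; the model applies first-year rates in model
  year 1), severe-state cystoscopy expectation 0.39/yr × 7% of patients
  (the conditional-count reading of an ambiguous table; overridable),
  incontinence visits, and entrant initial consultations. GP and initial
  consultation tariffs are absent from the published fee tables; defaults
  (GP = urologist follow-up tariff; initial = 2×) are flagged assumptions.
  The moderate-state GP rate (2/yr) is applied in both first and subsequent
  years. Serum creatinine appears in the tariff table but in no resource
  profile; default usage 0 with a config hook.
- **Surgery** — procedures at the complication-probability mixture of the
  without/with tariffs, plus peri-operative consultations (2.67 successful
  / 3.89 unsuccessful), 1.1 cystoscopies and 0.06 urodynamic tests per
  procedure, and complication follow-up visits.
- **AUR** — per-episode catheterization tariff.
- **Drugs** — severity-state occupancy × pack price × 3 packs/quarter
  (flat-3, matching monthly dispensing of 30-day packs; a day-exact
  91.25/30 convention is a config flag). FDC €30.02, tamsulosin €12.42.

Drug and routine-visit costs bill the state occupied at cycle start (after
mortality and entrants, before transitions); this is the determinate
membership convention adopted where the source fixes none. No discounting
or inflation. Adverse-event costs are excluded (<1% of patients in all
arms). Report rounding: euros and counts to whole units, percentages to
two decimals.

## Synthetic inputs and calibration

The per-arm quarterly transition matrices derive from unpublished
patient-level trial data, so `synthetic.generate_transition_set` builds
them from: SoC worsening/improvement probabilities (defaults: mild→moderate
0.10, moderate→severe 0.05, moderate→mild 0.03, severe→moderate 0.04 per
quarter), SoC event hazards (AUR 0.001/0.004/0.008, direct TURP
0/0.003/0.008 for mild/moderate/severe), and FDC multiplicative risk
reductions (worsening 0.65, AUR 0.35, TURP 0.35 — consistent with the
combination's reported ~65% relative reduction in AUR/surgery risk over 4
years). These defaults were chosen once to land the SoC world in the
reported range (≈10–13k TURPs and 6–7.5k AUR episodes per year on a 326k
cohort) and are not tuned thereafter. Freed probability mass returns to
the diagonal, so the FDC arm stochastically dominates on staying
mild/improving. Optional Dirichlet jitter (concentration = row/scale)
perturbs rows reproducibly; structural zeros stay zero; scale 0 is
deterministic.

`calibrate_to_event_table` fits two scalar multipliers — one on the AUR
hazards, one on the direct-TURP hazards — by a deterministic pattern
(coordinate) search minimising the maximum yearly relative error of
simulated vs target TURP/AUR counts, holding severity-shift probabilities
fixed (event-count targets cannot identify the severity block; a joint
search would be under-determined). Step halves from 0.5 down to 10⁻⁹;
non-convergence within `max_iter` returns the best-found result with an
explicit warning status. Parameter recovery against targets from a known
matrix reaches <0.1% relative error in ~65 evaluations.

## Validation oracle

`microsim.microsimulate` is an independent individual-level Monte Carlo
implementation of the identical per-cycle mechanics (vectorised over
patients, seeded). The validation compares yearly AUR/TURP/first/second
tallies of a closed 100,000-patient cohort (no incident entrants — an
expected-count entrant stream has no exact individual-level analogue)
against the cohort engine, requiring agreement within 3 binomial standard
errors. What this does and does not show: it verifies the expected-count
engine implements the stated stochastic process; it cannot validate the
synthetic transition probabilities against real disease progression, drug
adherence (assumed 100%), or severity-dependent mortality, none of which
the generator emulates.

## Numerical choices and limitations

- Row-stochasticity tolerance 10⁻¹²; conservation tolerance 10⁻⁶ persons
  (relative); probability-mass leaks raise, never warn.
- Problem sizes: all pipeline runs are 16-cycle expected-count propagations
  (milliseconds); the microsimulation uses 100,000 patients and the
  calibration ≤200 pattern-search iterations.
- The published cumulative AUR-avoided cell (942) contradicts both its own
  column sum (60+168+241+503 = 972) and the abstract's 972; this package
  reports the column sum.
- The reported 4-year "savings" figures (€1.13M/€1.95M) are not derivable
  from any combination of the published offset columns and are not
  reproduced.
- "±10%" prevalence variation is read as ±10 percentage points (20%/40%),
  matching the sensitivity table's row labels. The prostate-volume >50cc
  subset fraction is unpublished; default 0.5 (flagged), applied to the
  initial cohort and entrants alike, so that row is structurally — not
  numerically — comparable to the published one.
- Not modelled: age structure, per-age incidence/mortality, treatment
  discontinuation, alternative surgical modalities, adverse-event costs,
  quality-of-life or cost-effectiveness outputs, probabilistic sensitivity
  analysis.
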
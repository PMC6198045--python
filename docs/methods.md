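# Methods

## Model structure

The disease course is a discrete-time Markov chain over seven health
states: **BPH** (symptomatic, on study drug), **AUR** (acute urinary
retention), **TURP** (first transurethral resection), **repeat TURP**,
**medical intervention** (post-operative pharmacological management),
**recovery**, and **death**. All patients start in BPH. AUR, TURP and
repeat TURP are one-cycle tunnel states: an AUR episode resolves within
the cycle either to surgery (probability 0.8) or back to BPH; a TURP
cycle ends in 30-day surgical death (0.0237), repeat surgery (0.059),
medical management (0.059) or recovery (remainder). Survivors of a
repeat TURP may need medical management (0.0025) but never a third
procedure.

Because "at most two TURPs" is a history rule a 7×7 memoryless matrix
cannot carry, both engines run on an internal 9-state expansion that
splits the medical and recovery states by prior procedure count (one vs
two). The public 7×7 matrix exposed by `bphce.markov` is the aggregate
of that chain and is the right object for row-stochasticity audits and
CSV dumps; the engines guarantee that no simulated path contains a third
procedure.

Treatment acts only on disease progression from BPH: under combination
therapy the BPH→AUR and BPH→TURP probabilities are multiplied by
(1 − RRR) with RRR 0.676 and 0.706. The relative effect is held constant
over the whole horizon (no waning), including the 35-year run.

## Mortality

Background all-cause mortality enters every alive state as a competing
risk: state transitions are scaled by the cycle's survival probability
and the death entry receives `1 − (1 − q_surgical)(1 − q_background)`.
The schedule is a Gompertz stand-in `μ(a) = b·e^{0.09a}` discretised to
annual probabilities, with `b` root-found so that a cohort entering at
the default start age 66 has a 4-year cumulative background mortality of
0.055 (about 1.2%/yr at 66, 4.2%/yr at 80). That target is the model's
overall 4-year death risk under monotherapy (~0.0577) net of the ~0.002
surgical deaths the chain itself produces. The 35-year run ages the
cohort through the schedule year by year. The stand-in is synthetic: it
reproduces a plausible elderly-male mortality level and slope, not any
official national life table.

## Timescale and residual mass

Two conventions are deliberately configurable because the source
material for this class of model is often ambiguous about them:

* `settings.probability_timescale` — `annual` (default) applies the
  printed per-cycle probabilities to yearly cycles; `monthly` reads the
  state-time probabilities as monthly and converts
  `p_year = 1 − (1 − p_month)^12`. Event-conditional probabilities
  (AUR→TURP, the surgical splits, surgical mortality) are per episode
  and never rescaled. The annual default is the only reading compatible
  with a cohort spending ~3.4 of 4 person-years in BPH.
* `settings.residual_mode` — the printed "remain in state" values for
  BPH (0.345), recovery (0.329) and medical management (0.393) do not
  complement the printed exits of their rows. Under `residual`
  (default) they are informational: each self-loop is 1 − exits − death
  mass. Under `printed` the self-loop is pinned at the printed value,
  survival-scaled, and the explicit exits are renormalised over the
  remainder.

## Economic accrual

Cycle-start accrual, discount factor `(1+r)^{-t}` with `r = 0.03` on
both costs and QALYs and cycle 0 undiscounted; no half-cycle correction
by default (`settings.half_cycle_correction` adds the standard 1/2-1/2
end-point weighting). Conventions:

* Drug acquisition (464.97 vs 55.79 US$/yr) and BPH management
  (471 US$/yr) accrue to BPH occupancy only — beyond BPH, patients
  receive follow-up "medical intervention" pharmacotherapy (371 US$/yr
  on that state's occupancy) instead of study drug.
* AUR (1,312 US$) and TURP (6,334 US$) are charged per event; patients
  dying of surgical complications still incur the procedure cost.
* Recovery carries utility 1.0 and no recurring cost; a one-off
  follow-up charge on first recovery entry is supported
  (`costs.recovery_followup`) but defaults to 0 because no value is
  published for it.
* Utilities: BPH 0.876 (a severity-weighted single state — the model
  deliberately does not stratify mild/moderate/severe), AUR/TURP/medical
  0.25, recovery 1.0, death 0.
* Episode counts are undiscounted: BPH is person-years in state,
  AUR/TURP are event counts, deaths are cumulative mortality.

The microsimulation engine samples individual trajectories from the
same per-cycle matrices and shares the accrual code path: its
`accumulate_outcomes` recomputes every result from the stored
per-patient state log alone, so accumulation is idempotent and the two
engines agree in expectation (tested to 3 Monte-Carlo standard errors at
n = 200,000, with error scaling ~n^{-1/2}).

## Sensitivity analyses

**One-way:** each parameter with a published uncertainty range is set to
its low and high bound with everything else at base, both arms re-run
with the cohort engine, and the ICER recorded; entries sort by ICER
spread (tornado order). Ranges on informational stay probabilities are
retained and evaluated; under the default residual rule they leave the
ICER unchanged (zero-spread rows), which is itself a documented model
property.

**Probabilistic:** second-order Monte Carlo. Eleven parameters carry
distributions — beta for probabilities and the two RRRs, gamma for
costs. The published gamma rate constants are inconsistent with their
published means, so rates are rederived as shape/mean (keeping the
published shapes, hence the intended dispersion ordering). Each draw is
validated (sub-stochastic rows, bounds) and invalid draws are redrawn
with a logged count; both arms are then evaluated on the same draw with
the deterministic cohort engine — one (ΔC, ΔE) point per draw. A nested
per-draw microsimulation is intentionally not the default: it adds
first-order noise to a second-order question. The CEAC reports, per
willingness-to-pay value, the fraction of draws with strictly positive
incremental net monetary benefit (an exact zero counts as *not*
cost-effective); CE-plane quadrants assign boundary zeros to the
positive side. The deterministic base case uses the base-case values
even where a distribution's mean differs from them; the distributions
govern only the PSA.

## Problem sizes and verification

The cohort engine is verified against closed-form geometric-series
oracles on two- and three-state degenerate configurations to 1e-9 (the
oracles are computed independently of the matrix code). The test suite
uses 400–2,000 PSA draws and up to 200,000 microsimulated patients;
`scripts/acceptance.py` uses the deterministic cohort engine for
base-case quantities and 10,000 PSA draws per horizon, with all
randomness derived from one CLI seed.

## Known limitations

* Single BPH severity state (no IPSS mild/moderate/severe split); the
  0.876 utility is the pre-weighted aggregate.
* No adverse-event modelling and no societal/indirect costs; payer
  perspective only, 2018 US$ without inflation adjustment.
* Background mortality is a calibrated synthetic stand-in, not an
  official life table; absolute death counts inherit its calibration.
* Treatment effects are constant per-cycle multipliers estimated over a
  4-year trial; extrapolation to 35 years assumes no waning.
* The synthetic toy fixtures exercise the engine's arithmetic, not the
  clinical realism of the transition estimates: a green suite shows the
  machinery is faithful to its inputs, not that the inputs describe any
  particular population.
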
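# Methods

## Decision problem

Five strategies for identifying Lynch syndrome (LS) among women newly
diagnosed with endometrial cancer are compared twice: on diagnostic costs
per LS case identified (short term), and on lifetime discounted costs per
QALY for probands and their relatives (long term).  The comparison is a
standard incremental analysis: strategies are sorted by effectiveness,
strictly dominated strategies removed, extendedly dominated strategies
removed until ICERs strictly increase along the frontier, and each
surviving strategy priced against the previous frontier member.

## The calibration cohort

True patient-level data are unavailable, so `petals_fixture()` reconstructs
a 500-patient cohort that satisfies every published marginal *exactly*
(counts listed in the README).  Three reconstruction choices deserve
comment:

* **Tumour IHC patterns for LS cases** follow MMR heterodimer biology:
  path_MLH1 → MLH1+PMS2 absent, path_MSH2 → MSH2+MSH6 absent, path_MSH6 →
  MSH6 absent, path_PMS2 → PMS2 absent.  Consequently all 16 LS tumours
  show complete loss of MSH6 or PMS2, which is what makes the two-antibody
  (MSH6/PMS2) panel equally sensitive on this cohort.
* **Sporadic tumour composition** is not printed anywhere, but it is
  over-determined by the published per-strategy cohort costs.  Solving the
  integer system given the unit costs yields: 84 sporadic tumours with
  MLH1/PMS2 loss (72 explained by *MLH1* promoter hypermethylation, 12
  not), of which 76 are MSI-high; 3 MSI-high tumours with intact MMR
  expression; 20 MSI-low tumours; 377 unremarkable.  With this composition
  the simulated cohort costs reproduce the published totals
  (£41,512 / £27,523 / £27,183 / £127,125) to the pound, and switching
  MSI-low to "test positive" sends exactly 20 extra sporadic patients for
  unnecessary further testing while finding one extra LS case.
* **Per-case details never printed** (which LS case is MSI-low, which lack
  family history, integer age lists hitting the published means exactly)
  are fixed by documented deterministic rules chosen to keep every
  published scenario count correct: the single LS case aged ≥70 is
  microsatellite-stable (so age-restricted MSI triage still finds nine),
  and exactly 8 of the 11 LS cases with PREMM₅ ≥ 2.5% are MSI-high (so
  PREMM₅-gated MSI triage finds eight).

The random generator `generate_population(n, targets, seed)` draws each
patient independently from the proportions implied by the same targets;
its marginals converge by the law of large numbers but any single cohort is
noisy.  It emulates marginal structure only — it does not model the
age–hypermethylation correlation or any other covariance beyond what the
category definitions impose, so passing tests on synthetic cohorts say
nothing about such correlations in real data.

## Diagnostic pathways

Unit costs are 2016/17 GBP; salary-based items already include a 2.08
labour on-cost factor (employer pension, National Insurance, overheads),
exposed as `apply_labour_oncost` for deriving new cost items.  Decision
rules: patchy IHC staining counts as expressed; a methylation status never
ascertained is assumed negative when a strategy would have tested it;
germline NGS is definitive (no false positives/negatives) and only
variant-positive patients incur post-test counselling.  Tumours with
simultaneous MLH1/PMS2 and MSH2/MSH6 loss (possible in user data, absent
from the fixture) go straight to NGS: MSH2/MSH6 loss already mandates it.
NGS consent (£13.64) is charged whenever NGS is ordered, in all strategies.

Prefilters: the age filter (test only under-70s) is free; the PREMM₅ filter
charges £3.58 per patient *with a computable score* and gates at ≥ 2.5%.
Patients without family-history data are ineligible under the PREMM₅ filter
by default (`premm5_missing_eligible` reverses this).  The two prefilters
are never combined.

Counselling variants: `alt_428_403` swaps in £428 first-visit / £403
follow-up tariffs.  `nhs_reference` is represented as a flat, configurable
per-participant lifetime-cost uplift (£60 default) on testing strategies,
because the underlying NHS reference unit costs are not published as items.

## Markov model

Yearly cycles from the individual's current age to 100.  States: alive
without colorectal cancer (CRC); CRC stage I–IV as tunnel states carrying
time-since-diagnosis; CRC survivor; dead of CRC; dead of other causes.
From the at-risk state, background mortality competes with CRC onset
`1 − exp(−incidence × HR)` (HR = the surveillance hazard ratio 0.387, or
0.929 in the worst-case scenario, applied only when LS has been diagnosed);
onset splits over stages by the surveillance-specific stage distribution.
Stage-specific excess mortality applies for 5 years (configurable), after
which survivors revert to background mortality.  Accruals happen at cycle
start (half-cycle correction available but off by default — yearly cycles
match annual-rate inputs); utilities decline linearly with age and are
multiplied by 0.789 while in stage IV; colonoscopies (£583) recur every
2 years (configurable — the source does not state the interval) from
diagnosis while alive and CRC-free; CRC treatment costs are charged once at
diagnosis by age band and stage (spanning £807 to £14,490).  Discounting is
3.5%/year for costs and QALYs; life expectancy is reported undiscounted.
Endometrial-cancer-specific mortality for probands is not separately
modelled (background mortality only).

**Provenance.** Printed and therefore anchored: the 0.387/0.929 hazard
ratios, 0.789 stage-IV utility multiplier, £583 colonoscopy, the £807–
£14,490 CRC cost range, 3.5% discounting, and the stage-at-diagnosis
distributions (normalised from the published expected stage-specific CRC
counts with and without surveillance).  Placeholders, clearly flagged as
such: the genotype/age incidence curves (ordered MLH1 > MSH2 > MSH6 > PMS2
with a 1.2 male factor), stage-specific annual CRC mortality, Gompertz
background mortality (q = 1e-5·e^{0.105·age}, male ×1.5), the linear
utility profile, and the interior of the CRC cost table.  Lifetime outputs
(ICERs per QALY, QALY gains, lifetime CRC counts) therefore carry
placeholder uncertainty and are checked structurally (conservation,
closed-form discounting, monotonicity in HR/age/genotype), never against
published lifetime numbers.

## Cascade testing

Per identified proband: 6.0 relatives have a GP appointment (£38 each — a
national unit cost, configurable; not part of the microcosting), 4.7 attend
pre-test counselling (£171.73), 3.3 take a predictive test (£166.32) and,
by default, all 3.3 receive post-test counselling (£133.15;
`counsel_all_tested=False` restricts it to the 1.5 diagnosed).  The 1.5
diagnosed relatives carry the proband's family variant and receive
surveillance; their lifetime benefit is the equal-weights mean over the ten
age/sex profiles (ages 24.5, 35.7, 45.0, 53.2, 66.8; both sexes) of the
relative grid restricted to that genotype.  To keep the modelled population
identical across strategies, a strategy-independent baseline (6 relatives,
no surveillance, averaged over the full 50-profile grid) is added for every
proband; it cancels in all increments.  Cascade testing costs are charged
undiscounted in the diagnosis cycle.

## Uncertainty

Each of the 200 bootstrap+PSA iterations resamples the cohort with
replacement (fully — the LS-case count is not conditioned on) and draws one
joint parameter vector: gamma for unit costs, colonoscopy and a common CRC
treatment-cost scale; beta for stage mortality and the stage-IV utility
multiplier; lognormal for the surveillance hazard ratio (capped at 1) and a
common incidence scale; Dirichlet for the stage distributions.  Published
point estimates come without standard errors, so every distribution uses a
default coefficient of variation of 0.15 — common practice when only point
estimates are available — configurable in `PSAConfig`.  Everything is
reproducible from the single seed.  CEACs use net monetary benefit
(λ·Δeffect − Δcost > 0); ICER credible intervals use linear-interpolation
percentiles and exclude iterations with non-positive incremental effect
(the NMB-based CEAC is unaffected by that exclusion).

## Numerical choices and limitations

* Occupancy conservation is enforced at 1e-10 per cycle; stage
  distributions must sum to 1 within 1e-12.
* Frontier tie-breaks: equal effect keeps the cheaper strategy; exact
  (cost, effect) duplicates keep the first in sort order and mark the rest
  dominated.  Report ICERs round half away from zero.
* Deterministic analyses at the 500-patient scale run in well under a
  second per strategy set; a 200-iteration proband-level PSA takes tens of
  seconds on one CPU because each iteration re-runs the Markov model for
  every distinct (genotype, age, surveillance) combination (memoised
  within an iteration, not across iterations, since parameters change).
* Not modelled (by design): non-colorectal Lynch-associated cancers,
  gynaecological surveillance, aspirin chemoprevention, laboratory
  batching economies, NGS false positives, uptake variation in cascade
  testing, metastatic progression between stages after diagnosis.
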
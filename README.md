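# lynchcea

Cost-effectiveness modelling of reflex testing for Lynch syndrome in women
with endometrial cancer.

Lynch syndrome — a hereditary cancer-predisposition syndrome caused by
pathogenic germline variants in the DNA mismatch-repair (MMR) genes *MLH1*,
*MSH2*, *MSH6* and *PMS2* — accounts for roughly 3% of endometrial cancer.
Identifying carriers at the point of endometrial cancer diagnosis lets them
start colonoscopic surveillance (reducing colorectal cancer incidence and
shifting diagnoses to earlier stages) and triggers cascade genetic testing
of their relatives.  The package evaluates five reflex-testing strategies
for a UK NHS setting:

| Strategy | Triage |
|----------|--------|
| S0 | No testing |
| S1 | Microsatellite instability (MSI) testing, then germline NGS |
| S2 | MSI, then *MLH1* promoter methylation, then NGS |
| S3 | Four-protein MMR immunohistochemistry + *MLH1* methylation, then NGS (the "Manchester approach") |
| S4 | Direct germline NGS for all |

It is written for health-economics analysts: every model input (unit costs,
incidence curves, stage distributions, utilities, cascade parameters, PSA
settings) lives in a validated YAML configuration, and every stage of the
pipeline is an importable, tested function.

## What it computes

1. **Diagnostic pathways** (`lynchcea.diagnostics`) — each patient's tumour
   profile is pushed through each strategy's decision tree, accumulating
   unit costs (microcosting-based, labour scaled by the 2.08 on-cost
   factor) and determining whether a true carrier is identified.
2. **Lifetime extrapolation** (`lynchcea.markov`) — a yearly-cycle Markov
   cohort model with states {alive without CRC, CRC stage I–IV (tunnel
   states), CRC survivor, dead}.  Surveillance multiplies CRC incidence by
   a hazard ratio (base 0.387) and shifts stage at diagnosis; QALYs use an
   age-declining utility profile with a 0.789 multiplier in stage IV; costs
   and QALYs are discounted at 3.5%/year.
3. **Cascade testing** (`lynchcea.cascade`) — per identified proband, 6
   relatives see a GP, 4.7 are counselled, 3.3 are tested and 1.5 are
   diagnosed and start surveillance, modelled over a 5-ages × 2-sexes grid.
4. **Cost-effectiveness** (`lynchcea.cea`) — dominance / extended-dominance
   frontier with ICERs computed against the next most effective strategy on
   the frontier; combined non-parametric bootstrap + probabilistic
   sensitivity analysis (200 iterations by default); credible intervals and
   cost-effectiveness acceptability curves from net monetary benefit.

Patient-level data from the underlying diagnostic-accuracy study are not
public, so `lynchcea.population` provides a deterministic 500-patient
reconstruction matching every published marginal (16 Lynch cases split
8 *MSH6* / 4 *MSH2* / 2 *MLH1* / 2 *PMS2*, mean ages 54 vs 63.5, 9/16
MSI-high Lynch tumours, PREMM₅ computable for 299 patients, ...) plus a
seeded random cohort generator for larger synthetic populations.

## Worked example

```python
from lynchcea import (Scope, evaluate_strategies, frontier,
                      petals_fixture, render_table3)

cohort = petals_fixture()
outcomes = evaluate_strategies(cohort, scope=Scope.DIAGNOSTIC_ONLY)
print(render_table3(short_term=(outcomes, frontier(outcomes))))
```

prints

```
Deterministic base case cost-effectiveness analysis

Short-term                                   Cost (£)      Cases          ICER (£/case)
Strategy 0: No testing                              0          0                      —
Strategy 2: MSI and MLH1 methylation           27,523          9              Dominated
Strategy 1: MSI                                41,512          9              Dominated
Strategy 3: IHC and MLH1 methylation           27,183         16                  1,699
Strategy 4: Direct NGS                        127,125         16              Dominated
```

Reading: testing all 500 patients by direct NGS costs £127,125 and finds
all 16 carriers; MSI-based triage is both more expensive and less sensitive
(it misses the 7 carriers — mostly *MSH6* — whose tumours are not
MSI-high); IHC + methylation triage finds all 16 for £27,183, i.e., £1,699
per Lynch syndrome case identified versus no testing.  Every other testing
strategy is dominated.

The same engine runs from the shell:

```sh
lynchcea evaluate                      # the table above
lynchcea evaluate --scope proband_plus_relatives
lynchcea psa --iterations 200 --seed 17
lynchcea scenarios                     # age/PREMM5 prefilters, 2-antibody panel, MSI-L
lynchcea extrapolate --genotype path_MLH1 --age 34 --surveillance
```

e.g. `lynchcea psa --iterations 20 --seed 3` reports

```
ICER (S3 vs S0) 95% CrI: 1,189 to 2,776
P(S3 dominates other testing strategies) = 0.500
```

Lifetime results depend on incidence/survival/utility tables shipped as
documented placeholders (the source appendix is not public); see
`docs/methods.md` for what is anchored and what is not.

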
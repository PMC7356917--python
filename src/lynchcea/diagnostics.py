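"""Per-patient diagnostic pathway simulation for five testing strategies.

Strategies (S0-S4):

* **S0** — no testing for Lynch syndrome.
* **S1** — MSI triage; MSI-high tumours proceed to germline NGS.
* **S2** — MSI triage, then *MLH1* methylation testing of MSI-positive
  tumours; hypermethylated cases are discharged, the rest proceed to NGS.
* **S3** — the Manchester approach: four-protein MMR IHC; tumours with
  complete MLH1/PMS2 loss (MSH2/MSH6 expressed) undergo methylation testing
  and are discharged if hypermethylated; MSH2/MSH6 loss, or MLH1/PMS2 loss
  unexplained by methylation, mandates NGS.  Patchy staining counts as
  expressed.
* **S4** — direct germline NGS for everyone.

Germline NGS is treated as definitive: it finds a pathogenic variant if and
only if the patient truly carries one, and only variant-positive patients
are referred for post-test genetic counselling.  A tumour whose methylation
status was never ascertained is assumed not hypermethylated when a strategy
would have tested it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError
from .population import (
    Expression,
    Methylation,
    MSIStatus,
    Proband,
    PREMM5_THRESHOLD,
)


class Strategy(str, Enum):
    S0_NO_TESTING = "S0_no_testing"
    S1_MSI = "S1_msi"
    S2_MSI_METH = "S2_msi_meth"
    S3_MANCHESTER = "S3_manchester"
    S4_DIRECT_NGS = "S4_direct_ngs"


ALL_STRATEGIES = tuple(Strategy)


class CounsellingVariant(str, Enum):
    BASE = "base"                    # microcosting-based counselling costs
    ALT_428_403 = "alt_428_403"      # £428 first visit / £403 follow-up
    NHS_REFERENCE = "nhs_reference"  # flat lifetime-cost uplift (see config)


@dataclass(frozen=True)
class ScenarioOptions:
    """Scenario toggles; age and PREMM5 prefilters are mutually exclusive."""

    age_filter_under70: bool = False
    premm5_filter: bool = False
    two_antibody_panel: bool = False
    msi_low_positive: bool = False
    counselling_cost_variant: CounsellingVariant = CounsellingVariant.BASE
    # how to treat patients whose PREMM5 score cannot be computed under the
    # PREMM5 prefilter: excluded from testing (default) or tested anyway
    premm5_missing_eligible: bool = False

    def __post_init__(self) -> None:
        if self.age_filter_under70 and self.premm5_filter:
            raise ValidationError("age and PREMM5 prefilters are evaluated separately")


BASE_SCENARIO = ScenarioOptions()


@dataclass(frozen=True)
class UnitCosts:
    """Diagnostic unit costs in 2016/17 GBP.

    Salary-based items already include the 2.08 labour on-cost factor
    (pension, National Insurance, overheads).  The two-antibody IHC panel is
    assumed to cost half the four-antibody panel.
    """

    premm5_calc: float = 3.58
    ihc4: float = 30.36
    ihc2: float = 15.18
    msi: float = 36.63
    meth_s2: float = 22.84
    meth_s3: float = 32.65
    ngs_consent: float = 13.64
    ngs: float = 236.35
    counsel_post_proband: float = 133.15
    counsel_pre_relative: float = 171.73
    predictive_test_relative: float = 166.32
    counsel_post_relative: float = 133.15
    labour_oncost_factor: float = 2.08
    # alternative counselling tariffs (scenario analysis)
    counsel_first_visit_alt: float = 428.0
    counsel_followup_alt: float = 403.0
    # flat per-participant lifetime uplift under NHS reference counselling costs
    nhs_reference_delta: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "premm5_calc", "ihc4", "ihc2", "msi", "meth_s2", "meth_s3",
            "ngs_consent", "ngs", "counsel_post_proband", "counsel_pre_relative",
            "predictive_test_relative", "counsel_post_relative",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"unit cost {name} must be non-negative")
        if self.labour_oncost_factor <= 0:
            raise ValidationError("labour on-cost factor must be positive")


def effective_counselling(costs: UnitCosts, opts: ScenarioOptions) -> tuple[float, float, float]:
    """(proband post-test, relative pre-test, relative post-test) counselling costs."""
    if opts.counselling_cost_variant is CounsellingVariant.ALT_428_403:
        return (
            costs.counsel_first_visit_alt,
            costs.counsel_first_visit_alt,
            costs.counsel_followup_alt,
        )
    return (
        costs.counsel_post_proband,
        costs.counsel_pre_relative,
        costs.counsel_post_relative,
    )


@dataclass(frozen=True)
class DiagnosticOutcome:
    """Tests performed, cost incurred and identification result for one patient."""

    tests_performed: tuple[str, ...]
    diagnostic_cost: float
    identified: bool
    truth: bool


def apply_labour_oncost(salary_component: float, factor: float = 2.08) -> float:
    """Inflate a salary cost to a full labour cost (on-costs and overheads)."""
    if salary_component < 0:
        raise ValidationError("salary component must be non-negative")
    if factor <= 0:
        raise ValidationError("on-cost factor must be positive")
    return salary_component * factor


def apply_prefilter(
    p: Proband, opts: ScenarioOptions, costs: UnitCosts
) -> tuple[bool, float]:
    """Clinical-criteria gate applied before any tumour testing.

    The age filter is free; the PREMM5 filter charges the score-calculation
    cost to every patient with a computable score, eligible or not.
    Patients without family history default to ineligible under the PREMM5
    filter.
    """
    if opts.age_filter_under70:
        return p.age < 70, 0.0
    if opts.premm5_filter:
        if p.premm5 is None:
            return opts.premm5_missing_eligible, 0.0
        return p.premm5 >= PREMM5_THRESHOLD, costs.premm5_calc
    return True, 0.0


def _is_absent(expr: Expression) -> bool:
    # patchy staining counts as expressed: only complete loss is a positive
    return expr is Expression.ABSENT


def simulate_pathway(
    p: Proband,
    s: Strategy,
    opts: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
) -> DiagnosticOutcome:
    """Run one patient through one strategy's decision tree."""
    if not isinstance(s, Strategy):
        raise ValidationError(f"unknown strategy: {s!r}")
    truth = p.has_lynch
    tests: list[str] = []
    cost = 0.0
    reaches_ngs = False
    t = p.tumour
    counsel_proband, _, _ = effective_counselling(costs, opts)

    if s is Strategy.S0_NO_TESTING:
        return DiagnosticOutcome((), 0.0, False, truth)

    if s in (Strategy.S1_MSI, Strategy.S2_MSI_METH):
        tests.append("msi")
        cost += costs.msi
        positive = t.msi is MSIStatus.MSI_H or (
            opts.msi_low_positive and t.msi is MSIStatus.MSI_L
        )
        if positive:
            if s is Strategy.S2_MSI_METH:
                tests.append("mlh1_methylation")
                cost += costs.meth_s2
                if t.mlh1_hypermethylated is not Methylation.YES:
                    reaches_ngs = True  # not-done counts as not hypermethylated
            else:
                reaches_ngs = True
    elif s is Strategy.S3_MANCHESTER:
        if opts.two_antibody_panel:
            tests.append("ihc2")
            cost += costs.ihc2
            msh2_side = _is_absent(t.ihc_msh6)
            mlh1_side = _is_absent(t.ihc_pms2)
        else:
            tests.append("ihc4")
            cost += costs.ihc4
            msh2_side = _is_absent(t.ihc_msh2) or _is_absent(t.ihc_msh6)
            mlh1_side = _is_absent(t.ihc_mlh1) or _is_absent(t.ihc_pms2)
        if msh2_side:
            # MSH2/MSH6 loss mandates NGS directly, even with concurrent
            # MLH1/PMS2 loss (no methylation test can explain it away)
            reaches_ngs = True
        elif mlh1_side:
            tests.append("mlh1_methylation")
            cost += costs.meth_s3
            if t.mlh1_hypermethylated is not Methylation.YES:
                reaches_ngs = True
    elif s is Strategy.S4_DIRECT_NGS:
        reaches_ngs = True

    identified = False
    if reaches_ngs:
        tests.extend(["ngs_consent", "ngs"])
        cost += costs.ngs_consent + costs.ngs
        if truth:  # NGS is definitive; variant found -> counselling referral
            identified = True
            tests.append("post_test_counselling")
            cost += counsel_proband
    return DiagnosticOutcome(tuple(tests), cost, identified, truth)


def cohort_totals(
    cohort: Iterable[Proband],
    s: Strategy,
    opts: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
) -> tuple[float, int]:
    """Total diagnostic cost (prefilter costs included) and cases identified."""
    total = 0.0
    identified = 0
    for p in cohort:
        eligible, pre_cost = apply_prefilter(p, opts, costs)
        total += pre_cost
        if eligible:
            outcome = simulate_pathway(p, s, opts, costs)
            total += outcome.diagnostic_cost
            identified += outcome.identified
    return total, identified


def cohort_outcomes(
    cohort: Iterable[Proband],
    s: Strategy,
    opts: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
) -> list[tuple[Proband, Optional[DiagnosticOutcome], float]]:
    """Per-patient (proband, outcome-or-None-if-filtered, prefilter cost)."""
    results = []
    for p in cohort:
        eligible, pre_cost = apply_prefilter(p, opts, costs)
        outcome = simulate_pathway(p, s, opts, costs) if eligible else None
        results.append((p, outcome, pre_cost))
    return results


def outcomes_to_frame(
    cohort: Iterable[Proband],
    strategies: Iterable[Strategy] = ALL_STRATEGIES,
    opts: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
) -> pd.DataFrame:
    """Long-format per-patient outcome table (one row per patient/strategy)."""
    rows = []
    for s in strategies:
        for p, outcome, pre_cost in cohort_outcomes(cohort, s, opts, costs):
            rows.append(
                {
                    "id": p.id,
                    "strategy": s.value,
                    "eligible": outcome is not None,
                    "tests": ";".join(outcome.tests_performed) if outcome else "",
                    "cost": (outcome.diagnostic_cost if outcome else 0.0) + pre_cost,
                    "identified": bool(outcome.identified) if outcome else False,
                }
            )
    return pd.DataFrame(rows)
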
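"""Cascade testing of relatives after a proband's Lynch syndrome diagnosis.

Per diagnosed proband, on average 6.0 relatives see a general practitioner,
4.7 attend pre-test genetic counselling, 3.3 take a predictive genetic test
and 1.5 are diagnosed with Lynch syndrome.  Diagnosed relatives start
colonoscopic surveillance; their ages are the five quintile means of a
regional genetics-service cohort (24.5, 35.7, 45.0, 53.2, 66.8 years) and
both sexes are modelled, giving a 5 x 2 x 5 grid of 50 unique
age/sex/genotype profiles for lifetime extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import pandas as pd

from .diagnostics import ScenarioOptions, UnitCosts, effective_counselling
from .errors import ValidationError
from .markov import MarkovParams, surveillance_benefit
from .population import Genotype, PATHOGENIC_GENOTYPES

SEXES = ("female", "male")
DEFAULT_QUINTILE_AGES = (24.5, 35.7, 45.0, 53.2, 66.8)


@dataclass(frozen=True)
class CascadeParams:
    relatives_gp: float = 6.0          # GP appointments per proband
    relatives_counselled: float = 4.7  # attend pre-test counselling
    relatives_tested: float = 3.3      # take a predictive genetic test
    relatives_diagnosed: float = 1.5   # diagnosed with Lynch syndrome
    gp_visit_cost: float = 38.0        # national unit cost; not from microcosting
    quintile_ages: tuple = DEFAULT_QUINTILE_AGES
    sexes: tuple = SEXES
    # post-test counselling for every tested relative (default) or only
    # those diagnosed
    counsel_all_tested: bool = True

    def __post_init__(self) -> None:
        counts = (
            self.relatives_diagnosed,
            self.relatives_tested,
            self.relatives_counselled,
            self.relatives_gp,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("relative counts must be non-negative")
        if not (
            self.relatives_diagnosed
            <= self.relatives_tested
            <= self.relatives_counselled
            <= self.relatives_gp
        ):
            raise ValidationError("relative counts must satisfy diagnosed <= tested <= counselled <= GP")
        ages = self.quintile_ages
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("quintile ages must be strictly increasing")


@dataclass(frozen=True)
class RelativeProfile:
    age: float
    sex: str
    genotype: Genotype


def relative_grid(params: CascadeParams = CascadeParams()) -> list[RelativeProfile]:
    """All age x sex x genotype combinations (50 with the defaults)."""
    genotypes = (Genotype.SPORADIC,) + PATHOGENIC_GENOTYPES
    return [
        RelativeProfile(age=a, sex=s, genotype=g)
        for a in params.quintile_ages
        for s in params.sexes
        for g in genotypes
    ]


def cascade_cost_per_proband(
    params: CascadeParams = CascadeParams(),
    costs: UnitCosts = UnitCosts(),
    opts: Optional[ScenarioOptions] = None,
) -> float:
    """Testing-and-counselling cost triggered by one identified proband."""
    opts = opts if opts is not None else ScenarioOptions()
    _, pre_rel, post_rel = effective_counselling(costs, opts)
    n_post = params.relatives_tested if params.counsel_all_tested else params.relatives_diagnosed
    return (
        params.relatives_gp * params.gp_visit_cost
        + params.relatives_counselled * pre_rel
        + params.relatives_tested * costs.predictive_test_relative
        + n_post * post_rel
    )


def cascade_lifetime_outcomes(
    params: CascadeParams,
    markov_params: MarkovParams,
    proband_genotype: Genotype,
    costs: UnitCosts = UnitCosts(),
    opts: Optional[ScenarioOptions] = None,
    _benefit: Optional[Callable] = None,
) -> tuple[float, float]:
    """(Δ costs, Δ QALYs) per proband diagnosed with Lynch syndrome.

    The 1.5 diagnosed relatives carry the proband's (family) variant and
    receive surveillance; their benefit is the equal-weights average over
    the ten age/sex profiles of the grid restricted to that genotype.
    Testing costs are charged once, in the diagnosis cycle (undiscounted).
    ``_benefit`` may supply a cached surveillance_benefit implementation.
    """
    if proband_genotype is Genotype.SPORADIC:
        raise ValidationError("cascade surveillance requires a pathogenic proband genotype")
    benefit = _benefit or (
        lambda g, a, s: surveillance_benefit(g, a, s, markov_params)
    )
    d_cost_sum = 0.0
    d_qaly_sum = 0.0
    n = 0
    for age in params.quintile_ages:
        for sex in params.sexes:
            _, dq, dc = benefit(proband_genotype, int(round(age)), sex)
            d_cost_sum += dc
            d_qaly_sum += dq
            n += 1
    d_cost = cascade_cost_per_proband(params, costs, opts)
    d_cost += params.relatives_diagnosed * d_cost_sum / n
    d_qaly = params.relatives_diagnosed * d_qaly_sum / n
    return d_cost, d_qaly


def grid_to_frame(
    params: CascadeParams, markov_params: MarkovParams
) -> pd.DataFrame:
    """Per-profile surveillance benefit table for the full relative grid."""
    rows = []
    for prof in relative_grid(params):
        if prof.genotype is Genotype.SPORADIC:
            dly = dq = dc = float("nan")
        else:
            dly, dq, dc = surveillance_benefit(
                prof.genotype, int(round(prof.age)), prof.sex, markov_params
            )
        rows.append(
            {
                "age": prof.age,
                "sex": prof.sex,
                "genotype": prof.genotype.value,
                "delta_life_years": dly,
                "delta_qalys": dq,
                "delta_costs": dc,
            }
        )
    return pd.DataFrame(rows)
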
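"""Lifetime extrapolation by a yearly-cycle Markov cohort model.

An individual with a given MMR genotype, age and sex occupies one of:

* ``alive_no_CRC`` — at risk of colorectal cancer (CRC), with the annual
  incidence depending on genotype, age and sex;
* ``CRC stage I-IV`` — tunnel states tracking time since diagnosis; a
  stage-specific excess mortality applies for a fixed number of years
  (default 5), after which survivors revert to background mortality;
* ``CRC survivor``, ``dead (CRC)``, ``dead (other causes)``.

Colonoscopic surveillance (for diagnosed Lynch syndrome) acts in two ways:
it multiplies CRC incidence by a hazard ratio (base case 0.387, worst case
0.929) and shifts the stage distribution at diagnosis towards earlier
stages.  Costs cover scheduled colonoscopies and stage/age-dependent CRC
treatment; health is accrued as quality-adjusted life years with an
age-declining utility profile, scaled by 0.789 while in stage IV.  Costs
and QALYs are discounted at 3.5% per year; life expectancy is not
discounted.

The incidence, survival, background-mortality and utility tables shipped as
defaults are documented placeholders calibrated to plausible magnitudes
(see docs/methods.md); only the quantities printed above are anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import Genotype

STAGES = ("I", "II", "III", "IV")

# ---------------------------------------------------------------------------
# Default parameter tables (placeholders except where noted)
# ---------------------------------------------------------------------------

# Annual CRC incidence by genotype and age band [(age_lo, rate), ...];
# the rate applies from age_lo until the next band.  Pathogenic-variant
# rates are ordered MLH1 > MSH2 > MSH6 > PMS2, as in the penetrance
# literature; sporadic rates are population-scale.
DEFAULT_INCIDENCE = {
    "sporadic": [(0, 0.0), (30, 0.0002), (50, 0.001), (60, 0.002), (70, 0.003)],
    "path_MLH1": [(0, 0.0), (25, 0.008), (40, 0.015), (50, 0.02), (70, 0.015)],
    "path_MSH2": [(0, 0.0), (25, 0.006), (40, 0.012), (50, 0.016), (70, 0.012)],
    "path_MSH6": [(0, 0.0), (30, 0.002), (40, 0.005), (50, 0.008), (70, 0.007)],
    "path_PMS2": [(0, 0.0), (35, 0.001), (50, 0.003), (60, 0.004), (70, 0.004)],
}

# Stage distribution at diagnosis. These ARE anchored: normalised from the
# published expected stage-specific CRC counts with and without surveillance
# (1.2/3.1/1.3/0.7 undetected-early vs 2.2/0.4/0.4/0.3 under surveillance).
DEFAULT_STAGE_DIST_NOSURV = [1.2 / 6.3, 3.1 / 6.3, 1.3 / 6.3, 0.7 / 6.3]
DEFAULT_STAGE_DIST_SURV = [2.2 / 3.3, 0.4 / 3.3, 0.4 / 3.3, 0.3 / 3.3]

# Annual probability of CRC death during the excess-mortality window.
DEFAULT_STAGE_MORTALITY = [0.02, 0.06, 0.15, 0.45]

# CRC treatment cost by age band and stage (charged once at diagnosis),
# spanning the cited range £807 (80+, stage IV) to £14,490 (40-49, stage III).
DEFAULT_CRC_COST = {
    0: [6500.0, 10500.0, 14000.0, 12500.0],
    40: [6800.0, 11000.0, 14490.0, 13000.0],
    50: [6400.0, 10400.0, 13800.0, 12000.0],
    60: [5900.0, 9600.0, 12600.0, 10400.0],
    70: [4900.0, 8000.0, 10300.0, 7400.0],
    80: [3400.0, 5400.0, 6900.0, 807.0],
}

# Gompertz-style annual background mortality q(age) = a * exp(b * age).
DEFAULT_BACKGROUND_MORTALITY = {"a": 1.0e-5, "b": 0.105, "male_factor": 1.5}

# Utility declines linearly with age from `base` at age 20 down to `floor`.
DEFAULT_UTILITY_PROFILE = {"base": 0.95, "decline_per_year": 0.0022, "floor": 0.3}


@dataclass(frozen=True)
class MarkovParams:
    """All transition, cost and utility inputs for lifetime extrapolation."""

    incidence: dict = field(default_factory=lambda: dict(DEFAULT_INCIDENCE))
    male_incidence_factor: float = 1.2
    surveillance_hr: float = 0.387
    stage_dist_surv: tuple = tuple(DEFAULT_STAGE_DIST_SURV)
    stage_dist_nosurv: tuple = tuple(DEFAULT_STAGE_DIST_NOSURV)
    stage_mortality: tuple = tuple(DEFAULT_STAGE_MORTALITY)
    excess_mortality_years: int = 5
    background_mortality: dict = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_MORTALITY)
    )
    utility_profile: dict = field(default_factory=lambda: dict(DEFAULT_UTILITY_PROFILE))
    stage4_utility_multiplier: float = 0.789
    colonoscopy_cost: float = 583.0
    colonoscopy_interval: int = 2
    crc_cost: dict = field(default_factory=lambda: dict(DEFAULT_CRC_COST))
    discount_rate: float = 0.035
    max_age: int = 100
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("stage_dist_surv", "stage_dist_nosurv"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,) or (v < 0).any() or (v > 1).any():
                raise ValidationError(f"{name} must be 4 probabilities in [0,1]")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValidationError(f"{name} must sum to 1 (got {v.sum()!r})")
        if not (0.0 < self.surveillance_hr <= 1.0):
            raise ValidationError("surveillance_hr must lie in (0, 1]")
        m = np.asarray(self.stage_mortality, dtype=float)
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("stage mortality entries must be probabilities")
        if self.stage4_utility_multiplier < 0 or self.stage4_utility_multiplier > 1:
            raise ValidationError("stage4_utility_multiplier must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValidationError("discount rate must be non-negative")
        if self.colonoscopy_interval < 1 or self.excess_mortality_years < 1:
            raise ValidationError("intervals must be >= 1 year")

    # -- state indexing ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return 4 * self.excess_mortality_years + 4

    def state_index(self, name: str, stage: int = 0, year: int = 0) -> int:
        Y = self.excess_mortality_years
        if name == "alive_no_crc":
            return 0
        if name == "crc":
            return 1 + stage * Y + year
        if name == "survivor":
            return 1 + 4 * Y
        if name == "dead_crc":
            return 2 + 4 * Y
        if name == "dead_other":
            return 3 + 4 * Y
        raise ValidationError(f"unknown state {name!r}")

    # -- parameter lookups ------------------------------------------------

    def incidence_rate(self, genotype: Genotype, age: int, sex: str) -> float:
        bands = self.incidence[
            genotype.value if isinstance(genotype, Genotype) else str(genotype)
        ]
        rate = 0.0
        for lo, r in bands:
            if age >= lo:
                rate = r
        if sex == "male":
            rate *= self.male_incidence_factor
        return rate

    def background_q(self, age: int, sex: str) -> float:
        bm = self.background_mortality
        q = bm["a"] * math.exp(bm["b"] * age)
        if sex == "male":
            q *= bm.get("male_factor", 1.0)
        return min(q, 1.0)

    def utility(self, age: int) -> float:
        up = self.utility_profile
        u = up["base"] - up["decline_per_year"] * max(age - 20, 0)
        return float(min(1.0, max(up["floor"], u)))

    def crc_treatment_cost(self, age: int, stage: int) -> float:
        row = None
        for lo in sorted(self.crc_cost):
            if age >= lo:
                row = self.crc_cost[lo]
        if row is None:
            row = self.crc_cost[min(self.crc_cost)]
        return float(row[stage])


def transition_matrix(
    params: MarkovParams,
    genotype: Genotype,
    age: int,
    sex: str = "female",
    surveillance: bool = False,
) -> np.ndarray:
    """One-cycle stochastic matrix at the given age.

    From the at-risk state, background mortality competes with CRC onset:
    onset probability ``1 - exp(-incidence * HR)`` (HR = surveillance hazard
    ratio when under surveillance, else 1) applies to those surviving other
    causes, split across stages by the applicable stage distribution.
    """
    if age > params.max_age:
        raise ValidationError("age beyond model horizon")
    n = params.n_states
    Y = params.excess_mortality_years
    P = np.zeros((n, n))

    q = params.background_q(age, sex)
    inc = params.incidence_rate(genotype, age, sex)
    hr = params.surveillance_hr if surveillance else 1.0
    p_onset = 1.0 - math.exp(-inc * hr)
    sd = np.asarray(
        params.stage_dist_surv if surveillance else params.stage_dist_nosurv
    )

    i_alive = params.state_index("alive_no_crc")
    i_surv = params.state_index("survivor")
    i_dcrc = params.state_index("dead_crc")
    i_doth = params.state_index("dead_other")

    P[i_alive, i_doth] = q
    for s in range(4):
        P[i_alive, params.state_index("crc", s, 0)] = (1 - q) * p_onset * sd[s]
    P[i_alive, i_alive] = (1 - q) * (1 - p_onset)

    for s in range(4):
        e = params.stage_mortality[s]
        for y in range(Y):
            i = params.state_index("crc", s, y)
            P[i, i_dcrc] = e
            P[i, i_doth] = (1 - e) * q
            nxt = params.state_index("crc", s, y + 1) if y + 1 < Y else i_surv
            P[i, nxt] = (1 - e) * (1 - q)

    P[i_surv, i_doth] = q
    P[i_surv, i_surv] = 1 - q
    P[i_dcrc, i_dcrc] = 1.0
    P[i_doth, i_doth] = 1.0

    if (P < -1e-15).any() or (P > 1 + 1e-15).any():
        raise ValidationError("transition probabilities outside [0, 1]")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ValidationError("transition matrix rows must sum to 1")
    return P


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accruals of one extrapolation."""

    ages: np.ndarray              # cycle start ages, length n_cycles
    occupancy: np.ndarray         # (n_cycles + 1, n_states), row 0 = start
    disc_costs: np.ndarray        # discounted cost accrued each cycle
    disc_qalys: np.ndarray        # discounted QALYs accrued each cycle
    undisc_qalys: np.ndarray
    onset_by_stage: np.ndarray    # (n_cycles, 4) undiscounted incident flow
    alive_person_years: np.ndarray
    params: MarkovParams

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "age": self.ages,
                "disc_cost": self.disc_costs,
                "disc_qaly": self.disc_qalys,
                "alive": self.alive_person_years,
            }
        )
        for s, name in enumerate(STAGES):
            df[f"onset_stage_{name}"] = self.onset_by_stage[:, s]
        return df


@dataclass(frozen=True)
class ExtrapolationResult:
    life_years: float        # undiscounted
    qalys: float             # discounted
    costs: float             # discounted
    crc_count_by_stage: tuple

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValidationError("discounted QALYs cannot exceed life years")


def run_cohort(
    genotype: Genotype,
    start_age: int,
    sex: str = "female",
    surveillance: bool = False,
    params: MarkovParams = MarkovParams(),
) -> CohortTrace:
    """Extrapolate from ``start_age`` to ``max_age`` in yearly cycles.

    Accruals happen at cycle start (no half-cycle correction by default):
    utilities weighted by occupancy, colonoscopy costs on schedule for the
    at-risk state under surveillance, and CRC treatment costs charged to the
    incident flow at diagnosis.
    """
    if start_age >= params.max_age:
        raise ValidationError("start_age must be below max_age")
    n_cycles = params.max_age - start_age
    n = params.n_states
    Y = params.excess_mortality_years
    i_alive = params.state_index("alive_no_crc")
    i_surv = params.state_index("survivor")
    dead = {params.state_index("dead_crc"), params.state_index("dead_other")}
    alive_idx = [i for i in range(n) if i not in dead]
    stage4_idx = [params.state_index("crc", 3, y) for y in range(Y)]

    v = np.zeros(n)
    v[i_alive] = 1.0
    occupancy = np.zeros((n_cycles + 1, n))
    occupancy[0] = v
    disc_costs = np.zeros(n_cycles)
    disc_qalys = np.zeros(n_cycles)
    undisc_qalys = np.zeros(n_cycles)
    onset = np.zeros((n_cycles, 4))
    alive_py = np.zeros(n_cycles)
    ages = np.arange(start_age, params.max_age)

    hcc = 0.5 if params.half_cycle_correction else 0.0
    for t in range(n_cycles):
        age = int(ages[t])
        d = 1.0 / (1.0 + params.discount_rate) ** (t + hcc)
        u = params.utility(age)
        state_u = np.zeros(n)
        state_u[alive_idx] = u
        state_u[stage4_idx] = u * params.stage4_utility_multiplier
        q_cycle = float(v @ state_u)
        undisc_qalys[t] = q_cycle
        disc_qalys[t] = q_cycle * d
        alive_py[t] = v[alive_idx].sum()

        cost = 0.0
        if surveillance and t % params.colonoscopy_interval == 0:
            cost += v[i_alive] * params.colonoscopy_cost

        P = transition_matrix(params, genotype, age, sex, surveillance)
        flow = v[i_alive] * P[i_alive, [params.state_index("crc", s, 0) for s in range(4)]]
        onset[t] = flow
        for s in range(4):
            cost += flow[s] * params.crc_treatment_cost(age, s)
        disc_costs[t] = cost * d
        v = P.T @ v
        occupancy[t + 1] = v
        total = v.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValidationError("occupancy not conserved")

    return CohortTrace(
        ages=ages,
        occupancy=occupancy,
        disc_costs=disc_costs,
        disc_qalys=disc_qalys,
        undisc_qalys=undisc_qalys,
        onset_by_stage=onset,
        alive_person_years=alive_py,
        params=params,
    )


def crc_counts(trace: CohortTrace) -> tuple:
    """Expected lifetime incident colorectal cancers by stage."""
    return tuple(trace.onset_by_stage.sum(axis=0))


def summarise(trace: CohortTrace) -> ExtrapolationResult:
    return ExtrapolationResult(
        life_years=float(trace.alive_person_years.sum()),
        qalys=float(trace.disc_qalys.sum()),
        costs=float(trace.disc_costs.sum()),
        crc_count_by_stage=crc_counts(trace),
    )


def extrapolate(
    genotype: Genotype,
    start_age: int,
    sex: str = "female",
    surveillance: bool = False,
    params: MarkovParams = MarkovParams(),
) -> ExtrapolationResult:
    return summarise(run_cohort(genotype, start_age, sex, surveillance, params))


def surveillance_benefit(
    genotype: Genotype,
    start_age: int,
    sex: str = "female",
    params: MarkovParams = MarkovParams(),
) -> tuple[float, float, float]:
    """(Δ life years, Δ QALYs, Δ costs) of colonoscopic surveillance.

    Defined only for pathogenic genotypes: surveillance is offered on a
    Lynch syndrome diagnosis.
    """
    if genotype is Genotype.SPORADIC:
        raise ValidationError("surveillance benefit undefined for sporadic genotype")
    with_s = extrapolate(genotype, start_age, sex, True, params)
    without = extrapolate(genotype, start_age, sex, False, params)
    return (
        with_s.life_years - without.life_years,
        with_s.qalys - without.qalys,
        with_s.costs - without.costs,
    )
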
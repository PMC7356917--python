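"""Cost-effectiveness engine: frontier, ICERs, bootstrap + PSA, CEAC.

The frontier algorithm sorts strategies by effectiveness, removes strictly
dominated strategies (another strategy no more costly and no less effective,
with at least one strict inequality; equal-effect ties keep the cheaper),
then removes extendedly dominated strategies until the incremental
cost-effectiveness ratios (ICERs) along the frontier strictly increase.

Uncertainty is handled by a combined non-parametric bootstrap (the cohort
is resampled with replacement) and probabilistic sensitivity analysis (each
iteration re-runs the model with one joint draw of the parameters: gamma
for costs, beta for probabilities and utilities, lognormal for hazard
ratios, Dirichlet for stage distributions).  Cost-effectiveness
acceptability curves report, per willingness-to-pay threshold, the fraction
of iterations in which a strategy's net monetary benefit exceeds the
comparator's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeParams, cascade_lifetime_outcomes, relative_grid
from .diagnostics import (
    ALL_STRATEGIES,
    BASE_SCENARIO,
    CounsellingVariant,
    ScenarioOptions,
    Strategy,
    UnitCosts,
    cohort_outcomes,
)
from .errors import ValidationError
from .markov import MarkovParams, extrapolate
from .population import Genotype, Proband


class Scope(str, Enum):
    DIAGNOSTIC_ONLY = "diagnostic_only"
    PROBAND_ONLY = "proband_only"
    PROBAND_PLUS_RELATIVES = "proband_plus_relatives"


@dataclass(frozen=True)
class StrategyOutcome:
    """Cohort-level cost and effect for one strategy.

    For the diagnostic scope, ``cost`` is the cohort total in £ and
    ``effect`` the number of Lynch syndrome cases identified; for lifetime
    scopes they are per-participant means (£ and QALYs).
    """

    strategy: Strategy
    cost: float
    effect: float
    scope: Scope

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cost) and math.isfinite(self.effect)):
            raise ValidationError("cost and effect must be finite")


class Classification(str, Enum):
    ON_FRONTIER = "on_frontier"
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class FrontierResult:
    classification: dict          # Strategy -> Classification
    icers: dict                   # Strategy -> float (frontier strategies, bar the cheapest)
    frontier: tuple               # strategies in ascending effect order

    def icer(self, strategy: Strategy) -> Optional[float]:
        return self.icers.get(strategy)


def frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Dominance / extended-dominance classification and frontier ICERs."""
    if not outcomes:
        raise ValidationError("at least one strategy outcome required")
    scopes = {o.scope for o in outcomes}
    if len(scopes) > 1:
        raise ValidationError("outcomes must share a scope")

    ordered = sorted(outcomes, key=lambda o: (o.effect, o.cost))
    classification: dict = {}

    # strict dominance (equal-effect ties keep only the cheaper; exact
    # duplicates keep the first in sort order)
    candidates = []
    seen: set = set()
    for o in ordered:
        dominated = any(
            (other.cost <= o.cost and other.effect >= o.effect)
            and (other.cost < o.cost or other.effect > o.effect)
            for other in ordered
            if other is not o
        )
        if dominated or (o.effect, o.cost) in seen:
            classification[o.strategy] = Classification.DOMINATED
        else:
            seen.add((o.effect, o.cost))
            candidates.append(o)

    # extended dominance: drop interior strategies until ICERs strictly increase
    surviving = list(candidates)
    while True:
        if len(surviving) < 3:
            break
        removed = False
        for i in range(1, len(surviving) - 1):
            lo, mid, hi = surviving[i - 1], surviving[i], surviving[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.effect - lo.effect)
            icer_hi = (hi.cost - mid.cost) / (hi.effect - mid.effect)
            if icer_lo >= icer_hi:
                classification[mid.strategy] = Classification.EXTENDEDLY_DOMINATED
                surviving.pop(i)
                removed = True
                break
        if not removed:
            break

    icers: dict = {}
    for prev, cur in zip(surviving, surviving[1:]):
        icers[cur.strategy] = (cur.cost - prev.cost) / (cur.effect - prev.effect)
    for o in surviving:
        classification[o.strategy] = Classification.ON_FRONTIER
    return FrontierResult(
        classification=classification,
        icers=icers,
        frontier=tuple(o.strategy for o in surviving),
    )


# ---------------------------------------------------------------------------
# Deterministic strategy evaluation
# ---------------------------------------------------------------------------


def evaluate_strategies(
    cohort: Sequence[Proband],
    scenario: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
    markov_params: MarkovParams = MarkovParams(),
    cascade_params: CascadeParams = CascadeParams(),
    scope: Scope = Scope.DIAGNOSTIC_ONLY,
    strategies: Iterable[Strategy] = ALL_STRATEGIES,
) -> list[StrategyOutcome]:
    """Deterministic cohort-level cost and effect for each strategy.

    Lifetime scopes extrapolate every proband with the Markov model
    (surveillance if and only if identified); the relatives scope adds a
    strategy-independent baseline for each proband's relatives plus cascade
    testing and surveillance for relatives of identified probands.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort must be non-empty")
    cache: dict = {}

    def extrap(genotype, age, sex, surv):
        key = (genotype, age, sex, surv)
        if key not in cache:
            cache[key] = extrapolate(genotype, age, sex, surv, markov_params)
        return cache[key]

    def benefit(genotype, age, sex):
        w = extrap(genotype, age, sex, True)
        wo = extrap(genotype, age, sex, False)
        return (
            w.life_years - wo.life_years,
            w.qalys - wo.qalys,
            w.costs - wo.costs,
        )

    n = len(cohort)
    outcomes: list[StrategyOutcome] = []

    if scope is Scope.PROBAND_PLUS_RELATIVES:
        grid = relative_grid(cascade_params)
        base = [extrap(pr.genotype, int(round(pr.age)), pr.sex, False) for pr in grid]
        rel_base_cost = cascade_params.relatives_gp * float(
            np.mean([r.costs for r in base])
        )
        rel_base_qaly = cascade_params.relatives_gp * float(
            np.mean([r.qalys for r in base])
        )
        cascade_cache: dict = {}

    for s in strategies:
        per_patient = cohort_outcomes(cohort, s, scenario, costs)
        diag_cost = sum(
            (o.diagnostic_cost if o else 0.0) + pre for _, o, pre in per_patient
        )
        cases = sum(bool(o.identified) for _, o, _ in per_patient if o)
        if scope is Scope.DIAGNOSTIC_ONLY:
            outcomes.append(StrategyOutcome(s, diag_cost, cases, scope))
            continue

        cost_sum = diag_cost
        qaly_sum = 0.0
        for p, o, _ in per_patient:
            identified = bool(o.identified) if o else False
            r = extrap(p.genotype, p.age, p.sex, identified)
            cost_sum += r.costs
            qaly_sum += r.qalys
            if scope is Scope.PROBAND_PLUS_RELATIVES:
                cost_sum += rel_base_cost
                qaly_sum += rel_base_qaly
                if identified:
                    if p.genotype not in cascade_cache:
                        cascade_cache[p.genotype] = cascade_lifetime_outcomes(
                            cascade_params,
                            markov_params,
                            p.genotype,
                            costs,
                            scenario,
                            _benefit=benefit,
                        )
                    dc, dq = cascade_cache[p.genotype]
                    cost_sum += dc
                    qaly_sum += dq
        if (
            scenario.counselling_cost_variant is CounsellingVariant.NHS_REFERENCE
            and s is not Strategy.S0_NO_TESTING
        ):
            cost_sum += costs.nhs_reference_delta * n
        outcomes.append(StrategyOutcome(s, cost_sum / n, qaly_sum / n, scope))
    return outcomes


# ---------------------------------------------------------------------------
# Bootstrap + probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 200
    seed: int = 0
    cv: float = 0.15          # coefficient of variation for parameter draws
    resample: bool = True     # non-parametric bootstrap of the cohort

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.cv < 0:
            raise ValidationError("coefficient of variation must be non-negative")


def _gamma(rng, mean: float, cv: float) -> float:
    if mean == 0 or cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def _lognormal(rng, mean: float, cv: float) -> float:
    if mean == 0 or cv == 0:
        return mean
    sigma2 = math.log(1 + cv**2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _beta(rng, mean: float, cv: float) -> float:
    if cv == 0 or mean in (0.0, 1.0):
        return mean
    var = min((mean * cv) ** 2, mean * (1 - mean) * 0.99)
    k = mean * (1 - mean) / var - 1
    return float(rng.beta(mean * k, (1 - mean) * k))


def _dirichlet(rng, probs, cv: float):
    if cv == 0:
        return tuple(probs)
    conc = np.asarray(probs) / cv**2
    draw = rng.dirichlet(np.maximum(conc, 1e-6))
    return tuple(float(x) for x in draw)


def draw_parameters(
    rng: np.random.Generator,
    costs: UnitCosts,
    markov_params: MarkovParams,
    cv: float,
) -> tuple[UnitCosts, MarkovParams]:
    """One joint PSA draw: gamma costs, beta probabilities/utilities,
    lognormal hazard ratio and incidence scale, Dirichlet stage splits."""
    if cv == 0:
        return costs, markov_params
    cost_fields = (
        "premm5_calc", "ihc4", "ihc2", "msi", "meth_s2", "meth_s3",
        "ngs_consent", "ngs", "counsel_post_proband", "counsel_pre_relative",
        "predictive_test_relative", "counsel_post_relative",
    )
    new_costs = replace(
        costs, **{f: _gamma(rng, getattr(costs, f), cv) for f in cost_fields}
    )
    inc_scale = _lognormal(rng, 1.0, cv)
    incidence = {
        g: [(lo, r * inc_scale) for lo, r in bands]
        for g, bands in markov_params.incidence.items()
    }
    crc_scale = _gamma(rng, 1.0, cv)
    crc_cost = {
        lo: [c * crc_scale for c in row] for lo, row in markov_params.crc_cost.items()
    }
    new_mp = replace(
        markov_params,
        incidence=incidence,
        surveillance_hr=min(_lognormal(rng, markov_params.surveillance_hr, cv), 1.0),
        stage_dist_surv=_dirichlet(rng, markov_params.stage_dist_surv, cv),
        stage_dist_nosurv=_dirichlet(rng, markov_params.stage_dist_nosurv, cv),
        stage_mortality=tuple(
            _beta(rng, m, cv) for m in markov_params.stage_mortality
        ),
        stage4_utility_multiplier=_beta(
            rng, markov_params.stage4_utility_multiplier, cv
        ),
        colonoscopy_cost=_gamma(rng, markov_params.colonoscopy_cost, cv),
        crc_cost=crc_cost,
    )
    return new_costs, new_mp


@dataclass
class PSAResult:
    strategies: tuple
    scope: Scope
    costs: np.ndarray    # (n_iterations, n_strategies)
    effects: np.ndarray  # (n_iterations, n_strategies)
    seed: int

    def _col(self, strategy: Strategy) -> int:
        return self.strategies.index(strategy)

    def increments(self, strategy: Strategy, comparator: Strategy):
        i, j = self._col(strategy), self._col(comparator)
        return self.costs[:, i] - self.costs[:, j], self.effects[:, i] - self.effects[:, j]

    def icer_samples(self, strategy: Strategy, comparator: Strategy) -> np.ndarray:
        """Per-iteration ICERs; iterations with Δeffect <= 0 are excluded."""
        dc, de = self.increments(strategy, comparator)
        mask = de > 0
        return dc[mask] / de[mask]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in range(self.costs.shape[0]):
            for k, s in enumerate(self.strategies):
                rows.append(
                    {
                        "iteration": it,
                        "strategy": s.value,
                        "cost": self.costs[it, k],
                        "effect": self.effects[it, k],
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_psa(
    cohort: Sequence[Proband],
    config: PSAConfig = PSAConfig(),
    scenario: ScenarioOptions = BASE_SCENARIO,
    costs: UnitCosts = UnitCosts(),
    markov_params: MarkovParams = MarkovParams(),
    cascade_params: CascadeParams = CascadeParams(),
    scope: Scope = Scope.DIAGNOSTIC_ONLY,
    strategies: Iterable[Strategy] = ALL_STRATEGIES,
) -> PSAResult:
    """Combined bootstrap and PSA; fully reproducible from the seed."""
    strategies = tuple(strategies)
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    out_costs = np.zeros((config.n_iterations, len(strategies)))
    out_effects = np.zeros_like(out_costs)
    for it in range(config.n_iterations):
        if config.resample:
            idx = rng.integers(0, n, n)
            sample = [cohort[i] for i in idx]
        else:
            sample = list(cohort)
        it_costs, it_mp = draw_parameters(rng, costs, markov_params, config.cv)
        outcomes = evaluate_strategies(
            sample, scenario, it_costs, it_mp, cascade_params, scope, strategies
        )
        for k, o in enumerate(outcomes):
            out_costs[it, k] = o.cost
            out_effects[it, k] = o.effect
    return PSAResult(
        strategies=strategies,
        scope=scope,
        costs=out_costs,
        effects=out_effects,
        seed=config.seed,
    )


def ceac(
    psa: PSAResult,
    strategy: Strategy,
    comparator: Strategy,
    thresholds: Sequence[float],
) -> np.ndarray:
    """P(strategy cost-effective vs comparator) per willingness-to-pay λ:
    the fraction of iterations with λ·Δeffect − Δcost > 0."""
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any():
        raise ValidationError("willingness-to-pay thresholds must be non-negative")
    dc, de = psa.increments(strategy, comparator)
    nmb = thresholds[:, None] * de[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)


def ceac_frame(
    psa: PSAResult,
    strategy: Strategy,
    comparator: Strategy,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": list(thresholds),
            "probability_cost_effective": ceac(psa, strategy, comparator, thresholds),
        }
    )


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical central credible interval (linear-interpolation percentiles)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValidationError("need at least two samples")
    if not (0 < level <= 1):
        raise ValidationError("level must lie in (0, 1]")
    tail = (1 - level) / 2 * 100
    lo, hi = np.percentile(samples, [tail, 100 - tail], method="linear")
    return float(lo), float(hi)


def dominance_probability(psa: PSAResult, strategy: Strategy) -> float:
    """Fraction of iterations in which ``strategy`` dominates every other
    testing strategy (costs no more, is at least as effective, with one
    strict inequality; the no-testing arm is not a testing strategy)."""
    i = psa._col(strategy)
    others = [
        k
        for k, s in enumerate(psa.strategies)
        if s not in (strategy, Strategy.S0_NO_TESTING)
    ]
    if not others:
        raise ValidationError("no competing testing strategies in the PSA result")
    wins = np.ones(psa.costs.shape[0], dtype=bool)
    for j in others:
        weak = (psa.costs[:, i] <= psa.costs[:, j]) & (
            psa.effects[:, i] >= psa.effects[:, j]
        )
        strict = (psa.costs[:, i] < psa.costs[:, j]) | (
            psa.effects[:, i] > psa.effects[:, j]
        )
        wins &= weak & strict
    return float(wins.mean())


def outcomes_to_frame(
    outcomes: Sequence[StrategyOutcome], result: Optional[FrontierResult] = None
) -> pd.DataFrame:
    result = result if result is not None else frontier(outcomes)
    rows = []
    for o in sorted(outcomes, key=lambda o: (o.effect, o.cost)):
        rows.append(
            {
                "strategy": o.strategy.value,
                "cost": o.cost,
                "effect": o.effect,
                "scope": o.scope.value,
                "classification": result.classification[o.strategy].value,
                "icer": result.icers.get(o.strategy, float("nan")),
            }
        )
    return pd.DataFrame(rows)
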
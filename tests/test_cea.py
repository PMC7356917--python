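"""Cost-effectiveness engine: frontier vs a brute-force oracle, strategy
evaluation decomposition, bootstrap/PSA reproducibility, CEAC and credible
intervals."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchcea import (
    CascadeParams,
    Classification,
    Genotype,
    MarkovParams,
    PSAConfig,
    ScenarioOptions,
    Scope,
    Strategy,
    StrategyOutcome,
    UnitCosts,
    ValidationError,
    bootstrap_psa,
    ceac,
    credible_interval,
    dominance_probability,
    evaluate_strategies,
    frontier,
    surveillance_benefit,
)
from lynchcea.cea import PSAResult
from lynchcea.diagnostics import ALL_STRATEGIES, cohort_outcomes


def outcome(strategy, cost, effect):
    return StrategyOutcome(strategy, cost, effect, Scope.DIAGNOSTIC_ONLY)


S = list(Strategy)


def brute_force_frontier(points):
    """Independent O(n^3) classification straight from the definitions:
    strict dominance pairwise; extended dominance by a cheaper convex
    combination of two other non-dominated strategies."""
    n = len(points)
    dominated = set()
    for i, (ci, ei) in enumerate(points):
        for j, (cj, ej) in enumerate(points):
            if i == j:
                continue
            if cj <= ci and ej >= ei and (cj < ci or ej > ei):
                dominated.add(i)
    ext = set()
    live = [k for k in range(n) if k not in dominated]
    changed = True
    while changed:
        changed = False
        for i in list(live):
            if i in ext:
                continue
            ci, ei = points[i]
            for a in live:
                for b in live:
                    if a in ext or b in ext or i in (a, b):
                        continue
                    ca, ea = points[a]
                    cb, eb = points[b]
                    if ea < ei < eb:
                        lam = (ei - ea) / (eb - ea)
                        blend_cost = ca + lam * (cb - ca)
                        if blend_cost < ci:
                            ext.add(i)
                            changed = True
    on = [k for k in live if k not in ext]
    return dominated, ext, sorted(on, key=lambda k: points[k][1])


class TestFrontier:
    def test_published_short_term_block(self):
        """The printed diagnostic costs/cases classify S1, S2, S4 as dominated
        and give an ICER of 1699 per case for the IHC+methylation strategy."""
        outcomes = [
            outcome(Strategy.S0_NO_TESTING, 0, 0),
            outcome(Strategy.S1_MSI, 41_512, 9),
            outcome(Strategy.S2_MSI_METH, 27_523, 9),
            outcome(Strategy.S3_MANCHESTER, 27_183, 16),
            outcome(Strategy.S4_DIRECT_NGS, 127_125, 16),
        ]
        result = frontier(outcomes)
        for s in (Strategy.S1_MSI, Strategy.S2_MSI_METH, Strategy.S4_DIRECT_NGS):
            assert result.classification[s] is Classification.DOMINATED
        assert result.frontier == (Strategy.S0_NO_TESTING, Strategy.S3_MANCHESTER)
        assert round(result.icers[Strategy.S3_MANCHESTER]) == 1699

    def test_single_strategy(self):
        result = frontier([outcome(Strategy.S0_NO_TESTING, 10, 1)])
        assert result.classification[Strategy.S0_NO_TESTING] is Classification.ON_FRONTIER
        assert result.icers == {}

    def test_extended_dominance_hand_example(self):
        outcomes = [
            outcome(S[0], 0, 0),
            outcome(S[1], 50, 1),
            outcome(S[2], 60, 2),
        ]
        result = frontier(outcomes)
        assert result.classification[S[1]] is Classification.EXTENDEDLY_DOMINATED
        assert result.frontier == (S[0], S[2])
        assert result.icers[S[2]] == pytest.approx(30.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            frontier([])

    def test_identical_strategies_tie_break(self):
        outcomes = [outcome(s, 100.0, 5.0) for s in S]
        result = frontier(outcomes)
        kept = [s for s in S if result.classification[s] is Classification.ON_FRONTIER]
        assert len(kept) == 1
        assert all(
            result.classification[s] is Classification.DOMINATED
            for s in S
            if s is not kept[0]
        )

    def test_equivalence_with_brute_force_oracle(self):
        """1000 random instances of up to 6 strategies agree with the
        brute-force classification and ICERs strictly increase."""
        rng = np.random.default_rng(2020)
        extra = [f"X{i}" for i in range(1)]
        for _ in range(1000):
            k = rng.integers(2, 7)
            names = (S + ["X5"])[: int(k)]
            points = [
                (float(rng.uniform(0, 1000)), float(rng.uniform(0, 20)))
                for _ in range(int(k))
            ]
            outcomes = [outcome(nm, c, e) for nm, (c, e) in zip(names, points)]
            result = frontier(outcomes)
            dom, ext, on = brute_force_frontier(points)
            assert {names[i] for i in dom} == {
                nm for nm in names
                if result.classification[nm] is Classification.DOMINATED
            }
            assert {names[i] for i in ext} == {
                nm for nm in names
                if result.classification[nm] is Classification.EXTENDEDLY_DOMINATED
            }
            assert tuple(names[i] for i in on) == result.frontier
            icers = [result.icers[nm] for nm in result.frontier[1:]]
            assert all(a < b for a, b in zip(icers, icers[1:]))


class TestEvaluateStrategies:
    def test_diagnostic_scope_matches_cohort_totals(self, cohort):
        outcomes = evaluate_strategies(cohort, scope=Scope.DIAGNOSTIC_ONLY)
        by_s = {o.strategy: o for o in outcomes}
        assert by_s[Strategy.S4_DIRECT_NGS].effect == 16
        assert round(by_s[Strategy.S4_DIRECT_NGS].cost) == 127_125
        assert by_s[Strategy.S0_NO_TESTING].cost == 0.0

    def test_no_testing_equals_no_surveillance_extrapolation(self, cohort):
        """Under S0 every proband's lifetime outcome is the plain
        no-surveillance extrapolation."""
        from lynchcea import extrapolate

        small = cohort[:20]
        mp = MarkovParams()
        outcomes = evaluate_strategies(
            small, scope=Scope.PROBAND_ONLY, markov_params=mp,
            strategies=[Strategy.S0_NO_TESTING],
        )
        expected_qalys = np.mean(
            [extrapolate(p.genotype, p.age, p.sex, False, mp).qalys for p in small]
        )
        assert outcomes[0].effect == pytest.approx(expected_qalys, rel=1e-12)

    def test_incremental_qalys_decompose_into_surveillance_benefits(self, cohort):
        """Proband-only incremental QALYs of the Manchester approach vs no
        testing equal the summed surveillance benefit of the 16 identified
        true cases: only they change pathway."""
        mp = MarkovParams()
        outcomes = evaluate_strategies(
            cohort, scope=Scope.PROBAND_ONLY, markov_params=mp,
            strategies=[Strategy.S0_NO_TESTING, Strategy.S3_MANCHESTER],
        )
        s0, s3 = outcomes
        identified = [
            p for p, o, _ in cohort_outcomes(cohort, Strategy.S3_MANCHESTER)
            if o and o.identified
        ]
        assert len(identified) == 16
        total_benefit = sum(
            surveillance_benefit(p.genotype, p.age, p.sex, mp)[1] for p in identified
        )
        assert (s3.effect - s0.effect) * len(cohort) == pytest.approx(
            total_benefit, rel=1e-9
        )

    def test_relatives_scope_adds_constant_baseline(self, cohort):
        """The relatives' baseline is strategy-independent: S0's QALY gap
        between scopes equals the relatives baseline for every proband."""
        small = cohort[:10]
        po = evaluate_strategies(
            small, scope=Scope.PROBAND_ONLY, strategies=[Strategy.S0_NO_TESTING]
        )[0]
        pr = evaluate_strategies(
            small, scope=Scope.PROBAND_PLUS_RELATIVES,
            strategies=[Strategy.S0_NO_TESTING],
        )[0]
        assert pr.effect > po.effect
        assert pr.cost > po.cost

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_strategies([], scope=Scope.DIAGNOSTIC_ONLY)


class TestBootstrapPSA:
    def test_degenerate_collapse_to_base_case(self, cohort):
        """One iteration, zero-variance distributions and no resampling
        reproduce the deterministic result exactly."""
        cfg = PSAConfig(n_iterations=1, seed=5, cv=0.0, resample=False)
        psa = bootstrap_psa(cohort, cfg, scope=Scope.DIAGNOSTIC_ONLY)
        det = evaluate_strategies(cohort, scope=Scope.DIAGNOSTIC_ONLY)
        for k, o in enumerate(det):
            assert psa.costs[0, k] == pytest.approx(o.cost)
            assert psa.effects[0, k] == o.effect

    def test_seed_reproducibility(self, cohort):
        cfg = PSAConfig(n_iterations=10, seed=123)
        a = bootstrap_psa(cohort, cfg, scope=Scope.DIAGNOSTIC_ONLY)
        b = bootstrap_psa(cohort, cfg, scope=Scope.DIAGNOSTIC_ONLY)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects, b.effects)
        c = bootstrap_psa(
            cohort, dataclasses.replace(cfg, seed=124), scope=Scope.DIAGNOSTIC_ONLY
        )
        assert not np.array_equal(a.costs, c.costs)

    def test_bootstrap_mean_cases_identified(self, cohort):
        """Mean Manchester cases over 200 bootstrap iterations is within 3
        standard errors of 16 (each case resampled once in expectation)."""
        cfg = PSAConfig(n_iterations=200, seed=9)
        psa = bootstrap_psa(cohort, cfg, scope=Scope.DIAGNOSTIC_ONLY)
        k = psa.strategies.index(Strategy.S3_MANCHESTER)
        cases = psa.effects[:, k]
        se = cases.std(ddof=1) / np.sqrt(len(cases))
        assert abs(cases.mean() - 16) < 3 * se + 1e-9

    def test_dominance_probability_bounded(self, cohort):
        cfg = PSAConfig(n_iterations=50, seed=21)
        psa = bootstrap_psa(cohort, cfg, scope=Scope.DIAGNOSTIC_ONLY)
        p = dominance_probability(psa, Strategy.S3_MANCHESTER)
        assert 0.0 <= p <= 1.0


def synthetic_psa(costs, effects):
    strategies = (Strategy.S0_NO_TESTING, Strategy.S3_MANCHESTER)
    return PSAResult(
        strategies=strategies,
        scope=Scope.PROBAND_ONLY,
        costs=np.asarray(costs, dtype=float),
        effects=np.asarray(effects, dtype=float),
        seed=0,
    )


class TestCEAC:
    def test_zero_threshold_is_cost_saving_probability(self):
        psa = synthetic_psa(
            costs=[[0, -5], [0, 3], [0, 10]], effects=[[0, 1], [0, 1], [0, -1]]
        )
        probs = ceac(psa, Strategy.S3_MANCHESTER, Strategy.S0_NO_TESTING, [0.0])
        assert probs[0] == pytest.approx(1 / 3)

    def test_hand_enumerated_two_point_cloud(self):
        """Two iterations: (Δc, Δe) = (100, 0.01) and (300, 0.01); NMB > 0
        kicks in at λ > 10,000 and λ > 30,000 respectively."""
        psa = synthetic_psa(costs=[[0, 100], [0, 300]], effects=[[0, 0.01], [0, 0.01]])
        probs = ceac(
            psa, Strategy.S3_MANCHESTER, Strategy.S0_NO_TESTING,
            [0, 10_000, 20_000, 30_000, 40_000],
        )
        assert list(probs) == [0.0, 0.0, 0.5, 0.5, 1.0]

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(4)
        n = 200
        dcost = rng.normal(100, 80, n)
        deff = rng.uniform(0.001, 0.05, n)
        psa = synthetic_psa(
            costs=np.column_stack([np.zeros(n), dcost]),
            effects=np.column_stack([np.zeros(n), deff]),
        )
        thresholds = np.linspace(0, 50_000, 51)
        probs = ceac(psa, Strategy.S3_MANCHESTER, Strategy.S0_NO_TESTING, thresholds)
        assert ((probs >= 0) & (probs <= 1)).all()
        assert (np.diff(probs) >= 0).all()

    def test_negative_threshold_rejected(self):
        psa = synthetic_psa(costs=[[0, 1]], effects=[[0, 1]])
        with pytest.raises(ValidationError):
            ceac(psa, Strategy.S3_MANCHESTER, Strategy.S0_NO_TESTING, [-1.0])

    def test_icer_samples_exclude_nonpositive_increments(self):
        psa = synthetic_psa(
            costs=[[0, 100], [0, 200], [0, 50]],
            effects=[[0, 0.0], [0, 0.02], [0, -0.01]],
        )
        samples = psa.icer_samples(Strategy.S3_MANCHESTER, Strategy.S0_NO_TESTING)
        assert list(samples) == [pytest.approx(10_000)]


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 10_000).map(lambda i: i / 10),   # costs on a 10p grid
            st.integers(0, 200).map(lambda i: i / 10),      # effects: many ties
        ),
        min_size=1,
        max_size=6,
    )
)
def test_frontier_classification_exhaustive_and_exclusive(points):
    """Every strategy receives exactly one classification; frontier members
    are never dominated and their ICERs strictly increase."""
    outcomes = [
        StrategyOutcome(f"S{i}", c, e, Scope.DIAGNOSTIC_ONLY)
        for i, (c, e) in enumerate(points)
    ]
    result = frontier(outcomes)
    assert set(result.classification) == {o.strategy for o in outcomes}
    assert len(result.frontier) >= 1
    for s in result.frontier:
        assert result.classification[s] is Classification.ON_FRONTIER
    icers = [result.icers[s] for s in result.frontier[1:]]
    assert all(np.isfinite(icers))
    assert all(a < b for a, b in zip(icers, icers[1:]))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(-1e9, 1e9, allow_nan=False), min_size=2, max_size=50),
    st.floats(0.5, 1.0),
)
def test_credible_interval_bounds_property(samples, level):
    """The interval is ordered and contained in the sample range."""
    lo, hi = credible_interval(samples, level)
    assert min(samples) <= lo <= hi <= max(samples)


class TestCredibleInterval:
    def test_constant_samples(self):
        assert credible_interval([7.0, 7.0, 7.0]) == (7.0, 7.0)

    def test_linear_interpolation_rule(self):
        lo, hi = credible_interval(np.arange(1, 1001))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_full_level_returns_range(self):
        lo, hi = credible_interval([3.0, 1.0, 2.0], level=1.0)
        assert (lo, hi) == (1.0, 3.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            credible_interval([1.0])
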
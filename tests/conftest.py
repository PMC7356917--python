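import numpy as np
import pytest

from lynchcea import (
    Genotype,
    MarkovParams,
    MSIStatus,
    Proband,
    TumourProfile,
    petals_fixture,
)
from lynchcea.population import (
    Expression,
    Methylation,
    PATHOGENIC_GENOTYPES,
    ihc_pattern_for_genotype,
    _EXPR_ALL,
    _make_tumour,
)


@pytest.fixture(scope="session")
def cohort():
    return petals_fixture()


@pytest.fixture(scope="session")
def ls_cases(cohort):
    return [p for p in cohort if p.has_lynch]


@pytest.fixture(scope="session")
def sporadic_cases(cohort):
    return [p for p in cohort if not p.has_lynch]


def make_toy_markov(**overrides) -> MarkovParams:
    """Small, fully controlled Markov parameter set for oracle tests."""
    defaults = dict(
        incidence={g.value: [(0, 0.0)] for g in Genotype},
        surveillance_hr=0.5,
        stage_dist_surv=(0.25, 0.25, 0.25, 0.25),
        stage_dist_nosurv=(0.25, 0.25, 0.25, 0.25),
        stage_mortality=(0.0, 0.0, 0.0, 0.0),
        excess_mortality_years=2,
        background_mortality={"a": 0.0, "b": 0.0, "male_factor": 1.0},
        utility_profile={"base": 1.0, "decline_per_year": 0.0, "floor": 1.0},
        stage4_utility_multiplier=0.789,
        colonoscopy_cost=0.0,
        colonoscopy_interval=2,
        crc_cost={0: [0.0, 0.0, 0.0, 0.0]},
        discount_rate=0.0,
        max_age=100,
    )
    defaults.update(overrides)
    return MarkovParams(**defaults)


def random_proband(rng: np.random.Generator, i: int = 0) -> Proband:
    """Arbitrary valid proband for property tests."""
    def pick(options):
        return options[int(rng.integers(len(options)))]

    genotype = pick([Genotype.SPORADIC] * 3 + list(PATHOGENIC_GENOTYPES))
    if genotype is Genotype.SPORADIC:
        exprs = list(Expression)
        ihc = {
            k: pick(exprs)
            for k in ("ihc_mlh1", "ihc_pms2", "ihc_msh2", "ihc_msh6")
        }
    else:
        ihc = ihc_pattern_for_genotype(genotype)
    msi = pick(list(MSIStatus))
    mlh1_side = (
        ihc["ihc_mlh1"] is Expression.ABSENT or ihc["ihc_pms2"] is Expression.ABSENT
    )
    meth_choices = (
        [Methylation.YES, Methylation.NO]
        if mlh1_side
        else list(Methylation)
    )
    tumour = _make_tumour(dict(ihc), msi, pick(meth_choices))
    premm5 = None if rng.random() < 0.4 else float(rng.uniform(0, 0.4))
    return Proband(
        id=f"R{i}",
        age=int(rng.integers(30, 90)),
        genotype=genotype,
        tumour=tumour,
        premm5=premm5,
    )


def random_cohort(rng: np.random.Generator, n: int) -> list:
    return [random_proband(rng, i) for i in range(n)]
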
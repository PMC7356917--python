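"""Proband data model and synthetic endometrial-cancer cohorts.

The central object is the :class:`Proband`: a woman diagnosed with
endometrial cancer, carrying a true mismatch-repair (MMR) genotype, a tumour
test profile (four-protein immunohistochemistry, microsatellite instability,
*MLH1* promoter hypermethylation) and, where family history permits, a
PREMM5 risk score.

Two cohort sources are provided:

* :func:`petals_fixture` — a deterministic 500-patient cohort reconstructed
  to match the published marginal counts of a large UK reflex-testing study
  (16 Lynch syndrome cases, genotype split 8/4/2/2, mean ages 54 vs 63.5,
  9/16 MSI-high Lynch tumours, PREMM5 computable for 299, ...).  Individual
  records are a constrained reconstruction, not real patient data.
* :func:`generate_population` — a seeded random generator whose marginals
  converge to a supplied :class:`CalibrationTargets` as the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

PREMM5_THRESHOLD = 0.025  # "score >= 2.5%" stored as a probability


class Genotype(str, Enum):
    """Germline MMR status; ``SPORADIC`` means no pathogenic variant."""

    SPORADIC = "sporadic"
    PATH_MLH1 = "path_MLH1"
    PATH_MSH2 = "path_MSH2"
    PATH_MSH6 = "path_MSH6"
    PATH_PMS2 = "path_PMS2"


PATHOGENIC_GENOTYPES = (
    Genotype.PATH_MLH1,
    Genotype.PATH_MSH2,
    Genotype.PATH_MSH6,
    Genotype.PATH_PMS2,
)


class Expression(str, Enum):
    """IHC staining result for one MMR protein; patchy loss is not complete loss."""

    EXPRESSED = "expressed"
    ABSENT = "absent"
    PATCHY = "patchy"


class MSIStatus(str, Enum):
    """Microsatellite instability at a five-marker panel."""

    MSS = "MSS"       # no unstable markers
    MSI_L = "MSI_L"   # one unstable marker
    MSI_H = "MSI_H"   # two or more unstable markers


class Methylation(str, Enum):
    """*MLH1* promoter hypermethylation of tumour DNA."""

    YES = "yes"
    NO = "no"
    NOT_DONE = "not_done"


@dataclass(frozen=True)
class TumourProfile:
    """Complete tumour test profile for one proband.

    ``mlh1_hypermethylated`` may be ``NOT_DONE`` only when neither MLH1 nor
    PMS2 shows complete loss — methylation testing is only indicated by an
    MLH1/PMS2-deficient IHC pattern.
    """

    ihc_mlh1: Expression
    ihc_pms2: Expression
    ihc_msh2: Expression
    ihc_msh6: Expression
    msi: MSIStatus
    mlh1_hypermethylated: Methylation

    def __post_init__(self) -> None:
        mlh1_side_absent = (
            self.ihc_mlh1 is Expression.ABSENT or self.ihc_pms2 is Expression.ABSENT
        )
        if self.mlh1_hypermethylated is Methylation.NOT_DONE and mlh1_side_absent:
            raise ValidationError(
                "methylation status must be recorded when MLH1 or PMS2 is absent"
            )


@dataclass(frozen=True)
class Proband:
    """One endometrial-cancer patient entering the diagnostic pathway."""

    id: str
    age: int
    genotype: Genotype
    tumour: TumourProfile
    premm5: Optional[float] = None  # probability in [0, 1]; None = no family history
    sex: str = "female"

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 100):
            raise ValidationError(f"age {self.age} outside [18, 100]")
        if self.premm5 is not None and not (0.0 <= self.premm5 <= 1.0):
            raise ValidationError(f"premm5 {self.premm5} outside [0, 1]")
        if self.sex != "female":
            raise ValidationError("probands are endometrial cancer patients (female)")

    @property
    def has_lynch(self) -> bool:
        return self.genotype is not Genotype.SPORADIC


@dataclass(frozen=True)
class CalibrationTargets:
    """Marginal counts a synthetic cohort should reproduce."""

    n_total: int
    n_ls: int
    genotype_split: dict  # pathogenic Genotype -> count, sums to n_ls
    n_ls_under70: int
    n_sporadic_under70: int
    n_ls_msih: int
    n_premm5_available: int
    n_ls_premm5_available: int
    n_ls_premm5_high: int
    n_sporadic_premm5_high: int
    mean_age_ls: float
    mean_age_sporadic: float

    def validate(self) -> None:
        n_sporadic = self.n_total - self.n_ls
        if self.n_ls < 0 or n_sporadic < 0:
            raise ValidationError("n_ls must lie in [0, n_total]")
        if sum(self.genotype_split.values()) != self.n_ls:
            raise ValidationError("genotype_split must sum to n_ls")
        checks = [
            (self.n_ls_under70, self.n_ls, "n_ls_under70"),
            (self.n_sporadic_under70, n_sporadic, "n_sporadic_under70"),
            (self.n_ls_msih, self.n_ls, "n_ls_msih"),
            (self.n_premm5_available, self.n_total, "n_premm5_available"),
            (self.n_ls_premm5_available, self.n_ls, "n_ls_premm5_available"),
            (self.n_ls_premm5_high, self.n_ls_premm5_available, "n_ls_premm5_high"),
            (
                self.n_sporadic_premm5_high,
                self.n_premm5_available - self.n_ls_premm5_available,
                "n_sporadic_premm5_high",
            ),
        ]
        for sub, parent, name in checks:
            if not (0 <= sub <= parent):
                raise ValidationError(f"{name}={sub} exceeds its parent count {parent}")


#: Published marginals of the 500-patient reflex-testing cohort.
PETALS_TARGETS = CalibrationTargets(
    n_total=500,
    n_ls=16,
    genotype_split={
        Genotype.PATH_MSH6: 8,
        Genotype.PATH_MSH2: 4,
        Genotype.PATH_MLH1: 2,
        Genotype.PATH_PMS2: 2,
    },
    n_ls_under70=15,
    n_sporadic_under70=314,
    n_ls_msih=9,
    n_premm5_available=299,
    n_ls_premm5_available=13,
    n_ls_premm5_high=11,
    n_sporadic_premm5_high=153,
    mean_age_ls=54.0,
    mean_age_sporadic=63.5,
)


@dataclass(frozen=True)
class SporadicTumourRates:
    """Composition of sporadic tumours by test category.

    Counts are per 484 sporadic patients.  The defaults are the unique
    integer solution consistent with the published per-strategy cohort
    diagnostic costs (see docs/methods.md): tumours with MLH1/PMS2 loss are
    overwhelmingly explained by somatic *MLH1* promoter hypermethylation.
    """

    msih_dmmr_meth: int = 64     # MSI-H, MLH1/PMS2 absent, hypermethylated
    mss_dmmr_meth: int = 8       # MSS, MLH1/PMS2 absent, hypermethylated
    msih_dmmr_unmeth: int = 12   # MSI-H, MLH1/PMS2 absent, NOT hypermethylated
    msih_pmmr: int = 3           # MSI-H, all proteins expressed
    msil_pmmr: int = 20          # MSI-L, all proteins expressed
    denominator: int = 484

    def counts(self) -> list[int]:
        special = [
            self.msih_dmmr_meth,
            self.mss_dmmr_meth,
            self.msih_dmmr_unmeth,
            self.msih_pmmr,
            self.msil_pmmr,
        ]
        rest = self.denominator - sum(special)
        if rest < 0:
            raise ValidationError("sporadic tumour category counts exceed denominator")
        return special + [rest]


# ---------------------------------------------------------------------------
# IHC patterns implied by genotype (complete loss of the mutated protein and,
# for MLH1/MSH2, its heterodimer partner).
# ---------------------------------------------------------------------------

_EXPR_ALL = dict(
    ihc_mlh1=Expression.EXPRESSED,
    ihc_pms2=Expression.EXPRESSED,
    ihc_msh2=Expression.EXPRESSED,
    ihc_msh6=Expression.EXPRESSED,
)


def ihc_pattern_for_genotype(genotype: Genotype) -> dict:
    """Deterministic IHC loss pattern for a pathogenic genotype."""
    pattern = dict(_EXPR_ALL)
    if genotype is Genotype.PATH_MLH1:
        pattern["ihc_mlh1"] = Expression.ABSENT
        pattern["ihc_pms2"] = Expression.ABSENT
    elif genotype is Genotype.PATH_MSH2:
        pattern["ihc_msh2"] = Expression.ABSENT
        pattern["ihc_msh6"] = Expression.ABSENT
    elif genotype is Genotype.PATH_MSH6:
        pattern["ihc_msh6"] = Expression.ABSENT
    elif genotype is Genotype.PATH_PMS2:
        pattern["ihc_pms2"] = Expression.ABSENT
    else:
        raise ValidationError("sporadic genotype has no deterministic IHC pattern")
    return pattern


def _integer_ages(n: int, lo: int, hi: int, total: int) -> np.ndarray:
    """Deterministic integer ages in [lo, hi] with the exact given sum."""
    if not (n * lo <= total <= n * hi):
        raise ValidationError("age sum infeasible for the given bounds")
    ages = np.floor(np.linspace(lo, hi, n)).astype(int) if n > 1 else np.array([lo])
    i = 0
    guard = 0
    while ages.sum() != total:
        if ages.sum() < total and ages[i % n] < hi:
            ages[i % n] += 1
        elif ages.sum() > total and ages[i % n] > lo:
            ages[i % n] -= 1
        i += 1
        guard += 1
        if guard > 10 * n * (hi - lo + 2):  # pragma: no cover
            raise RuntimeError("age adjustment failed to converge")
    return ages


def _make_tumour(ihc: dict, msi: MSIStatus, meth: Methylation) -> TumourProfile:
    return TumourProfile(msi=msi, mlh1_hypermethylated=meth, **ihc)


# Per-case Lynch fixture plan: (genotype, msi, premm5 slot) where the premm5
# slot is "high" (0.06), "low" (0.01) or None (no family history).  The MSI
# pattern gives 9 MSI-H, exactly one MSI-L and six MSS tumours; the single
# case aged >= 70 (index 10) is MSS so that age-restricted MSI testing still
# finds nine cases; exactly 8 of the 11 high-PREMM5 cases are MSI-H.
_LS_PLAN = [
    (Genotype.PATH_MLH1, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MLH1, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH2, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH2, MSIStatus.MSI_H, None),
    (Genotype.PATH_MSH2, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH2, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH6, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH6, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_MSH6, MSIStatus.MSI_L, "high"),
    (Genotype.PATH_MSH6, MSIStatus.MSS, "low"),
    (Genotype.PATH_MSH6, MSIStatus.MSS, None),   # the case aged >= 70
    (Genotype.PATH_MSH6, MSIStatus.MSS, None),
    (Genotype.PATH_MSH6, MSIStatus.MSS, "low"),
    (Genotype.PATH_MSH6, MSIStatus.MSS, "high"),
    (Genotype.PATH_PMS2, MSIStatus.MSI_H, "high"),
    (Genotype.PATH_PMS2, MSIStatus.MSS, "high"),
]

_PREMM5_HIGH = 0.06
_PREMM5_LOW = 0.01
_FIXTURE_SHUFFLE_SEED = 20160501  # fixed: the fixture is fully deterministic


def petals_fixture() -> list[Proband]:
    """Deterministic 500-patient cohort matching the published marginals.

    Returns the same cohort on every call.  Aggregates satisfied exactly:
    500 patients; 16 Lynch syndrome cases split 8 path_MSH6 / 4 path_MSH2 /
    2 path_MLH1 / 2 path_PMS2; 15 LS and 314 sporadic cases aged under 70;
    mean ages 54.0 (LS) and 63.5 (sporadic); 9 of 16 LS tumours MSI-H and
    exactly one MSI-L; every LS tumour shows complete loss of MSH6 or PMS2;
    PREMM5 computable for 299 patients of whom 11/13 LS and 153/286 sporadic
    score >= 2.5%.
    """
    probands: list[Proband] = []

    # --- Lynch syndrome cases -------------------------------------------
    ls_under70 = _integer_ages(15, 36, 69, int(16 * 54 - 72))
    ls_ages = []
    k = 0
    for i in range(16):
        if i == 10:
            ls_ages.append(72)
        else:
            ls_ages.append(int(ls_under70[k]))
            k += 1
    for i, ((genotype, msi, slot), age) in enumerate(zip(_LS_PLAN, ls_ages)):
        ihc = ihc_pattern_for_genotype(genotype)
        # methylation recorded (negative) whenever MLH1/PMS2 is absent
        mlh1_side = (
            ihc["ihc_mlh1"] is Expression.ABSENT or ihc["ihc_pms2"] is Expression.ABSENT
        )
        meth = Methylation.NO if mlh1_side else Methylation.NOT_DONE
        premm5 = {None: None, "high": _PREMM5_HIGH, "low": _PREMM5_LOW}[slot]
        probands.append(
            Proband(
                id=f"LS{i + 1:03d}",
                age=age,
                genotype=genotype,
                tumour=_make_tumour(ihc, msi, meth),
                premm5=premm5,
            )
        )

    # --- sporadic cases --------------------------------------------------
    rates = SporadicTumourRates()
    counts = rates.counts()
    dmmr = ihc_pattern_for_genotype(Genotype.PATH_MLH1)  # MLH1/PMS2 absent
    categories = [
        (dmmr, MSIStatus.MSI_H, Methylation.YES),
        (dmmr, MSIStatus.MSS, Methylation.YES),
        (dmmr, MSIStatus.MSI_H, Methylation.NO),
        (_EXPR_ALL, MSIStatus.MSI_H, Methylation.NOT_DONE),
        (_EXPR_ALL, MSIStatus.MSI_L, Methylation.NOT_DONE),
        (_EXPR_ALL, MSIStatus.MSS, Methylation.NOT_DONE),
    ]
    tumours = []
    for (ihc, msi, meth), count in zip(categories, counts):
        tumours.extend([_make_tumour(dict(ihc), msi, meth)] * count)

    n_sporadic = rates.denominator
    sum_total = int(round(n_sporadic * 63.5))           # 30734
    sum_over70 = 12580                                  # 170 patients, mean 74.0
    under = _integer_ages(314, 45, 69, sum_total - sum_over70)
    over = _integer_ages(170, 70, 88, sum_over70)
    ages = np.concatenate([under, over])

    # fixed permutations decorrelate age / tumour category / PREMM5
    rng = np.random.default_rng(_FIXTURE_SHUFFLE_SEED)
    age_perm = rng.permutation(n_sporadic)
    premm5_perm = rng.permutation(n_sporadic)
    premm5_values: list[Optional[float]] = [None] * n_sporadic
    n_avail = 286
    n_high = 153
    for rank, idx in enumerate(premm5_perm):
        if rank < n_high:
            premm5_values[idx] = _PREMM5_HIGH
        elif rank < n_avail:
            premm5_values[idx] = _PREMM5_LOW

    for i in range(n_sporadic):
        probands.append(
            Proband(
                id=f"SP{i + 1:03d}",
                age=int(ages[age_perm[i]]),
                genotype=Genotype.SPORADIC,
                tumour=tumours[i],
                premm5=premm5_values[i],
            )
        )
    return probands


def generate_population(
    n: int,
    targets: CalibrationTargets = PETALS_TARGETS,
    seed: int = 0,
    sporadic_rates: SporadicTumourRates = SporadicTumourRates(),
) -> list[Proband]:
    """Draw a synthetic cohort whose marginals converge to ``targets``.

    Each patient is sampled independently: Lynch status is Bernoulli with
    the target prevalence, pathogenic genotypes follow the target split,
    ages are drawn from truncated normal distributions with the target
    means, and tumour/PREMM5 attributes follow the target conditional
    proportions.  Identical seeds give identical cohorts.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    targets.validate()
    rng = np.random.default_rng(seed)

    p_ls = targets.n_ls / targets.n_total
    genotypes = list(targets.genotype_split)
    genotype_p = np.array([targets.genotype_split[g] for g in genotypes], dtype=float)
    genotype_p = genotype_p / genotype_p.sum() if genotype_p.sum() else genotype_p

    n_ls = targets.n_ls
    n_sp = targets.n_total - n_ls
    p_ls_msih = targets.n_ls_msih / n_ls if n_ls else 0.0
    p_ls_msil = 1.0 / n_ls if n_ls else 0.0  # one MSI-L case in the calibration cohort
    p_ls_avail = targets.n_ls_premm5_available / n_ls if n_ls else 0.0
    p_ls_high = (
        targets.n_ls_premm5_high / targets.n_ls_premm5_available
        if targets.n_ls_premm5_available
        else 0.0
    )
    n_sp_avail = targets.n_premm5_available - targets.n_ls_premm5_available
    p_sp_avail = n_sp_avail / n_sp if n_sp else 0.0
    p_sp_high = targets.n_sporadic_premm5_high / n_sp_avail if n_sp_avail else 0.0

    sp_counts = np.array(sporadic_rates.counts(), dtype=float)
    sp_category_p = sp_counts / sp_counts.sum()
    dmmr = ihc_pattern_for_genotype(Genotype.PATH_MLH1)
    sp_categories = [
        (dmmr, MSIStatus.MSI_H, Methylation.YES),
        (dmmr, MSIStatus.MSS, Methylation.YES),
        (dmmr, MSIStatus.MSI_H, Methylation.NO),
        (_EXPR_ALL, MSIStatus.MSI_H, Methylation.NOT_DONE),
        (_EXPR_ALL, MSIStatus.MSI_L, Methylation.NOT_DONE),
        (_EXPR_ALL, MSIStatus.MSS, Methylation.NOT_DONE),
    ]

    def draw_age(mean: float, sd: float) -> int:
        a, b = (18 - mean) / sd, (100 - mean) / sd
        x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
        return int(np.clip(round(x), 18, 100))

    def draw_premm5(p_avail: float, p_high: float) -> Optional[float]:
        if rng.random() >= p_avail:
            return None
        if rng.random() < p_high:
            return float(rng.uniform(PREMM5_THRESHOLD, 0.5))
        return float(rng.uniform(0.001, PREMM5_THRESHOLD * 0.99))

    probands: list[Proband] = []
    for i in range(n):
        if rng.random() < p_ls:
            genotype = genotypes[rng.choice(len(genotypes), p=genotype_p)]
            ihc = ihc_pattern_for_genotype(genotype)
            u = rng.random()
            if u < p_ls_msih:
                msi = MSIStatus.MSI_H
            elif u < p_ls_msih + p_ls_msil:
                msi = MSIStatus.MSI_L
            else:
                msi = MSIStatus.MSS
            mlh1_side = (
                ihc["ihc_mlh1"] is Expression.ABSENT
                or ihc["ihc_pms2"] is Expression.ABSENT
            )
            meth = Methylation.NO if mlh1_side else Methylation.NOT_DONE
            probands.append(
                Proband(
                    id=f"G{i + 1:06d}",
                    age=draw_age(targets.mean_age_ls, 9.0),
                    genotype=genotype,
                    tumour=_make_tumour(ihc, msi, meth),
                    premm5=draw_premm5(p_ls_avail, p_ls_high),
                )
            )
        else:
            cat = rng.choice(len(sp_categories), p=sp_category_p)
            ihc, msi, meth = sp_categories[cat]
            probands.append(
                Proband(
                    id=f"G{i + 1:06d}",
                    age=draw_age(targets.mean_age_sporadic, 11.0),
                    genotype=Genotype.SPORADIC,
                    tumour=_make_tumour(dict(ihc), msi, meth),
                    premm5=draw_premm5(p_sp_avail, p_sp_high),
                )
            )
    return probands


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "id",
    "age",
    "sex",
    "genotype",
    "ihc_mlh1",
    "ihc_pms2",
    "ihc_msh2",
    "ihc_msh6",
    "msi",
    "mlh1_hypermethylated",
    "premm5",
]


def cohort_to_frame(cohort: Iterable[Proband]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        rows.append(
            {
                "id": p.id,
                "age": p.age,
                "sex": p.sex,
                "genotype": p.genotype.value,
                "ihc_mlh1": p.tumour.ihc_mlh1.value,
                "ihc_pms2": p.tumour.ihc_pms2.value,
                "ihc_msh2": p.tumour.ihc_msh2.value,
                "ihc_msh6": p.tumour.ihc_msh6.value,
                "msi": p.tumour.msi.value,
                "mlh1_hypermethylated": p.tumour.mlh1_hypermethylated.value,
                "premm5": p.premm5 if p.premm5 is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort_csv(cohort: Iterable[Proband], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[Proband]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"patient table missing columns: {sorted(missing)}")
    cohort = []
    for row in df.itertuples(index=False):
        tumour = TumourProfile(
            ihc_mlh1=Expression(row.ihc_mlh1),
            ihc_pms2=Expression(row.ihc_pms2),
            ihc_msh2=Expression(row.ihc_msh2),
            ihc_msh6=Expression(row.ihc_msh6),
            msi=MSIStatus(row.msi),
            mlh1_hypermethylated=Methylation(row.mlh1_hypermethylated),
        )
        premm5 = None if pd.isna(row.premm5) else float(row.premm5)
        cohort.append(
            Proband(
                id=str(row.id),
                age=int(row.age),
                genotype=Genotype(row.genotype),
                tumour=tumour,
                premm5=premm5,
                sex=str(row.sex),
            )
        )
    return cohort
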
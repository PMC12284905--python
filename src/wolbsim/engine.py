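"""Individual-based daily life cycle of a haplodiploid host population.

Each simulated day: virgin adult females mate (first-male sperm precedence),
mated adult females oviposit, every egg's fate is resolved (fertilization,
sex-allocation distortion, fecundity benefit, maternal transmission, and
cytoplasmic incompatibility modulated by additive host suppressors carried by
the fertilizing male), then density-dependent mortality removes a fraction of
the population toward a logistic target and survivors age by one day.

The population is stored as a structure of arrays (one numpy array per
attribute) so that whole-population updates are vectorized; the
:class:`Individual` view reconstructs the per-mite record on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "Population",
    "PopulationState",
    "Individual",
    "StoredSperm",
    "DailyRecord",
    "OvipositionStats",
    "init_population",
    "expected_eggs",
    "draw_egg_count",
    "draw_traits",
    "mate_virgins",
    "alpha_from_sd",
    "effective_ci",
    "produce_offspring",
    "mortality_fraction",
    "apply_mortality_and_aging",
    "measure",
    "step_day",
    "run_season",
    "run_replicate",
    "new_season",
    "records_to_frame",
]

_MAX_DEATH_AGE_BIN = 64


class Population:
    """Structure-of-arrays container for the living population.

    Females are diploid (``hap_maternal`` and ``hap_paternal`` both
    meaningful); males are haploid and only ``hap_maternal`` is read.  A
    female's stored sperm (``sperm_hap``, ``sperm_infected``) is set once at
    her first mating and never changes.
    """

    __slots__ = (
        "female",
        "age",
        "infected",
        "hap_maternal",
        "hap_paternal",
        "D",
        "M",
        "Mp",
        "eggsM",
        "eggsMp",
        "mated",
        "sperm_hap",
        "sperm_infected",
    )

    def __init__(self, **arrays) -> None:
        for name in self.__slots__:
            setattr(self, name, arrays[name])

    @classmethod
    def empty(cls, L: int) -> "Population":
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int64)
        zb = np.zeros(0, dtype=bool)
        zh = np.zeros((0, L), dtype=np.uint8)
        return cls(
            female=zb.copy(),
            age=zi,
            infected=zb.copy(),
            hap_maternal=zh,
            hap_paternal=zh.copy(),
            D=z.copy(),
            M=z.copy(),
            Mp=z.copy(),
            eggsM=z.copy(),
            eggsMp=z.copy(),
            mated=zb.copy(),
            sperm_hap=zh.copy(),
            sperm_infected=zb.copy(),
        )

    @property
    def size(self) -> int:
        return self.female.shape[0]

    @property
    def L(self) -> int:
        return self.hap_maternal.shape[1]

    def subset(self, index) -> "Population":
        return Population(**{name: getattr(self, name)[index] for name in self.__slots__})

    @staticmethod
    def concat(a: "Population", b: "Population") -> "Population":
        if b.size == 0:
            return a
        if a.size == 0:
            return b
        return Population(
            **{
                name: np.concatenate([getattr(a, name), getattr(b, name)])
                for name in Population.__slots__
            }
        )

    def individual(self, i: int) -> "Individual":
        sperm = None
        if self.female[i] and self.mated[i]:
            sperm = StoredSperm(
                haplotype=self.sperm_hap[i].copy(),
                donor_infected=bool(self.sperm_infected[i]),
            )
        traits = {"D": float(self.D[i]), "M": float(self.M[i])}
        if self.female[i]:
            traits.update(
                Mp=float(self.Mp[i]),
                eggsM=float(self.eggsM[i]),
                eggsMp=float(self.eggsMp[i]),
            )
        return Individual(
            id=i,
            sex="female" if self.female[i] else "male",
            age=int(self.age[i]),
            infected=bool(self.infected[i]),
            hap_maternal=self.hap_maternal[i].copy(),
            hap_paternal=self.hap_paternal[i].copy() if self.female[i] else None,
            traits=traits,
            sperm=sperm,
        )


@dataclass(frozen=True)
class StoredSperm:
    haplotype: np.ndarray
    donor_infected: bool


@dataclass(frozen=True)
class Individual:
    """Read-only per-mite view of one slot of a :class:`Population`."""

    id: int
    sex: str
    age: int
    infected: bool
    hap_maternal: np.ndarray
    hap_paternal: np.ndarray | None
    traits: dict
    sperm: StoredSperm | None


@dataclass
class PopulationState:
    """The living population on a given day plus the logistic constants."""

    pop: Population
    day: int
    year: int
    A: float
    r: float
    rng: np.random.Generator
    born: int = 0
    deaths_by_age: np.ndarray = field(
        default_factory=lambda: np.zeros(_MAX_DEATH_AGE_BIN, dtype=np.int64)
    )
    extinct: bool = False


@dataclass(frozen=True)
class DailyRecord:
    """Per-day observables, measured on the population surviving the day."""

    day: int
    year: int
    pop_size: int
    inf_freq_female: float
    inf_freq_male: float
    inf_freq_all: float
    mf_ratio: float
    ci_cross_frac: float
    psi: float
    suppressor_freq: float
    newborn_supp_from_ci: float
    supp_lost_in_ci: float


@dataclass
class OvipositionStats:
    """Bookkeeping of one day's oviposition, for :func:`measure`."""

    mothers_laid: int = 0
    ci_mothers_laid: int = 0
    eggs_total: int = 0
    eggs_dead: int = 0
    eggs_male: int = 0
    eggs_female: int = 0
    supp_newborn_total: int = 0
    supp_newborn_from_ci: int = 0
    supp_killed_fm: int = 0
    supp_compat_newborn: int = 0


def alpha_from_sd(Sd: float, lam: float) -> float:
    """Extra per-egg fertilization probability implied by sex-allocation distortion.

    alpha = Sd/(1-lam); Sd may not exceed 1-lam, so alpha is a probability.
    """
    if lam >= 1.0:
        raise ValueError("lam must be < 1 for Sd to act on unfertilized eggs")
    alpha = Sd / (1.0 - lam)
    if alpha > 1.0 + 1e-12:
        raise ValueError(f"Sd={Sd} exceeds 1-lam={1-lam:.3g}; alpha would exceed 1")
    return min(alpha, 1.0)


def effective_ci(sigma_fm, sigma_md, suppressor_count, L: int):
    """CI strength after additive suppression by the fertilizing male's alleles.

    Each of the male's ``suppressor_count`` active alleles removes a 1/L share
    of both CI components.  Returns ``(theta, sigma_md_eff)`` where ``theta``
    is the hatching probability of a fertilized egg in an incompatible cross
    (1 - effective sigma_fm) and ``sigma_md_eff`` the probability that a
    hatching egg develops into a haploid male.
    """
    s = np.asarray(suppressor_count)
    if np.any(s < 0) or np.any(s > L):
        raise ValueError("suppressor_count must lie in [0, L]")
    factor = 1.0 - s / L
    theta = 1.0 - sigma_fm * factor
    sigma_md_eff = sigma_md * factor
    return theta, sigma_md_eff


def expected_eggs(age, M, Mp, D, eggsM, eggsMp):
    """Expected daily oviposition of a female at a given age (piecewise linear).

    Rises from ``eggsM`` at maturity ``M`` to ``eggsMp`` at the peak ``Mp``,
    then declines linearly to 0 at the death age ``D``; zero outside [M, D).
    """
    age = np.asarray(age, dtype=float)
    rising = (eggsMp * (age - M) + eggsM * (Mp - age)) / (Mp - M)
    falling = eggsMp * (D - age) / (D - Mp)
    out = np.where(age < Mp, rising, falling)
    out = np.where((age >= M) & (age < D), out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def draw_egg_count(expected, rng: np.random.Generator):
    """Realized egg count: Normal(expected, 0.5) rounded, clamped at zero."""
    expected = np.asarray(expected, dtype=float)
    draw = rng.normal(expected, 0.5)
    count = np.maximum(np.rint(draw), 0.0).astype(np.int64)
    if count.ndim == 0:
        return int(count)
    return count


def draw_traits(n: int, female: np.ndarray, params: ModelParams, rng: np.random.Generator):
    """Per-individual life-history traits, Normal(mean, trait_sd).

    Draws are repeated for individuals violating M < Mp < D so that every
    female has a well-formed oviposition schedule (violations are ~8 sigma
    events at the default means, so redraws are essentially never needed).
    """
    sd = params.trait_sd
    m_mean = np.where(female, params.M_female_mean, params.M_male_mean)
    D = rng.normal(params.D_mean, sd, n)
    M = rng.normal(m_mean, sd, n)
    Mp = rng.normal(params.Mp_mean, sd, n)
    eggsM = rng.normal(params.eggsM_mean, sd, n)
    eggsMp = rng.normal(params.eggsMp_mean, sd, n)
    for _ in range(100):
        bad = ~((M < Mp) & (Mp < D))
        if not bad.any():
            break
        k = int(bad.sum())
        D[bad] = rng.normal(params.D_mean, sd, k)
        M[bad] = rng.normal(m_mean[bad], sd, k)
        Mp[bad] = rng.normal(params.Mp_mean, sd, k)
    return D, M, Mp, eggsM, eggsMp


def init_population(params: ModelParams, rng: np.random.Generator | None = None) -> PopulationState:
    """Found a population of P0 mated adult females.

    Exactly round(omega0 * P0) females are infected (random assignment).  Each
    female is pre-fertilized by virtual sperm whose donor infection state
    equals her own (mirroring within-line matings of the founding cohort) and
    whose suppressor alleles are i.i.d. Bernoulli(suppressor_init_freq), as
    are her own haplotypes.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.P0
    L = params.L
    female = np.ones(n, dtype=bool)
    D, M, Mp, eggsM, eggsMp = draw_traits(n, female, params, rng)
    age = np.ceil(M).astype(np.int64)
    infected = np.zeros(n, dtype=bool)
    n_inf = int(round(params.omega0 * n))
    infected[rng.permutation(n)[:n_inf]] = True
    p = params.suppressor_init_freq
    hap_m = (rng.random((n, L)) < p).astype(np.uint8)
    hap_p = (rng.random((n, L)) < p).astype(np.uint8)
    sperm_hap = (rng.random((n, L)) < p).astype(np.uint8)
    pop = Population(
        female=female,
        age=age,
        infected=infected,
        hap_maternal=hap_m,
        hap_paternal=hap_p,
        D=D,
        M=M,
        Mp=Mp,
        eggsM=eggsM,
        eggsMp=eggsMp,
        mated=np.ones(n, dtype=bool),
        sperm_hap=sperm_hap,
        sperm_infected=infected.copy(),
    )
    A, r = params.logistic_constants(n)
    if not math.isfinite(r):
        # season founded at or above K/2: logistic target is ~K from day one
        r = 0.0
    state = PopulationState(pop=pop, day=0, year=0, A=A, r=r, rng=rng, born=n)
    return state


def mate_virgins(state: PopulationState, params: ModelParams) -> PopulationState:
    """Pair every virgin adult female with a uniformly random mature male.

    The chosen male's haplotype and infection state are stored for life
    (first-male sperm precedence); males may fertilize any number of females.
    With no mature male present, females stay virgin and retry the next day.
    """
    pop = state.pop
    virgins = np.flatnonzero(pop.female & ~pop.mated & (pop.age >= pop.M))
    if virgins.size == 0:
        return state
    males = np.flatnonzero(~pop.female & (pop.age >= pop.M))
    if males.size == 0:
        return state
    chosen = males[state.rng.integers(0, males.size, size=virgins.size)]
    pop.sperm_hap[virgins] = pop.hap_maternal[chosen]
    pop.sperm_infected[virgins] = pop.infected[chosen]
    pop.mated[virgins] = True
    return state


def produce_offspring(
    state: PopulationState,
    params: ModelParams,
    mothers: np.ndarray | None = None,
) -> tuple[Population, OvipositionStats]:
    """One day of oviposition by mated adult females; returns age-0 newborns.

    Per egg, in order: base count from the oviposition schedule; an extra egg
    with probability F for infected mothers; fertilization with probability
    lam, plus alpha = Sd/(1-lam) for remaining eggs of infected mothers;
    maternal transmission with probability 1-mu; an oocyte haplotype drawn
    locus-by-locus from the mother (free recombination); and the fate —
    unfertilized eggs become haploid males, fertilized eggs in compatible
    crosses become diploid females, and fertilized eggs in incompatible
    crosses die with probability 1-theta or develop as haploid males (with
    probability sigma_md_eff) carrying only maternal information, where theta
    and sigma_md_eff reflect the additive suppressors in the stored sperm.
    """
    pop = state.pop
    rng = state.rng
    L = pop.L
    if mothers is None:
        mothers = np.flatnonzero(pop.female & pop.mated & (pop.age >= pop.M) & (pop.age < pop.D))
    else:
        mothers = np.asarray(mothers, dtype=np.int64)
        if mothers.size and not (pop.female[mothers].all() and pop.mated[mothers].all()):
            raise ValueError("mothers must be mated females")
    stats = OvipositionStats()
    if mothers.size == 0:
        return Population.empty(L), stats

    exp = expected_eggs(
        pop.age[mothers], pop.M[mothers], pop.Mp[mothers], pop.D[mothers],
        pop.eggsM[mothers], pop.eggsMp[mothers],
    )
    base = draw_egg_count(exp, rng)
    mother_inf = pop.infected[mothers]
    counts = base.copy()
    if params.F > 0.0:
        extra = rng.binomial(base, params.F)
        counts = counts + np.where(mother_inf, extra, 0)

    laid = counts > 0
    mother_ci = ~mother_inf & pop.sperm_infected[mothers]
    stats.mothers_laid = int(laid.sum())
    stats.ci_mothers_laid = int((laid & mother_ci).sum())

    n_eggs = int(counts.sum())
    stats.eggs_total = n_eggs
    if n_eggs == 0:
        return Population.empty(L), stats

    em = np.repeat(mothers, counts)  # mother index per egg
    inf_m = pop.infected[em]
    donor_inf = pop.sperm_infected[em]

    fert = rng.random(n_eggs) < params.lam
    alpha = params.alpha
    if alpha > 0.0:
        fert |= (~fert) & inf_m & (rng.random(n_eggs) < alpha)
    egg_inf = inf_m & (rng.random(n_eggs) < 1.0 - params.mu)

    pick = rng.random((n_eggs, L)) < 0.5
    oocyte = np.where(pick, pop.hap_maternal[em], pop.hap_paternal[em]).astype(np.uint8)
    sperm = pop.sperm_hap[em]

    if params.ci_rescue_scope == "egg_level":
        incomp = fert & ~egg_inf & donor_inf
    else:
        incomp = fert & ~inf_m & donor_inf
    s = sperm.sum(axis=1)
    theta, md_eff = effective_ci(params.sigma_fm, params.sigma_md, s, L)
    die = incomp & (rng.random(n_eggs) >= theta)
    md_male = incomp & ~die & (rng.random(n_eggs) < md_eff)
    is_male = ~fert | md_male
    is_female = fert & ~die & ~md_male
    alive = ~die

    stats.eggs_dead = int(die.sum())
    stats.eggs_male = int(is_male.sum())
    stats.eggs_female = int(is_female.sum())

    # suppressor-allele flow bookkeeping (maternal + paternal contributions)
    oo_alleles = oocyte.sum(axis=1).astype(np.int64)
    sp_alleles = sperm.sum(axis=1).astype(np.int64)
    newborn_alleles = np.where(is_female, oo_alleles + sp_alleles, oo_alleles)
    cross_ci = ~inf_m & donor_inf  # mother-level cross type for the flow census
    stats.supp_newborn_total = int(newborn_alleles[alive].sum())
    stats.supp_newborn_from_ci = int(newborn_alleles[alive & cross_ci].sum())
    stats.supp_killed_fm = int((oo_alleles + sp_alleles)[die].sum())
    stats.supp_compat_newborn = int(newborn_alleles[alive & ~cross_ci].sum())

    n_new = int(alive.sum())
    if n_new == 0:
        return Population.empty(L), stats
    nf = is_female[alive]
    D, M, Mp, eggsM, eggsMp = draw_traits(n_new, nf, params, rng)
    hap_p = np.where(nf[:, None], sperm[alive], np.zeros(1, dtype=np.uint8))
    newborns = Population(
        female=nf,
        age=np.zeros(n_new, dtype=np.int64),
        infected=egg_inf[alive],
        hap_maternal=oocyte[alive],
        hap_paternal=hap_p.astype(np.uint8),
        D=D,
        M=M,
        Mp=Mp,
        eggsM=eggsM,
        eggsMp=eggsMp,
        mated=np.zeros(n_new, dtype=bool),
        sperm_hap=np.zeros((n_new, L), dtype=np.uint8),
        sperm_infected=np.zeros(n_new, dtype=bool),
    )
    return newborns, stats


def mortality_fraction(Pt: int, t: int, K: int, A: float, r: float) -> float:
    """Fraction of the population dying at the end of day t.

    psi_t = (Pt - K/(1 + A e^(-r t)))/Pt, clamped to [0, 1]; zero whenever the
    population sits below the logistic target.
    """
    if Pt <= 0:
        raise ValueError("Pt must be positive")
    target = K / (1.0 + A * math.exp(-r * t))
    return min(max((Pt - target) / Pt, 0.0), 1.0)


def apply_mortality_and_aging(
    state: PopulationState, psi: float, params: ModelParams
) -> PopulationState:
    """Remove round(psi * Pt) uniformly random individuals, then age survivors.

    Random removal is age-, sex- and infection-blind, so the population sex
    ratio is shaped by the fertilized-egg proportion lam alone.  Survivors
    reaching their individual death age D are then removed.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    pop = state.pop
    n = pop.size
    if n == 0:
        return state
    n_dead = int(round(psi * n))
    if n_dead > 0:
        order = state.rng.permutation(n)
        dead_idx = order[:n_dead]
        ages = np.minimum(pop.age[dead_idx], _MAX_DEATH_AGE_BIN - 1)
        state.deaths_by_age += np.bincount(ages, minlength=_MAX_DEATH_AGE_BIN)
        keep = np.ones(n, dtype=bool)
        keep[dead_idx] = False
        pop = pop.subset(keep)
    pop.age += 1
    senile = pop.age >= pop.D
    if senile.any():
        ages = np.minimum(pop.age[senile], _MAX_DEATH_AGE_BIN - 1)
        state.deaths_by_age += np.bincount(ages, minlength=_MAX_DEATH_AGE_BIN)
        pop = pop.subset(~senile)
    state.pop = pop
    return state


def measure(state: PopulationState, stats: OvipositionStats, psi: float, day: int) -> DailyRecord:
    """Populate the day's record from the surviving population.

    Frequencies over empty categories are reported as 0 by convention.
    """
    pop = state.pop
    n = pop.size
    females = pop.female
    nf = int(females.sum())
    nm = n - nf
    inf = pop.infected
    inf_f = int((inf & females).sum())
    inf_m = int(inf.sum()) - inf_f
    L = pop.L
    allele_count = int(pop.hap_maternal.sum()) + int(pop.hap_paternal[females].sum())
    allele_slots = L * (2 * nf + nm)
    return DailyRecord(
        day=day,
        year=state.year,
        pop_size=n,
        inf_freq_female=inf_f / nf if nf else 0.0,
        inf_freq_male=inf_m / nm if nm else 0.0,
        inf_freq_all=(inf_f + inf_m) / n if n else 0.0,
        mf_ratio=nm / nf if nf else 0.0,
        ci_cross_frac=stats.ci_mothers_laid / stats.mothers_laid if stats.mothers_laid else 0.0,
        psi=psi,
        suppressor_freq=allele_count / allele_slots if allele_slots else 0.0,
        newborn_supp_from_ci=(
            stats.supp_newborn_from_ci / stats.supp_newborn_total
            if stats.supp_newborn_total
            else 0.0
        ),
        supp_lost_in_ci=(
            stats.supp_killed_fm / stats.supp_compat_newborn
            if stats.supp_compat_newborn and stats.supp_killed_fm
            else 0.0
        ),
    )


def step_day(state: PopulationState, params: ModelParams) -> DailyRecord:
    """Advance the population by one day: mate, oviposit, cull, age, record."""
    t = state.day + 1
    if state.pop.size == 0:
        state.extinct = True
        state.day = t
        return DailyRecord(
            day=t, year=state.year, pop_size=0, inf_freq_female=0.0, inf_freq_male=0.0,
            inf_freq_all=0.0, mf_ratio=0.0, ci_cross_frac=0.0, psi=0.0,
            suppressor_freq=0.0, newborn_supp_from_ci=0.0, supp_lost_in_ci=0.0,
        )
    mate_virgins(state, params)
    newborns, stats = produce_offspring(state, params)
    state.pop = Population.concat(state.pop, newborns)
    state.born += newborns.size
    psi = mortality_fraction(state.pop.size, t, params.K, state.A, state.r)
    apply_mortality_and_aging(state, psi, params)
    record = measure(state, stats, psi, day=t)
    state.day = t
    return record


def run_season(state: PopulationState, params: ModelParams) -> list[DailyRecord]:
    """Run one reproductive season of T days, returning every daily record."""
    return [step_day(state, params) for _ in range(params.T)]


def run_replicate(
    params: ModelParams, seed: int | None = None
) -> tuple[PopulationState, pd.DataFrame]:
    """Initialize and run one full season; convenience wrapper for campaigns."""
    p = params if seed is None else params.replace(seed=seed)
    state = init_population(p)
    records = run_season(state, p)
    return state, records_to_frame(records)


def new_season(
    state: PopulationState, params: ModelParams, carryover: str = "full"
) -> PopulationState:
    """Transition into the next reproductive year.

    ``full`` carryover keeps the entire end-of-year population as founders
    (P0_season = population size; no extra drift), ``subsample`` keeps a
    uniformly random subset of size P0 (periodic bottleneck).  Carryover
    individuals retain their ages and states; the logistic constant A is
    recomputed from the new starting size while r is kept from the run's
    first season whenever the midpoint calibration is ill-posed (A <= 1).
    """
    if carryover not in ("full", "subsample"):
        raise ValueError("carryover must be 'full' or 'subsample'")
    pop = state.pop
    if carryover == "subsample" and pop.size > params.P0:
        keep = state.rng.permutation(pop.size)[: params.P0]
        state.pop = pop.subset(keep)
    p_start = max(state.pop.size, 1)
    A, r = params.logistic_constants(p_start) if p_start < params.K else (0.0, float("nan"))
    state.A = A
    if math.isfinite(r):
        state.r = r
    state.day = 0
    state.year += 1
    return state


def records_to_frame(records: list[DailyRecord]) -> pd.DataFrame:
    """Daily records as a tidy DataFrame, one row per day."""
    return pd.DataFrame([r.__dict__ for r in records])
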
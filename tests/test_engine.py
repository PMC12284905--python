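import math

import numpy as np
import pytest

from wolbsim.engine import (
    Population,
    PopulationState,
    alpha_from_sd,
    apply_mortality_and_aging,
    draw_egg_count,
    effective_ci,
    expected_eggs,
    init_population,
    mate_virgins,
    mortality_fraction,
    produce_offspring,
    run_season,
    step_day,
)
from wolbsim.params import ModelParams


def make_state(pop: Population, seed=0, A=99.0, r=None) -> PopulationState:
    if r is None:
        r = math.log(99.0) / 60.0
    return PopulationState(pop=pop, day=0, year=0, A=A, r=r,
                           rng=np.random.default_rng(seed))


def make_females(
    n,
    L=5,
    age=13,
    infected=False,
    mated=True,
    sperm_infected=False,
    sperm_suppressors=0,
    hap_fill=0,
    eggs=10.0,
):
    """Homogeneous mated adult females with controlled traits and sperm."""
    sperm = np.zeros((n, L), dtype=np.uint8)
    sperm[:, :sperm_suppressors] = 1
    return Population(
        female=np.ones(n, dtype=bool),
        age=np.full(n, age, dtype=np.int64),
        infected=np.full(n, infected, dtype=bool),
        hap_maternal=np.full((n, L), hap_fill, dtype=np.uint8),
        hap_paternal=np.full((n, L), hap_fill, dtype=np.uint8),
        D=np.full(n, 20.0),
        M=np.full(n, 11.0),
        Mp=np.full(n, 16.0),
        eggsM=np.full(n, eggs),
        eggsMp=np.full(n, eggs),
        mated=np.full(n, mated, dtype=bool),
        sperm_hap=sperm,
        sperm_infected=np.full(n, sperm_infected, dtype=bool),
    )


class TestExpectedEggs:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (11, 1.0),   # at maturity
            (16, 10.0),  # at the oviposition peak
            (13, 4.6),   # linear rise between M and Mp
            (9, 0.0),    # juvenile
            (18, 5.0),   # linear decline toward zero at D
            (20, 0.0),   # at the death age
        ],
    )
    def test_piecewise_schedule(self, age, expected):
        value = expected_eggs(age, M=11.0, Mp=16.0, D=20.0, eggsM=1.0, eggsMp=10.0)
        assert value == pytest.approx(expected)

    def test_vectorized_matches_scalar(self):
        ages = np.arange(0, 25)
        vec = expected_eggs(ages, 11.0, 16.0, 20.0, 1.0, 10.0)
        scal = [expected_eggs(a, 11.0, 16.0, 20.0, 1.0, 10.0) for a in ages]
        assert np.allclose(vec, scal)


class TestDrawEggCount:
    def test_never_negative(self, rng):
        counts = draw_egg_count(np.zeros(2000), rng)
        assert counts.min() >= 0

    def test_mean_recovers_expectation(self, rng):
        counts = draw_egg_count(np.full(20000, 10.0), rng)
        assert counts.mean() == pytest.approx(10.0, abs=0.05)

    def test_mid_expectation_concentrates(self, rng):
        counts = draw_egg_count(np.full(5000, 4.6), rng)
        assert np.mean(np.isin(counts, (4, 5))) > 0.9
        assert np.mean(counts == 5) > 0.3


class TestEffectiveCI:
    def test_worked_two_suppressor_example(self):
        theta, md = effective_ci(1.0, 0.0, 2, 5)
        assert theta == pytest.approx(0.40)

    def test_full_suppression(self):
        theta, md = effective_ci(0.98, 0.02, 5, 5)
        assert theta == pytest.approx(1.0) and md == pytest.approx(0.0)

    def test_no_suppression_beis(self):
        theta, md = effective_ci(0.98, 0.02, 0, 5)
        assert theta == pytest.approx(0.02) and md == pytest.approx(0.02)

    def test_rejects_out_of_range_count(self):
        with pytest.raises(ValueError):
            effective_ci(1.0, 0.0, 6, 5)


class TestAlphaFromSd:
    def test_zero(self):
        assert alpha_from_sd(0.0, 0.8) == 0.0

    def test_quarter(self):
        assert alpha_from_sd(0.05, 0.8) == pytest.approx(0.25)

    def test_maximum(self):
        assert alpha_from_sd(0.2, 0.8) == pytest.approx(1.0)

    def test_rejects_excess(self):
        with pytest.raises(ValueError):
            alpha_from_sd(0.25, 0.8)


class TestInitPopulation:
    def test_founders_are_mated_adult_females(self):
        p = ModelParams(omega0=0.5)
        state = init_population(p)
        pop = state.pop
        assert pop.size == 50
        assert pop.female.all() and pop.mated.all()
        assert (pop.age >= pop.M).all()

    def test_exact_infected_count(self):
        state = init_population(ModelParams(omega0=0.5, seed=3))
        assert int(state.pop.infected.sum()) == 25

    def test_full_infection_boundary(self):
        state = init_population(ModelParams(omega0=1.0))
        assert state.pop.infected.all() and state.pop.sperm_infected.all()

    def test_sperm_donor_matches_female_state(self):
        state = init_population(ModelParams(omega0=0.3, seed=1))
        assert (state.pop.sperm_infected == state.pop.infected).all()

    def test_logistic_constants(self):
        state = init_population(ModelParams())
        assert state.A == pytest.approx(99.0)
        assert state.r == pytest.approx(math.log(99.0) / 60.0)

    def test_suppressor_initialization(self):
        state = init_population(ModelParams(suppressor_init_freq=1.0))
        assert state.pop.hap_maternal.all() and state.pop.hap_paternal.all()
        assert state.pop.sperm_hap.all()


class TestMateVirgins:
    def _with_males(self, females, n_males, male_infected, L=5, hap_fill=1):
        males = Population(
            female=np.zeros(n_males, dtype=bool),
            age=np.full(n_males, 12, dtype=np.int64),
            infected=np.full(n_males, male_infected, dtype=bool),
            hap_maternal=np.full((n_males, L), hap_fill, dtype=np.uint8),
            hap_paternal=np.zeros((n_males, L), dtype=np.uint8),
            D=np.full(n_males, 20.0),
            M=np.full(n_males, 10.0),
            Mp=np.full(n_males, 16.0),
            eggsM=np.zeros(n_males),
            eggsMp=np.zeros(n_males),
            mated=np.zeros(n_males, dtype=bool),
            sperm_hap=np.zeros((n_males, L), dtype=np.uint8),
            sperm_infected=np.zeros(n_males, dtype=bool),
        )
        return Population.concat(females, males)

    def test_single_pairing_copies_sperm(self):
        females = make_females(1, mated=False)
        state = make_state(self._with_males(females, 1, male_infected=True))
        mate_virgins(state, ModelParams())
        assert state.pop.mated[0]
        assert state.pop.sperm_infected[0]
        assert state.pop.sperm_hap[0].sum() == 5

    def test_no_males_means_retry(self):
        state = make_state(make_females(3, mated=False))
        mate_virgins(state, ModelParams())
        assert not state.pop.mated.any()

    def test_males_fertilize_many_females(self):
        females = make_females(100, mated=False)
        state = make_state(self._with_males(females, 2, male_infected=False))
        mate_virgins(state, ModelParams())
        assert state.pop.mated[:100].all()

    def test_sperm_never_overwritten(self):
        females = make_females(1, mated=True, sperm_infected=False, sperm_suppressors=0)
        state = make_state(self._with_males(females, 1, male_infected=True))
        mate_virgins(state, ModelParams())
        assert not state.pop.sperm_infected[0]


class TestProduceOffspring:
    def test_compatible_cross_sex_ratio(self):
        pop = make_females(200, infected=False, sperm_infected=False)
        state = make_state(pop)
        newborns, stats = produce_offspring(state, ModelParams())
        frac_female = newborns.female.mean()
        assert frac_female == pytest.approx(0.8, abs=0.02)
        assert not newborns.infected.any()

    def test_fate_conservation(self):
        pop = make_females(300, infected=False, sperm_infected=True)
        state = make_state(pop)
        p = ModelParams(sigma_fm=0.6, sigma_md=0.4, sigma_total=1.0)
        newborns, stats = produce_offspring(state, p)
        assert stats.eggs_dead + stats.eggs_male + stats.eggs_female == stats.eggs_total
        assert newborns.size == stats.eggs_male + stats.eggs_female

    def test_pure_fm_ci_kills_all_fertilized(self):
        pop = make_females(200, infected=False, sperm_infected=True)
        state = make_state(pop)
        p = ModelParams(sigma_fm=1.0, sigma_md=0.0, sigma_total=1.0)
        newborns, _ = produce_offspring(state, p)
        assert not newborns.female.any()  # only unfertilized-egg males hatch

    def test_pure_md_ci_converts_all_fertilized(self):
        pop = make_females(200, infected=False, sperm_infected=True)
        state = make_state(pop)
        p = ModelParams(sigma_fm=0.0, sigma_md=1.0, sigma_total=1.0)
        newborns, stats = produce_offspring(state, p)
        assert stats.eggs_dead == 0
        assert not newborns.female.any()
        assert not newborns.infected.any()

    def test_partial_fm_md_split(self, ):
        pop = make_females(2000, infected=False, sperm_infected=True)
        state = make_state(pop)
        p = ModelParams(sigma_fm=0.9, sigma_md=0.1, sigma_total=1.0)
        newborns, stats = produce_offspring(state, p)
        fert = stats.eggs_total * p.lam
        # ~90% of fertilized eggs die; ~10% of survivors develop as males
        assert stats.eggs_dead / fert == pytest.approx(0.9, abs=0.02)
        surv_fert = fert - stats.eggs_dead
        md_males = stats.eggs_male - (stats.eggs_total - fert)
        assert md_males / surv_fert == pytest.approx(0.1, abs=0.04)

    def test_perfect_transmission_infects_all(self):
        pop = make_females(100, infected=True, sperm_infected=True)
        state = make_state(pop)
        newborns, _ = produce_offspring(state, ModelParams(mu=0.0))
        assert newborns.infected.all()

    def test_imperfect_transmission_rate(self):
        pop = make_females(1000, infected=True, sperm_infected=True)
        state = make_state(pop)
        newborns, _ = produce_offspring(state, ModelParams(mu=0.05))
        assert newborns.infected.mean() == pytest.approx(0.95, abs=0.01)

    def test_sd_biases_sex_ratio(self):
        pop = make_females(1000, infected=True, sperm_infected=True)
        state = make_state(pop)
        newborns, _ = produce_offspring(state, ModelParams(Sd=0.2, mu=0.0))
        # alpha = 1: every egg fertilized, all offspring female
        assert newborns.female.all()

    def test_fecundity_boost_increases_output(self):
        n = 500
        base_counts = []
        for infected in (False, True):
            pop = make_females(n, infected=infected, sperm_infected=infected)
            state = make_state(pop, seed=7)
            _, stats = produce_offspring(state, ModelParams(F=0.10, mu=0.0))
            base_counts.append(stats.eggs_total)
        assert base_counts[1] / base_counts[0] == pytest.approx(1.10, abs=0.03)

    def test_theta_oracle_per_suppressor_count(self):
        """Hatch fraction of incompatible fertilized eggs is 1 - sigma_fm(1-s/L)."""
        p = ModelParams(sigma_fm=1.0, sigma_md=0.0, sigma_total=1.0, lam=0.8)
        for s in range(6):
            pop = make_females(500, infected=False, sperm_infected=True,
                               sperm_suppressors=s, eggs=10.0)
            state = make_state(pop, seed=100 + s)
            _, stats = produce_offspring(state, p)
            fert = p.lam * stats.eggs_total
            hatch = 1.0 - stats.eggs_dead / fert
            expect = 1.0 - 1.0 * (1.0 - s / 5.0)
            assert hatch == pytest.approx(expect, abs=3 * math.sqrt(0.25 / fert) + 1e-9)

    def test_unmated_female_rejected(self):
        pop = make_females(1, mated=False)
        state = make_state(pop)
        with pytest.raises(ValueError, match="mated"):
            produce_offspring(state, ModelParams(), mothers=np.array([0]))

    def test_egg_level_rescue_exposes_mu_loss_eggs(self):
        p = ModelParams(sigma_fm=1.0, sigma_md=0.0, sigma_total=1.0, mu=0.5,
                        ci_rescue_scope="egg_level")
        pop = make_females(800, infected=True, sperm_infected=True)
        state = make_state(pop, seed=11)
        _, stats = produce_offspring(state, p)
        assert stats.eggs_dead > 0  # uninfected eggs of infected mothers die
        # under female-level rescue the same cross kills nothing
        pop2 = make_females(800, infected=True, sperm_infected=True)
        state2 = make_state(pop2, seed=11)
        _, stats2 = produce_offspring(state2, p.replace(ci_rescue_scope="female_level"))
        assert stats2.eggs_dead == 0


class TestMortality:
    def test_clamped_to_zero_below_target(self):
        assert mortality_fraction(100, 60, 5000, 99.0, math.log(99) / 60) == 0.0

    def test_half_when_double_target(self):
        t, K, A, r = 60, 5000, 99.0, math.log(99) / 60
        target = K / (1 + A * math.exp(-r * t))
        assert target == pytest.approx(2500.0)
        assert mortality_fraction(int(2 * target), t, K, A, r) == pytest.approx(0.5)

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            mortality_fraction(0, 1, 5000, 99.0, 0.07)

    def test_psi_zero_leaves_only_age_deaths(self):
        pop = make_females(50, age=19)
        state = make_state(pop)
        apply_mortality_and_aging(state, 0.0, ModelParams())
        assert state.pop.size == 0  # all reached D = 20
        assert state.deaths_by_age[20] == 50

    def test_removal_count_is_exact(self):
        pop = make_females(100, age=5)
        state = make_state(pop)
        apply_mortality_and_aging(state, 0.3, ModelParams())
        assert state.pop.size == 70
        assert (state.pop.age == 6).all()


class TestStepAndSeason:
    def test_fixation_is_absorbing(self):
        p = ModelParams(omega0=1.0, mu=0.0, K=500, sigma_fm=0.98, sigma_md=0.02,
                        sigma_total=1.0)
        state = init_population(p)
        for _ in range(40):
            rec = step_day(state, p)
        assert rec.inf_freq_all == 1.0

    def test_zero_infection_is_absorbing(self):
        p = ModelParams(omega0=0.0, K=500)
        state = init_population(p)
        recs = [step_day(state, p) for _ in range(40)]
        assert all(r.inf_freq_all == 0.0 for r in recs)

    def test_empty_population_records_zeros(self):
        pop = make_females(0)
        state = make_state(pop)
        rec = step_day(state, ModelParams())
        assert state.extinct and rec.pop_size == 0 and rec.mf_ratio == 0.0

    def test_season_length_and_day_grid(self):
        p = ModelParams(K=400, T=30)
        state = init_population(p)
        recs = run_season(state, p)
        assert len(recs) == 30
        assert [r.day for r in recs] == list(range(1, 31))

    def test_population_tracks_logistic_target(self):
        p = ModelParams(K=1000)
        state = init_population(p)
        recs = run_season(state, p)
        target60 = p.K / (1 + state.A * math.exp(-state.r * 60))
        assert recs[59].pop_size == pytest.approx(target60, rel=0.1)
        assert recs[-1].pop_size == pytest.approx(p.K, rel=0.1)

    def test_individual_view_roundtrip(self):
        state = init_population(ModelParams(omega0=1.0, suppressor_init_freq=1.0))
        ind = state.pop.individual(0)
        assert ind.sex == "female" and ind.infected
        assert ind.sperm is not None and ind.sperm.donor_infected
        assert ind.hap_maternal.sum() == 5 and ind.hap_paternal.sum() == 5
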
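import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hybridzone import (Individual, Population, SimulationParams,
                        acceptance_probability, choose_father, disperse,
                        expected_offspring, initialize_population,
                        local_density, make_offspring, mating_trait,
                        run_generation, run_simulation)
from hybridzone.simulator import reflect_into_unit, uniform_density_at_capacity


# ---------------------------------------------------------------------------
# mating trait

@pytest.mark.parametrize("genotype, dominance, expected", [
    ([2], 0.75, 1.0),            # dominant homozygote: full phenotype
    ([1], 0.75, 0.75),           # heterozygote expresses the coefficient
    ([1, 0], 0.5, 0.25),         # mean over loci
    ([0], 0.3, 0.0),
    ([1], 1.0, 1.0),             # complete dominance
    ([2, 2], 0.5, 1.0),
])
def test_mating_trait_values(genotype, dominance, expected):
    assert mating_trait(genotype, dominance) == pytest.approx(expected)


@given(st.lists(st.integers(0, 2), min_size=1, max_size=4))
def test_codominant_trait_is_mean_dosage(genotype):
    assert mating_trait(genotype, 0.5) == pytest.approx(
        np.mean(genotype) / 2.0)


def test_mating_trait_empty_genotype_errors():
    with pytest.raises(ValueError):
        mating_trait([], 0.5)


# ---------------------------------------------------------------------------
# mate acceptance

@pytest.mark.parametrize("tf, tm, ratio, expected", [
    (0.3, 0.3, 0.5, 1.0),
    (0.0, 1.0, 0.75, 0.75),
    (0.0, 0.5, 0.5, 0.5 ** 0.25),
    (1.0, 0.0, 0.5, 0.5),
])
def test_acceptance_examples(tf, tm, ratio, expected):
    assert acceptance_probability(tf, tm, ratio) == pytest.approx(expected)


@given(st.floats(0, 1), st.floats(0, 1),
       st.floats(0.01, 1, exclude_min=False))
def test_acceptance_closed_form(tf, tm, ratio):
    assert acceptance_probability(tf, tm, ratio) == pytest.approx(
        ratio ** ((tf - tm) ** 2))


def test_acceptance_degenerate_ratio_errors():
    with pytest.raises(ValueError):
        acceptance_probability(0.1, 0.2, 0.0)


# ---------------------------------------------------------------------------
# density and reproduction

def _pop(locations, n_mating=1, n_neutral=3, dosage=0):
    n = len(locations)
    return Population(np.array(locations, float),
                      np.full((n, n_mating), dosage, np.int8),
                      np.full((n, n_neutral), dosage, np.int8))


def test_local_density_self_only():
    pop = _pop([0.5])
    assert local_density(0.5, pop, 0.01) == pytest.approx(1.0, abs=1e-9)


def test_local_density_coincident_pair():
    pop = _pop([0.4, 0.4])
    assert local_density(0.4, pop, 0.01) == pytest.approx(2.0, abs=1e-9)


def test_local_density_one_sd_apart():
    pop = _pop([0.5, 0.51])
    assert local_density(0.5, pop, 0.01) == pytest.approx(
        1.0 + math.exp(-0.5), abs=1e-9)


def test_local_density_edge_correction_keeps_uniform_flat():
    # uniform population: corrected density should be ~equal at the edge
    # and in the interior
    x = np.linspace(0, 1, 2001)
    pop = _pop(x)
    interior = local_density(0.5, pop, 0.01)
    edge = local_density(0.0, pop, 0.01)
    assert edge == pytest.approx(interior, rel=0.02)


def test_expected_offspring_fixed_points():
    params = SimulationParams()
    rho0 = uniform_density_at_capacity(params)
    assert expected_offspring(rho0, params) == pytest.approx(1.0)
    assert expected_offspring(0.0, params) == pytest.approx(1.05)
    assert expected_offspring(2 * rho0, params) == pytest.approx(1.05 / 1.10)


def test_hybrid_fitness_scales_offspring():
    params = SimulationParams(hybrid_fitness=0.5)
    assert expected_offspring(0.0, params) == pytest.approx(0.525)


# ---------------------------------------------------------------------------
# mate search

def test_choose_father_single_identical_candidate(rng):
    params = SimulationParams(pref_ratio=0.5)
    pop = _pop([0.5, 0.505], dosage=0)
    mother = pop.individual(0)
    father = choose_father(mother, pop, params, rng, mother_index=0)
    assert father is not None
    assert father.location == pytest.approx(0.505)


def test_choose_father_complete_assortment_rejects_opposite(rng):
    params = SimulationParams(pref_ratio=1e-12, dominance=0.5)
    pop = Population(np.array([0.5, 0.505]),
                     np.array([[0], [2]], np.int8),
                     np.zeros((2, 3), np.int8))
    mother = pop.individual(0)
    assert choose_father(mother, pop, params, rng, mother_index=0) is None


def test_choose_father_random_mating_never_rejects(rng):
    params = SimulationParams(pref_ratio=1.0)
    pop = Population(np.array([0.5, 0.505, 0.495]),
                     np.array([[0], [2], [1]], np.int8),
                     np.zeros((3, 3), np.int8))
    for _ in range(20):
        assert choose_father(pop.individual(0), pop, params, rng,
                             mother_index=0) is not None


def test_choose_father_alone_returns_none(rng):
    params = SimulationParams()
    pop = _pop([0.5])
    assert choose_father(pop.individual(0), pop, params, rng,
                         mother_index=0) is None


# ---------------------------------------------------------------------------
# transmission and dispersal

def test_make_offspring_fixed_parents(rng):
    mother = Individual(0.5, [0], [0, 0, 0])
    father = Individual(0.5, [0], [0, 0, 0])
    child = make_offspring(mother, father, rng)
    assert child.mating_genotype.tolist() == [0]
    assert child.neutral_genotype.tolist() == [0, 0, 0]


def test_make_offspring_opposite_homozygotes_always_het(rng):
    mother = Individual(0.5, [2], [2, 2, 2])
    father = Individual(0.5, [0], [0, 0, 0])
    for _ in range(20):
        child = make_offspring(mother, father, rng)
        assert child.mating_genotype.tolist() == [1]
        assert child.neutral_genotype.tolist() == [1, 1, 1]


def test_het_cross_segregates_one_two_one(rng):
    mother = Individual(0.5, [1], [1])
    father = Individual(0.5, [1], [1])
    dosages = [make_offspring(mother, father, rng).mating_genotype[0]
               for _ in range(3000)]
    counts = np.bincount(dosages, minlength=3)
    chi2 = stats.chisquare(counts, f_exp=3000 * np.array([.25, .5, .25]))
    assert chi2.pvalue > 0.001


def test_disperse_zero_sd_is_identity(rng):
    assert disperse(0.5, 0.0, rng) == 0.5


@pytest.mark.parametrize("raw, expected", [
    (-0.01, 0.01), (1.03, 0.97), (0.42, 0.42), (-1.2, 0.8),
])
def test_reflection_rule(raw, expected):
    assert reflect_into_unit(raw) == pytest.approx(expected)


@given(st.floats(-5, 5))
def test_reflection_lands_in_unit_interval(raw):
    assert 0.0 <= reflect_into_unit(raw) <= 1.0


# ---------------------------------------------------------------------------
# initialization

def test_initialize_population(rng):
    params = SimulationParams(carrying_capacity_per_species=800)
    pop = initialize_population(params, rng)
    assert len(pop) == 1600
    k = 800
    assert np.all(pop.locations[:k] <= 0.48)
    assert np.all(pop.locations[k:] >= 0.52)
    assert np.all(pop.mating[:k] == 0) and np.all(pop.mating[k:] == 2)
    assert np.all(pop.neutral[:k] == 0) and np.all(pop.neutral[k:] == 2)
    # symmetric initialization: pooled allele-1 frequency is exactly 0.5
    assert pop.mating.mean() / 2 == pytest.approx(0.5)
    assert pop.neutral.mean() / 2 == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# generation loop

def test_run_generation_is_deterministic(small_params):
    rng1 = np.random.default_rng(3)
    rng2 = np.random.default_rng(3)
    pop = initialize_population(small_params, np.random.default_rng(0))
    a = run_generation(pop, small_params, rng1)
    b = run_generation(pop, small_params, rng2)
    assert np.array_equal(a.locations, b.locations)
    assert np.array_equal(a.mating, b.mating)
    assert np.array_equal(a.neutral, b.neutral)
    assert a.generation == pop.generation + 1


def test_run_generation_locations_stay_in_transect(small_params, rng):
    pop = initialize_population(small_params, rng)
    nxt = run_generation(pop, small_params, rng)
    assert nxt.locations.min() >= 0.0 and nxt.locations.max() <= 1.0
    assert np.isin(nxt.mating, (0, 1, 2)).all()


def test_run_generation_requires_individuals(small_params, rng):
    empty = Population(np.empty(0), np.empty((0, 1), np.int8),
                       np.empty((0, 3), np.int8))
    with pytest.raises(ValueError):
        run_generation(empty, small_params, rng)


def test_single_species_population_is_demographically_stationary():
    """A uniform single-species population stays near carrying capacity."""
    params = SimulationParams(carrying_capacity_per_species=400,
                              pref_ratio=1.0)
    sizes = []
    for rep in range(10):
        rng = np.random.default_rng(100 + rep)
        n0 = 2 * params.carrying_capacity_per_species
        pop = Population(rng.uniform(0, 1, n0),
                         np.zeros((n0, 1), np.int8),
                         np.zeros((n0, 3), np.int8))
        for _ in range(100):
            pop = run_generation(pop, params, rng)
        sizes.append(len(pop))
    mean_size = np.mean(sizes)
    assert mean_size == pytest.approx(800, rel=0.05)


def test_random_mating_conserves_allele_frequencies():
    """pref_ratio 1, codominance: pooled frequencies drift around 0.5."""
    params = SimulationParams(carrying_capacity_per_species=400,
                              pref_ratio=1.0, dominance=0.5,
                              n_generations=80, snapshot_interval=80)
    finals = []
    for rep in range(8):
        traj = run_simulation(params.replace(seed=500 + rep))
        snap = traj.final
        finals.append([snap.mating_freq.mean(), snap.neutral_freq.mean()])
    finals = np.array(finals)
    # binomial-scale drift: SD of pooled frequency after t generations is
    # roughly sqrt(t p q / 2N) ~ 0.07 here; replicate means must bracket 0.5
    se = finals.std(ddof=1) / np.sqrt(finals.shape[0])
    assert abs(finals.mean() - 0.5) < 3 * max(se, 0.01)
    assert finals.std(ddof=1) < 3 * np.sqrt(80 * 0.25 / 800)


def test_neutral_loci_are_exchangeable():
    """The three neutral loci have indistinguishable final frequencies."""
    params = SimulationParams(carrying_capacity_per_species=250,
                              n_generations=60, snapshot_interval=60)
    per_locus = []
    for rep in range(10):
        rng = np.random.default_rng(900 + rep)
        pop = initialize_population(params.replace(seed=900 + rep), rng)
        for _ in range(params.n_generations):
            pop = run_generation(pop, params, rng)
        per_locus.append(pop.neutral.mean(axis=0) / 2.0)
    per_locus = np.array(per_locus)
    kw = stats.kruskal(*(per_locus[:, j] for j in range(3)))
    assert kw.pvalue > 0.01


def test_run_simulation_snapshot_schedule():
    params = SimulationParams(carrying_capacity_per_species=150,
                              n_generations=20, snapshot_interval=5, seed=4)
    traj = run_simulation(params)
    assert [s.generation for s in traj.snapshots] == [0, 5, 10, 15, 20]
    assert not traj.extinct

    zero = run_simulation(params.replace(n_generations=0))
    assert len(zero.snapshots) == 1
    assert zero.snapshots[0].generation == 0


def test_run_simulation_is_seed_deterministic():
    params = SimulationParams(carrying_capacity_per_species=150,
                              n_generations=10, seed=11)
    a, b = run_simulation(params), run_simulation(params)
    assert np.array_equal(a.final.locations, b.final.locations)
    assert np.array_equal(a.final.mating_freq, b.final.mating_freq)
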
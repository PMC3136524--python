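"""Ensemble specs, direct and MCMC sampling, diversity summaries.

Uniformity of the samplers over exhaustively enumerable genotype spaces is
exercised at full chain length in the acceptance suite; here the focus is
proposal symmetry, detailed balance, constraint checking, caching
equivalence and reproducibility.
"""

import itertools
import random
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

import metnetrand as mn
from metnetrand import ensembles
from metnetrand.ensembles import ChainParams, EnsembleError, EnsembleSpec
from metnetrand.fba_core import ViabilityChecker
from metnetrand.universe_io import Environment

from conftest import cap_toy_universe, viability_toy_universe


class TestEnsembleSpec:
    def test_levels_and_requirements(self, synthetic_case):
        _, universe, _, truth = synthetic_case
        EnsembleSpec.build("R", universe, 10)
        with pytest.raises(EnsembleError, match="cap"):
            EnsembleSpec("RM", 10, universe.metabolic_ids)
        with pytest.raises(EnsembleError, match="pool"):
            EnsembleSpec.build("uRM", universe, 10, max_metabolites=50)
        with pytest.raises(EnsembleError, match="environments"):
            EnsembleSpec("uRM-V2", 10, universe.metabolic_ids, 50, truth.environments[:1])
        with pytest.raises(EnsembleError):
            EnsembleSpec("R", 10 ** 6, universe.metabolic_ids)

    def test_chain_params_validation(self):
        with pytest.raises(EnsembleError):
            ChainParams(burn_in=0)
        assert ChainParams(burn_in=10, thin=5, n_save=3).total_steps == 25


class TestSampleR:
    def test_full_pool_single_subset(self, glycolysis_universe):
        out = mn.sample_R(glycolysis_universe, 3, 5, seed=0)
        assert all(g == glycolysis_universe.metabolic_ids for g in out)

    def test_zero_size(self, glycolysis_universe):
        assert mn.sample_R(glycolysis_universe, 0, 3, seed=0) == [frozenset()] * 3

    def test_oversized_raises(self, glycolysis_universe):
        with pytest.raises(EnsembleError):
            mn.sample_R(glycolysis_universe, 4, 1, seed=0)

    def test_uniform_over_enumerable_subsets(self):
        universe = cap_toy_universe()
        pool = sorted(universe.metabolic_ids)[:5]
        sub = universe.restrict(pool)
        draws = mn.sample_R(sub, 3, 30_000, seed=1)
        counts = Counter(draws)
        assert len(counts) == 10  # C(5,3)
        _, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestProposeSwap:
    def test_enumerated_distribution(self):
        rng = random.Random(0)
        pool = frozenset("abc")
        counts = Counter(mn.propose_swap(frozenset("ab"), pool, rng) for _ in range(4000))
        assert set(counts) == {frozenset("ac"), frozenset("bc")}
        assert abs(counts[frozenset("ac")] / 4000 - 0.5) < 0.05

    def test_unique_swap(self):
        rng = random.Random(0)
        assert mn.propose_swap(frozenset("a"), frozenset("ab"), rng) == frozenset("b")

    def test_pool_exhausted_raises(self):
        with pytest.raises(EnsembleError):
            mn.propose_swap(frozenset("ab"), frozenset("ab"), random.Random(0))

    def test_proposal_symmetry_on_toy_pool(self):
        """P(G -> G') = P(G' -> G) for every neighbour pair: both equal
        1/(n * |pool \\ G|), constant across genotypes of fixed size."""
        pool = sorted("abcde")
        n = 3
        genotypes = [frozenset(c) for c in itertools.combinations(pool, n)]
        for g in genotypes:
            neighbours = Counter()
            for out in g:
                for new in set(pool) - g:
                    neighbours[g - {out} | {new}] += 1
            # every reachable neighbour arises from exactly one (out, new) pair
            assert set(neighbours.values()) == {1}
            assert len(neighbours) == n * (len(pool) - n)


class TestSatisfies:
    def test_cheap_constraints(self, synthetic_case):
        _, universe, _, truth = synthetic_case
        n = len(truth.seed_genotype)
        m = mn.distinct_metabolite_count(truth.seed_genotype, universe)
        spec = EnsembleSpec("RM", n, universe.metabolic_ids, max_metabolites=m)
        assert ensembles.satisfies(truth.seed_genotype, spec, universe)
        tight = EnsembleSpec("RM", n, universe.metabolic_ids, max_metabolites=m - 1)
        assert not ensembles.satisfies(truth.seed_genotype, tight, universe)
        wrong_size = EnsembleSpec("R", n - 1, universe.metabolic_ids)
        assert not ensembles.satisfies(truth.seed_genotype, wrong_size, universe)

    def test_viability_constraint(self, synthetic_case):
        _, universe, _, truth = synthetic_case
        n = len(truth.seed_genotype)
        m = mn.distinct_metabolite_count(truth.seed_genotype, universe)
        spec = EnsembleSpec("uRM-V1", n, universe.metabolic_ids, m, truth.environments[:1])
        assert ensembles.satisfies(truth.seed_genotype, spec, universe)
        essential = sorted(truth.planted_essential)[0]
        swap_in = sorted(universe.metabolic_ids - truth.seed_genotype)[0]
        broken = truth.seed_genotype - {essential} | {swap_in}
        assert not ensembles.satisfies(broken, spec, universe)


class TestRunMCMC:
    def test_size_only_spec_accepts_everything(self):
        universe = cap_toy_universe()
        spec = EnsembleSpec("R", 4, universe.metabolic_ids)
        start = frozenset(sorted(universe.metabolic_ids)[:4])
        s = ensembles.run_mcmc(spec, start, ChainParams(burn_in=100, thin=10, n_save=50, seed=0), universe)
        assert s.acceptance_rate == pytest.approx(1.0)
        assert len(s.genotypes) == 50

    def test_start_outside_ensemble_raises(self):
        universe = cap_toy_universe()
        spec = EnsembleSpec("RM", 4, universe.metabolic_ids, max_metabolites=3)
        start = frozenset(sorted(universe.metabolic_ids)[:4])  # touches > 3 metabolites
        with pytest.raises(EnsembleError, match="start"):
            ensembles.run_mcmc(spec, start, ChainParams(seed=0), universe)

    def test_reproducible_under_seed(self):
        universe = cap_toy_universe()
        spec = EnsembleSpec("RM", 4, universe.metabolic_ids, max_metabolites=6)
        start = frozenset(["r0", "r1", "r2", "r3"])
        params = ChainParams(burn_in=500, thin=20, n_save=30, seed=9)
        a = ensembles.run_mcmc(spec, start, params, universe)
        b = ensembles.run_mcmc(spec, start, params, universe)
        assert a.genotypes == b.genotypes
        assert a.acceptance_rate == b.acceptance_rate

    def test_saved_genotypes_satisfy_spec(self):
        universe = cap_toy_universe()
        spec = EnsembleSpec("RM", 4, universe.metabolic_ids, max_metabolites=6)
        start = frozenset(["r0", "r1", "r2", "r3"])
        s = ensembles.run_mcmc(spec, start, ChainParams(burn_in=200, thin=10, n_save=40, seed=3), universe)
        assert all(ensembles.satisfies(g, spec, universe) for g in s.genotypes)

    def test_transition_matrix_doubly_stochastic(self):
        """Three-genotype toy: accept-iff-valid with the symmetric swap
        proposal yields a doubly stochastic transition matrix over the
        valid set, hence a uniform stationary distribution."""
        universe = cap_toy_universe()
        pool = ["r0", "r1", "r2"]
        genotypes = [frozenset(c) for c in itertools.combinations(pool, 2)]
        cap = 5
        valid = [g for g in genotypes
                 if mn.distinct_metabolite_count(g, universe) <= cap]
        assert 2 <= len(valid) <= 3
        P = np.zeros((len(genotypes), len(genotypes)))
        index = {g: i for i, g in enumerate(genotypes)}
        for g in valid:
            moves = [(out, new) for out in g for new in set(pool) - g]
            for out, new in moves:
                target = g - {out} | {new}
                dest = target if target in valid else g
                P[index[g], index[dest]] += 1 / len(moves)
        sub = P[np.ix_([index[g] for g in valid], [index[g] for g in valid])]
        assert np.allclose(sub.sum(axis=1), 1.0)
        assert np.allclose(sub.sum(axis=0), 1.0)

    def test_viability_cache_matches_uncached_chain(self):
        universe = viability_toy_universe()
        env = Environment(carbon_source="A")
        spec = EnsembleSpec("uRM-V1", 4, universe.metabolic_ids, 10, [env])
        start = frozenset(["r0", "r3", "r1", "r2"])
        params = ChainParams(burn_in=200, thin=10, n_save=30, seed=4)
        cached = ensembles.run_mcmc(spec, start, params, universe)
        fresh_checker = ViabilityChecker(universe, [env], pool=spec.pool)
        fresh_checker._cache = NoCache()
        uncached = ensembles.run_mcmc(spec, start, params, universe, checker=fresh_checker)
        assert cached.genotypes == uncached.genotypes
        assert cached.acceptance_rate == uncached.acceptance_rate


class NoCache(dict):
    """A dict that forgets everything, forcing an LP per viability query."""

    def __setitem__(self, key, value):
        pass


class TestDiversity:
    def test_identical_genotypes(self):
        g = frozenset("abc")
        out = ensembles.diversity_summary([g, g, g])
        assert out["mean_dissimilarity"] == 0.0
        assert out["core_set"] == g

    def test_disjoint_genotypes(self):
        out = ensembles.diversity_summary([frozenset("ab"), frozenset("cd")])
        assert out["mean_dissimilarity"] == 1.0
        assert out["core_set"] == frozenset()

    def test_matches_pairwise_brute_force(self):
        rng = random.Random(2)
        genotypes = [frozenset(rng.sample("abcdefghij", 4)) for _ in range(12)]
        out = ensembles.diversity_summary(genotypes)
        vals = [mn.dissimilarity(g1, g2)
                for g1 in genotypes for g2 in genotypes if g1 is not g2]
        assert out["mean_dissimilarity"] == pytest.approx(np.mean(vals))

    def test_needs_two_genotypes(self):
        with pytest.raises(EnsembleError):
            ensembles.diversity_summary([frozenset("ab")])


class TestSampleIO:
    def test_round_trip(self, tmp_path):
        universe = cap_toy_universe()
        spec = EnsembleSpec("RM", 4, universe.metabolic_ids, max_metabolites=6)
        start = frozenset(["r0", "r1", "r2", "r3"])
        s = ensembles.run_mcmc(spec, start, ChainParams(burn_in=100, thin=5, n_save=20, seed=1), universe)
        path = tmp_path / "sample.jsonl"
        ensembles.write_sample(s, path)
        header, genotypes = ensembles.read_sample(path)
        assert genotypes == s.genotypes
        assert header["level"] == "RM" and header["seed"] == 1
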
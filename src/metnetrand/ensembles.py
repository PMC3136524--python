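"""Nested randomized-network ensembles and their uniform samplers.

The ensembles are nested sets of genotypes (fixed-size reaction subsets)
with cumulative constraints:

=========  =============================================================
R          exactly n reactions from the full universe
RM         ... and at most m_max distinct metabolites
uRM        ... drawn from the unblocked reaction pool only
uRM-Vk     ... and FBA-viable on each of k minimal environments
=========  =============================================================

R is sampled directly (uniform n-subsets).  The others use reaction-swap
MCMC: a trial move removes one uniformly chosen member and adds one
uniformly chosen non-member (a symmetric proposal) and is accepted iff
the new genotype satisfies every constraint.  Accept-iff-valid with a
symmetric proposal is the Metropolis rule for a uniform target, so every
genotype of the ensemble is equiprobable in the stationary distribution.
Rejected trials advance the step counter ("attempted swaps").
"""

from __future__ import annotations

import json
import logging
import random
import re
from dataclasses import dataclass, field

import numpy as np

from metnetrand.fba_core import ViabilityChecker
from metnetrand.universe_io import ReactionUniverse, distinct_metabolite_count

logger = logging.getLogger(__name__)

LEVELS = ("R", "RM", "uRM", "uRM-V")
_LEVEL_RE = re.compile(r"^(R|RM|uRM|uRM-V(\d+))$")


class EnsembleError(ValueError):
    pass


@dataclass
class EnsembleSpec:
    """Constraint set defining one ensemble level."""

    level: str
    n_reactions: int
    pool: frozenset
    max_metabolites: int | None = None
    environments: list = field(default_factory=list)

    def __post_init__(self):
        m = _LEVEL_RE.match(self.level)
        if not m:
            raise EnsembleError(f"unknown level {self.level!r}")
        if self.n_reactions > len(self.pool):
            raise EnsembleError("n_reactions exceeds pool size")
        if self.level != "R" and self.max_metabolites is None:
            raise EnsembleError(f"{self.level} requires a metabolite cap")
        k = int(m.group(2)) if m.group(2) else 0
        if k and len(self.environments) != k:
            raise EnsembleError(f"{self.level} requires exactly {k} environments")
        if not k and self.environments:
            raise EnsembleError(f"{self.level} takes no environments")

    @property
    def k_environments(self) -> int:
        return len(self.environments)

    @classmethod
    def build(
        cls,
        level: str,
        universe: ReactionUniverse,
        n_reactions: int,
        max_metabolites: int | None = None,
        environments=(),
        unblocked=None,
    ) -> "EnsembleSpec":
        """Assemble the spec for a level; uRM levels need the unblocked id set."""
        if level.startswith("uRM"):
            if unblocked is None:
                raise EnsembleError(f"{level} needs the unblocked reaction pool")
            pool = frozenset(unblocked) & universe.metabolic_ids
        else:
            pool = universe.metabolic_ids
        envs = list(environments) if level.startswith("uRM-V") else []
        return cls(level, n_reactions, pool, None if level == "R" else max_metabolites, envs)


@dataclass
class ChainParams:
    burn_in: int = 100_000
    thin: int = 1_000
    n_save: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if min(self.burn_in, self.thin, self.n_save) < 1:
            raise EnsembleError("chain parameters must be positive")

    @property
    def total_steps(self) -> int:
        return self.burn_in + self.thin * self.n_save


@dataclass
class EnsembleSample:
    spec: EnsembleSpec
    genotypes: list
    acceptance_rate: float
    start: frozenset
    seed: int


def sample_R(universe: ReactionUniverse, n: int, count: int, seed=None) -> list:
    """``count`` independent uniform n-subsets of the metabolic reactions."""
    ids = sorted(universe.metabolic_ids)
    if n > len(ids):
        raise EnsembleError(f"n={n} exceeds the {len(ids)} metabolic reactions")
    rng = np.random.default_rng(seed)
    return [frozenset(ids[i] for i in rng.choice(len(ids), size=n, replace=False)) for _ in range(count)]


def propose_swap(genotype, pool, rng: random.Random):
    """One uniform member out, one uniform non-member in (symmetric proposal)."""
    if not genotype:
        raise EnsembleError("cannot swap on an empty genotype")
    members = sorted(genotype)
    outside = sorted(set(pool) - set(genotype))
    if not outside:
        raise EnsembleError("genotype equals the pool: no swap possible")
    out = members[rng.randrange(len(members))]
    new = outside[rng.randrange(len(outside))]
    return frozenset(g for g in genotype if g != out) | {new}


def satisfies(
    genotype,
    spec: EnsembleSpec,
    universe: ReactionUniverse,
    checker: ViabilityChecker | None = None,
) -> bool:
    """Constraint predicate, checked cheap-to-expensive with short-circuiting."""
    genotype = frozenset(genotype)
    if len(genotype) != spec.n_reactions:
        return False
    if not genotype <= spec.pool:
        return False
    if spec.max_metabolites is not None:
        if distinct_metabolite_count(genotype, universe) > spec.max_metabolites:
            return False
    if spec.environments:
        if checker is None:
            checker = ViabilityChecker(universe, spec.environments, pool=spec.pool)
        if not checker.viable_on_all(genotype):
            return False
    return True


def run_mcmc(
    spec: EnsembleSpec,
    start,
    params: ChainParams,
    universe: ReactionUniverse,
    checker: ViabilityChecker | None = None,
) -> EnsembleSample:
    """Reaction-swap Metropolis chain; saves every ``thin``-th genotype.

    The chain must start inside the ensemble.  Constraint bookkeeping is
    incremental (a running per-metabolite usage counter gives the
    distinct-metabolite count in O(reaction size) per trial); viability
    results are cached per (genotype, environment) so rejected moves that
    revisit a state cost no LP.
    """
    start = frozenset(start)
    if spec.environments and checker is None:
        checker = ViabilityChecker(universe, spec.environments, pool=spec.pool)
    if not satisfies(start, spec, universe, checker):
        raise EnsembleError("start genotype violates the ensemble constraints")
    pool = sorted(spec.pool)
    if len(pool) == len(start):
        raise EnsembleError("pool exhausted: genotype equals the pool")
    idx_of = {rid: i for i, rid in enumerate(pool)}

    # per-reaction metabolite index tuples (metabolic reactions only)
    met_index: dict = {}
    rxn_mets = []
    for rid in pool:
        row = []
        for m in universe.reactions[rid].stoich:
            if m not in met_index:
                met_index[m] = len(met_index)
            row.append(met_index[m])
        rxn_mets.append(tuple(row))

    members = [idx_of[rid] for rid in sorted(start)]
    member_set = set(members)
    outside = [i for i in range(len(pool)) if i not in member_set]
    counts = [0] * len(met_index)
    m_distinct = 0
    for i in members:
        for m in rxn_mets[i]:
            if counts[m] == 0:
                m_distinct += 1
            counts[m] += 1

    rng = random.Random(params.seed)
    cap = spec.max_metabolites if spec.max_metabolites is not None else len(met_index) + 1
    check_viability = bool(spec.environments)
    n_members, n_outside = len(members), len(outside)

    saved: list = []
    accepted = attempted = 0
    log_every = 10_000
    for step in range(params.total_steps):
        sampling = step >= params.burn_in
        if sampling:
            attempted += 1
        i_pos = rng.randrange(n_members)
        j_pos = rng.randrange(n_outside)
        r_out, r_in = members[i_pos], outside[j_pos]

        ok = True
        delta = 0
        for m in rxn_mets[r_out]:
            counts[m] -= 1
            if counts[m] == 0:
                delta -= 1
        for m in rxn_mets[r_in]:
            if counts[m] == 0:
                delta += 1
            counts[m] += 1
        if m_distinct + delta > cap:
            ok = False
        if ok and check_viability:
            member_set.discard(r_out)
            member_set.add(r_in)
            candidate = frozenset(pool[i] for i in member_set)
            ok = checker.viable_on_all(candidate)
            if not ok:
                member_set.discard(r_in)
                member_set.add(r_out)
        if ok:
            m_distinct += delta
            members[i_pos], outside[j_pos] = r_in, r_out
            if not check_viability:
                member_set.discard(r_out)
                member_set.add(r_in)
            if sampling:
                accepted += 1
        else:  # revert the counter updates
            for m in rxn_mets[r_in]:
                counts[m] -= 1
            for m in rxn_mets[r_out]:
                counts[m] += 1
        if sampling and (step - params.burn_in + 1) % params.thin == 0:
            saved.append(frozenset(pool[i] for i in member_set))
        if (step + 1) % log_every == 0:
            logger.debug(
                "MCMC step %d/%d acceptance so far %.3f",
                step + 1, params.total_steps, accepted / max(1, attempted),
            )

    return EnsembleSample(
        spec=spec,
        genotypes=saved[: params.n_save],
        acceptance_rate=accepted / max(1, attempted),
        start=start,
        seed=params.seed,
    )


def diversity_summary(sample: EnsembleSample | list) -> dict:
    """Mean pairwise dissimilarity, per-reaction usage, and the core set.

    The mean runs over ordered pairs of distinct saved genotypes; the
    core set contains the reactions present in every saved genotype.
    """
    genotypes = sample.genotypes if isinstance(sample, EnsembleSample) else list(sample)
    if len(genotypes) < 2:
        raise EnsembleError("diversity needs at least two genotypes")
    ids = sorted(set().union(*genotypes))
    idx = {r: j for j, r in enumerate(ids)}
    M = np.zeros((len(genotypes), len(ids)), dtype=bool)
    for i, g in enumerate(genotypes):
        M[i, [idx[r] for r in g]] = True
    sizes = M.sum(axis=1)
    inter = (M.astype(np.int32) @ M.T.astype(np.int32)).astype(float)
    # d(g1, g2) = |g2 - g1| / |g2| over ordered pairs (g1, g2), g1 != g2
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / sizes[None, :]
    n = len(genotypes)
    mean_d = float((d.sum() - np.trace(d)) / (n * (n - 1)))
    usage = M.mean(axis=0)
    core = frozenset(ids[j] for j in range(len(ids)) if usage[j] == 1.0)
    return {
        "mean_dissimilarity": mean_d,
        "core_set": core,
        "usage": dict(zip(ids, usage.tolist())),
    }


def write_sample(sample: EnsembleSample, path) -> None:
    """JSON-lines output: a metadata header, then one sorted genotype per line."""
    header = {
        "level": sample.spec.level,
        "n_reactions": sample.spec.n_reactions,
        "max_metabolites": sample.spec.max_metabolites,
        "environments": [e.name for e in sample.spec.environments],
        "seed": sample.seed,
        "acceptance_rate": sample.acceptance_rate,
        "n_genotypes": len(sample.genotypes),
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for g in sample.genotypes:
            fh.write(json.dumps(sorted(g)) + "\n")


def read_sample(path) -> tuple:
    """Returns (header dict, list of genotypes) from a JSON-lines sample file."""
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        genotypes = [frozenset(json.loads(line)) for line in fh if line.strip()]
    return header, genotypes
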
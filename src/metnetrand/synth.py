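"""Synthetic reaction universes with planted, provable ground truth.

The generator emulates the statistical anatomy of curated genome-scale
reaction databases so that every downstream stage (blocked-reaction
detection, essentiality, MCMC ensembles, graph statistics, degree-tail
fits) can be validated without external data:

* **currency couples** (ATP/ADP-like carrier pairs) attach to most
  reactions, one couple usually and occasionally two, which concentrates
  degree on a few carrier species and produces the fat-tailed metabolite
  degree distribution seen in real databases;
* **bulk reactions** draw their 1-3 non-currency substrates by a
  rich-get-richer (Simon/preferential-attachment) process over a growing
  metabolite pool, giving the non-carrier part of the degree tail;
* a **backbone pathway** runs from each environment's carbon source
  through a linear chain to the biomass precursors, guaranteeing a
  viable seed genotype; selected chain steps get parallel two-step
  bypasses, so exactly the un-bypassed steps are essential;
* **dead-end reactions** touch a fresh metabolite used nowhere else and
  are therefore blocked by mass balance alone, independent of any LP.

Currency metabolites, carbon sources, inorganic nutrients and all bulk
metabolites are external (exchangeable); backbone intermediates,
precursors and dead-end metabolites are internal.  This makes the
planted blocked and essential sets provably exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from metnetrand.universe_io import (
    CurrencyList,
    Environment,
    Reaction,
    ReactionUniverse,
    UniverseError,
    write_currency,
    write_environment,
    write_genotype,
    write_universe,
)
from metnetrand.netgraph import universe_metabolite_degrees

ONE = Fraction(1)

#: Non-currency substrate count distribution of bulk reactions (mean ~2,
#: at most 3, as in curated databases where reactions rarely move more
#: than three non-carrier species).
SUBSTRATE_COUNT_PROBS = {1: 0.15, 2: 0.60, 3: 0.25}


@dataclass
class SyntheticUniverseSpec:
    """Parameters of a generated universe (defaults sized for fast tests)."""

    n_currency_pairs: int = 6
    n_core_metabolites: int = 120
    n_reactions: int = 300          # metabolic reactions, planted pathway included
    p_currency_pair: float = 0.8    # first carrier couple attachment probability
    p_second_pair: float = 0.2      # second couple, conditional on the first
    reuse_exponent: float = 1.0     # preferential-attachment strength
    n_deadend_reactions: int = 25
    n_parallel_routes: int = 2      # chain steps that get a bypass
    n_environments: int = 3
    backbone_length: int = 8        # internal chain metabolites
    n_precursors: int = 3           # biomass components
    p_reversible: float = 0.4       # bulk reactions; curated sets are ~40% reversible
    seed_bulk_fraction: float = 0.4  # share of bulk reactions in the seed genotype
    seed: int = 0

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SyntheticUniverseSpec":
        """A database-sized preset: ~5900 reactions, roughly half dead ends,
        10 minimal environments, degree-tail exponent in the low 2s."""
        return cls(
            n_currency_pairs=6,
            n_core_metabolites=2200,
            n_reactions=5870,
            n_deadend_reactions=2900,
            n_parallel_routes=3,
            n_environments=10,
            backbone_length=12,
            n_precursors=5,
            seed=seed,
        )

    def n_planted(self) -> int:
        return (
            self.n_environments                  # entry reactions
            + (self.backbone_length - 1)         # chain steps
            + 2 * self.n_parallel_routes         # bypass pairs
            + self.n_precursors                  # precursor steps
            + self.n_deadend_reactions
        )

    def validate(self) -> None:
        if min(self.n_currency_pairs, self.n_core_metabolites, self.n_reactions,
               self.n_environments, self.n_precursors) < 1 or self.backbone_length < 2:
            raise UniverseError("all synthetic-spec counts must be positive")
        if not (0 <= self.p_currency_pair <= 1 and 0 <= self.p_second_pair <= 1):
            raise UniverseError("couple probabilities must be in [0, 1]")
        if self.n_parallel_routes > self.backbone_length - 1:
            raise UniverseError("more parallel routes than chain steps")
        if self.n_planted() >= self.n_reactions:
            raise UniverseError(
                f"spec inconsistent: {self.n_planted()} planted reactions leave no room "
                f"for bulk reactions within n_reactions={self.n_reactions}"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for exact validation of the pipeline."""

    planted_blocked: frozenset
    planted_essential: frozenset
    seed_genotype: frozenset
    environments: list = field(default_factory=list)


def _attach_currency(stoich: dict, rng, spec: SyntheticUniverseSpec) -> None:
    """Attach 0-2 carrier couples; each couple adds one reactant and one product."""
    if rng.random() >= spec.p_currency_pair:
        return
    first = int(rng.integers(spec.n_currency_pairs))
    couples = [first]
    if rng.random() < spec.p_second_pair and spec.n_currency_pairs > 1:
        second = int(rng.integers(spec.n_currency_pairs - 1))
        couples.append(second if second < first else second + 1)
    for i in couples:
        a, b = f"cur{i}a", f"cur{i}b"
        if rng.random() < 0.5:
            a, b = b, a
        stoich[a] = stoich.get(a, 0) - ONE
        stoich[b] = stoich.get(b, 0) + ONE


class _SimonPool:
    """Growing metabolite pool with preferential reuse prob ~ degree^alpha."""

    def __init__(self, n_target: int, n_slots_expected: float, alpha: float, rng):
        self.n_target = n_target
        self.alpha = alpha
        self.rng = rng
        self.ids: list = []
        self.deg: list = []
        self.slots_left = max(1.0, n_slots_expected)

    def draw(self, exclude: set) -> str:
        p_new = (self.n_target - len(self.ids)) / max(1.0, self.slots_left)
        self.slots_left -= 1
        make_new = (not self.ids) or (len(self.ids) < self.n_target and self.rng.random() < p_new)
        if not make_new:
            w = np.asarray(self.deg, dtype=float) ** self.alpha
            for mid in exclude:
                if mid.startswith("met") and mid[3:].isdigit():
                    w[int(mid[3:])] = 0.0
            tot = w.sum()
            if tot > 0:
                j = int(self.rng.choice(len(w), p=w / tot))
                self.deg[j] += 1
                return self.ids[j]
            make_new = True  # pool exhausted by exclusions
        mid = f"met{len(self.ids)}"
        self.ids.append(mid)
        self.deg.append(1)
        return mid


def generate_universe(spec: SyntheticUniverseSpec):
    """Build (universe, currency_list, ground_truth) deterministically from spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    currency_ids = [f"cur{i}{s}" for i in range(spec.n_currency_pairs) for s in "ab"]
    carbon_ids = [f"carbon{j}" for j in range(spec.n_environments)]
    inorganic_ids = ["inorg0", "inorg1"]
    L, P = spec.backbone_length, spec.n_precursors

    reactions: list = []
    essential: set = set()

    # --- bulk reactions over the external core pool -------------------------
    n_bulk = spec.n_reactions - spec.n_planted()
    mean_s = sum(k * v for k, v in SUBSTRATE_COUNT_PROBS.items())
    pool = _SimonPool(spec.n_core_metabolites, n_bulk * mean_s, spec.reuse_exponent, rng)
    s_values = np.array(list(SUBSTRATE_COUNT_PROBS), dtype=int)
    s_probs = np.array(list(SUBSTRATE_COUNT_PROBS.values()))
    bulk_ids = []
    for b in range(n_bulk):
        stoich: dict = {}
        _attach_currency(stoich, rng, spec)
        has_couple = bool(stoich)
        s = int(rng.choice(s_values, p=s_probs))
        if not has_couple and s < 2:
            s = 2  # need a reactant and a product without carrier help
        chosen: list = []
        for _ in range(s):
            chosen.append(pool.draw(exclude=set(chosen)))
        if len(set(chosen)) == 1 and not has_couple:
            chosen.append(pool.draw(exclude=set(chosen)))
            s += 1
        if has_couple and s == 1:
            side = -ONE if rng.random() < 0.5 else ONE
            stoich[chosen[0]] = stoich.get(chosen[0], 0) + side
        else:
            n_reac = int(rng.integers(1, s))
            for m in chosen[:n_reac]:
                stoich[m] = stoich.get(m, 0) - ONE
            for m in chosen[n_reac:]:
                stoich[m] = stoich.get(m, 0) + ONE
        stoich = {m: c for m, c in stoich.items() if c != 0}
        rid = f"bulk{b}"
        reactions.append(Reaction(rid, stoich, reversible=bool(rng.random() < spec.p_reversible)))
        bulk_ids.append(rid)

    # --- planted backbone pathway --------------------------------------------
    # The chain hands a *carrier* core metabolite from step to step: step i
    # consumes y_i and emits y_{i+1}, both drawn from the preferentially
    # reused pool (hence hubs).  Real biosynthetic routes are threaded
    # through hub metabolites the same way; the resulting arcs embed the
    # pathway in the core graph instead of leaving it a dangling linear
    # appendage.  Carrier balance holds at equal flux through the chain, so
    # viability and the essential set stay provable: the bb spine is still
    # the unique route to the precursors.
    carriers = []
    for _ in range(L):
        carriers.append(pool.draw(exclude=set(carriers[-1:])))

    for j in range(spec.n_environments):
        rid = f"entry{j}"
        stoich = {carbon_ids[j]: -ONE, "bb0": ONE, carriers[0]: ONE}
        _attach_currency(stoich, rng, spec)
        reactions.append(Reaction(rid, stoich, reversible=False))
        essential.add(rid)

    bypassed = set(rng.choice(L - 1, size=spec.n_parallel_routes, replace=False).tolist())
    for i in range(L - 1):
        rid = f"chain{i}"
        stoich = {f"bb{i}": -ONE, f"bb{i + 1}": ONE}
        stoich[carriers[i]] = stoich.get(carriers[i], 0) - ONE
        stoich[carriers[i + 1]] = stoich.get(carriers[i + 1], 0) + ONE
        if i == 0:
            stoich["inorg0"] = -ONE  # first step fixes an inorganic nutrient
        stoich = {m: c for m, c in stoich.items() if c != 0}
        _attach_currency(stoich, rng, spec)
        reactions.append(Reaction(rid, stoich, reversible=False))
        if i in bypassed:
            s1 = {f"bb{i}": -ONE, carriers[i]: -ONE, f"alt{i}": ONE}
            s2 = {f"alt{i}": -ONE, f"bb{i + 1}": ONE, carriers[i + 1]: ONE}
            _attach_currency(s1, rng, spec)
            _attach_currency(s2, rng, spec)
            reactions.append(Reaction(f"bypass{i}a", s1, reversible=False))
            reactions.append(Reaction(f"bypass{i}b", s2, reversible=False))
        else:
            essential.add(rid)
    for p in range(P):
        rid = f"precstep{p}"
        stoich = {f"bb{L - 1}": -ONE, f"prec{p}": ONE}
        stoich[pool.draw(exclude=set(stoich))] = ONE  # secreted byproduct
        _attach_currency(stoich, rng, spec)
        reactions.append(Reaction(rid, stoich, reversible=False))
        essential.add(rid)

    # --- planted dead ends ---------------------------------------------------
    blocked: set = set()
    core_ids = list(pool.ids)
    for d in range(spec.n_deadend_reactions):
        src = core_ids[int(rng.integers(len(core_ids)))]
        dead = f"dead{d}"
        if rng.random() < 0.5:
            stoich = {src: -ONE, dead: ONE}    # produces an unconsumable species
        else:
            stoich = {dead: -ONE, src: ONE}    # consumes an unproducible species
        _attach_currency(stoich, rng, spec)
        rid = f"deadrxn{d}"
        reactions.append(Reaction(rid, stoich, reversible=False))
        blocked.add(rid)

    # --- scaffold: exchanges for all externals, biomass ----------------------
    external = currency_ids + carbon_ids + inorganic_ids + core_ids
    for m in external:
        reactions.append(Reaction(f"EX_{m}", {m: -ONE}, reversible=True, category="exchange"))
    biomass = Reaction("BIOMASS", {f"prec{p}": -ONE for p in range(P)}, reversible=False, category="biomass")
    reactions.append(biomass)

    universe = ReactionUniverse(reactions)
    currency = CurrencyList(currency_ids)
    environments = [
        Environment(
            carbon_source=carbon_ids[j],
            inorganics=frozenset(inorganic_ids) | frozenset(currency_ids),
            name=f"minimal-{carbon_ids[j]}",
        )
        for j in range(spec.n_environments)
    ]

    pathway = frozenset(r.id for r in reactions if r.category == "metabolic" and not r.id.startswith(("bulk", "deadrxn")))
    n_seed_bulk = int(round(spec.seed_bulk_fraction * len(bulk_ids)))
    seed_bulk = rng.choice(len(bulk_ids), size=n_seed_bulk, replace=False) if n_seed_bulk else []
    seed_genotype = pathway | frozenset(bulk_ids[i] for i in np.sort(seed_bulk))

    truth = GroundTruth(
        planted_blocked=frozenset(blocked),
        planted_essential=frozenset(essential),
        seed_genotype=seed_genotype,
        environments=environments,
    )
    return universe, currency, truth


def modified_currency_list(currency: CurrencyList, universe: ReactionUniverse, drop_n: int) -> CurrencyList:
    """Robustness variant of the currency list: drop the drop_n lowest-degree entries.

    Currency metabolites are ranked by their degree in the complete
    reaction database, ascending (rank 1 = lowest degree, ties broken by
    id for determinism); the drop_n smallest ranks are removed.
    """
    if drop_n >= len(currency):
        raise UniverseError(f"cannot drop {drop_n} of {len(currency)} currency metabolites")
    deg = universe_metabolite_degrees(universe, metabolic_only=True)
    ranked = sorted(currency, key=lambda m: (deg.get(m, 0), m))
    dropped = set(ranked[:drop_n])
    return CurrencyList([m for m in currency if m not in dropped])


def write_synth_bundle(spec: SyntheticUniverseSpec, out_dir) -> dict:
    """Generate and write reaction table, currency list, environments,
    seed genotype and ground-truth JSON into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe, currency, truth = generate_universe(spec)
    paths = {
        "universe": out / "reactions.tsv",
        "currency": out / "currency.txt",
        "seed_genotype": out / "seed_genotype.txt",
        "ground_truth": out / "ground_truth.json",
    }
    write_universe(universe, paths["universe"])
    write_currency(currency, paths["currency"])
    write_genotype(truth.seed_genotype, paths["seed_genotype"])
    env_paths = []
    for i, env in enumerate(truth.environments):
        p = out / f"environment_{i}.yaml"
        write_environment(env, p)
        env_paths.append(p)
    paths["environments"] = env_paths
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted_blocked": sorted(truth.planted_blocked),
                "planted_essential": sorted(truth.planted_essential),
                "seed_genotype": sorted(truth.seed_genotype),
                "seed": spec.seed,
            },
            fh,
            indent=1,
        )
    return paths
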
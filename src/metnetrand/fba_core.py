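"""Flux balance analysis: viability, flux variability, blocked and necessary reactions.

Everything reduces to linear programs over steady-state fluxes v with
S v = 0 and per-reaction bounds; the objective is the biomass flux Z.
A genotype is *viable* in an environment when Z_max exceeds a small
threshold; a reaction is *blocked* when its flux is forced to zero even
with every exchange open in both directions (the most permissive
polytope, so zero there implies zero under every environment); a
reaction is *necessary* when deleting it from the unblocked universe
abolishes growth in at least one environment.

LPs are solved with scipy's HiGHS backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from metnetrand.universe_io import Environment, ReactionUniverse

logger = logging.getLogger(__name__)

#: Generic flux cap (flux units); only the sign of Z_max matters for viability.
V_MAX = 1000.0
#: Z_max above this counts as growth (absorbs LP round-off).
VIABILITY_EPS = 1e-6
#: |flux| below this counts as zero in blocked-reaction detection.
ZERO_TOL = 1e-9


class FBAError(RuntimeError):
    pass


@dataclass
class FluxRange:
    reaction_id: str
    vmin: float
    vmax: float


@dataclass
class StoichiometricSystem:
    """S matrix plus bounds and the biomass column index."""

    reaction_ids: list
    metabolite_ids: list
    S: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective_index: int

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index_of(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise FBAError(f"reaction {rid} not in system") from None


def build_system(
    reactions,
    environment: Environment | None = None,
    open_all_exchanges: bool = False,
    v_max: float = V_MAX,
) -> StoichiometricSystem:
    """Assemble the steady-state LP for a reaction set (scaffold included).

    Bounds: irreversible [0, V], reversible [-V, V].  Exchange reactions
    (coefficient -1 on their single metabolite, positive flux = secretion)
    allow uptake only for medium members: the carbon source down to
    -carbon_uptake_bound, inorganics down to -inorganic_uptake_bound.
    ``open_all_exchanges`` instead opens every exchange to [-V, V].
    """
    if (environment is None) == (not open_all_exchanges):
        raise FBAError("give an environment XOR open_all_exchanges")
    reactions = list(reactions)
    obj = [i for i, r in enumerate(reactions) if r.category == "biomass"]
    if len(obj) != 1:
        raise FBAError(f"system needs exactly one biomass reaction, found {len(obj)}")

    used = sorted({m for r in reactions for m in r.stoich})
    met_index = {m: i for i, m in enumerate(used)}
    rows, cols, vals = [], [], []
    lb = np.zeros(len(reactions))
    ub = np.full(len(reactions), v_max)
    for j, r in enumerate(reactions):
        for m, c in r.stoich.items():
            rows.append(met_index[m])
            cols.append(j)
            vals.append(float(c))
        if r.reversible:
            lb[j] = -v_max
        if r.category == "exchange":
            if open_all_exchanges:
                lb[j] = -v_max
            else:
                met = next(iter(r.stoich))
                if met == environment.carbon_source:
                    lb[j] = -environment.carbon_uptake_bound
                elif met in environment.inorganics:
                    lb[j] = -environment.inorganic_uptake_bound
                else:
                    lb[j] = 0.0  # secretion only
            ub[j] = v_max
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(used), len(reactions))
    )
    # metabolites in no reaction cannot occur here (index built from reactions)
    return StoichiometricSystem([r.id for r in reactions], used, S, lb, ub, obj[0])


def _solve(system: StoichiometricSystem, c: np.ndarray) -> np.ndarray:
    """min c.v s.t. Sv=0, bounds; returns the flux vector."""
    res = linprog(
        c,
        A_eq=system.S,
        b_eq=np.zeros(system.S.shape[0]),
        bounds=np.column_stack([system.lb, system.ub]),
        method="highs",
    )
    if not res.success:
        raise FBAError(f"LP failed: status={res.status} ({res.message})")
    return res.x


def max_biomass(system: StoichiometricSystem, return_fluxes: bool = False):
    """Maximum biomass flux Z_max (always >= 0: v = 0 is feasible)."""
    c = np.zeros(system.n_reactions)
    c[system.objective_index] = -1.0
    v = _solve(system, c)
    z = float(v[system.objective_index])
    return (z, v) if return_fluxes else z


def is_viable(genotype, universe: ReactionUniverse, environment: Environment, eps: float = VIABILITY_EPS) -> bool:
    """FBA-predicted growth: Z_max > eps for genotype + scaffold in the environment."""
    universe.validate_genotype(genotype)
    if not genotype:
        return False
    rxns = [universe.reactions[rid] for rid in genotype] + universe.scaffold
    return max_biomass(build_system(rxns, environment=environment)) > eps


def flux_range(system: StoichiometricSystem, reaction_id: str) -> FluxRange:
    """FVA range of one reaction: two LPs (min and max of its flux)."""
    j = system.index_of(reaction_id)
    c = np.zeros(system.n_reactions)
    c[j] = 1.0
    vmin = float(_solve(system, c)[j])
    vmax = float(_solve(system, -c)[j])
    return FluxRange(reaction_id, vmin, vmax)


def find_blocked(universe: ReactionUniverse, zero_tol: float = ZERO_TOL, rng=None) -> frozenset:
    """Metabolic reactions that can carry no steady-state flux in any environment.

    Computed with every exchange open in both directions; a reaction with
    zero feasible flux in that polytope has zero flux in every
    sub-polytope, hence under all environments.  Only the swappable
    (metabolic) reactions are assessed -- the scaffold is fixed and never
    enters a genotype.  Accelerated by first maximizing a random positive
    combination of fluxes and, during the FVA sweep, marking every
    flux-carrying reaction of each LP solution as unblocked; the result
    is identical to plain per-reaction FVA.
    """
    rng = np.random.default_rng(rng)
    system = build_system(universe.reactions.values(), open_all_exchanges=True)
    n = system.n_reactions
    metabolic = universe.metabolic_ids
    assess = [j for j in range(n) if system.reaction_ids[j] in metabolic]
    unblocked = np.zeros(n, dtype=bool)

    # warm-up LP: random positive weights; any nonzero flux proves unblocked
    w = rng.uniform(0.5, 1.5, size=n)
    v = _solve(system, -w)
    unblocked |= np.abs(v) > zero_tol

    n_lp = 1
    for j in sorted(assess, key=lambda i: system.reaction_ids[i]):  # order-independent result
        if unblocked[j]:
            continue
        c = np.zeros(n)
        c[j] = -1.0
        v = _solve(system, c)
        n_lp += 1
        unblocked |= np.abs(v) > zero_tol
        if unblocked[j]:
            continue
        v = _solve(system, -c)
        n_lp += 1
        unblocked |= np.abs(v) > zero_tol
    blocked = frozenset(system.reaction_ids[j] for j in assess if not unblocked[j])
    logger.info("blocked detection: %d LPs, %d of %d metabolic blocked", n_lp, len(blocked), len(assess))
    return blocked


def find_necessary(universe: ReactionUniverse, environments, eps: float = VIABILITY_EPS) -> frozenset:
    """Metabolic reactions whose single deletion abolishes growth in >= 1 environment.

    Intended to be run on the unblocked universe.  Deletion tests are
    skipped (provably non-essential) for reactions carrying zero flux in
    a stored optimal solution of that environment, since that solution
    remains feasible after the deletion.
    """
    environments = list(environments)
    if not environments:
        raise FBAError("at least one environment required")
    rxns = list(universe.reactions.values())
    metabolic = [i for i, r in enumerate(rxns) if r.category == "metabolic"]
    necessary: set = set()
    n_lp = 0
    for env in environments:
        system = build_system(rxns, environment=env)
        z0, v0 = max_biomass(system, return_fluxes=True)
        n_lp += 1
        if z0 <= eps:
            raise FBAError(f"universe itself is not viable on {env.name}")
        for i in metabolic:
            rid = rxns[i].id
            if rid in necessary or abs(v0[i]) <= ZERO_TOL:
                continue
            lo, hi = system.lb[i], system.ub[i]
            system.lb[i] = system.ub[i] = 0.0
            z = max_biomass(system)
            n_lp += 1
            system.lb[i], system.ub[i] = lo, hi
            if z <= eps:
                necessary.add(rid)
    logger.info("necessary detection: %d LPs, %d necessary", n_lp, len(necessary))
    return frozenset(necessary)


class ViabilityChecker:
    """Fast repeated viability tests against a fixed pool of metabolic reactions.

    Builds one LP system per environment over the full pool + scaffold;
    testing a genotype closes the bounds of the non-member columns.
    Results are cached by (genotype, environment).
    """

    def __init__(self, universe: ReactionUniverse, environments, pool=None, eps: float = VIABILITY_EPS):
        self.eps = eps
        self.environments = list(environments)
        pool = frozenset(pool) if pool is not None else universe.metabolic_ids
        self.pool = pool
        rxns = [universe.reactions[rid] for rid in sorted(pool)] + universe.scaffold
        self._systems = [build_system(rxns, environment=env) for env in self.environments]
        self._col = {rid: j for j, rid in enumerate(self._systems[0].reaction_ids)}
        self._pool_cols = np.array([self._col[rid] for rid in sorted(pool)])
        self._base_lb = [s.lb.copy() for s in self._systems]
        self._base_ub = [s.ub.copy() for s in self._systems]
        self._cache: dict = {}
        self.n_lp = 0

    def is_viable(self, genotype, env_index: int) -> bool:
        key = (genotype, env_index)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        system = self._systems[env_index]
        lb, ub = self._base_lb[env_index].copy(), self._base_ub[env_index].copy()
        absent = [self._col[rid] for rid in self.pool if rid not in genotype]
        lb[absent] = 0.0
        ub[absent] = 0.0
        system.lb, system.ub = lb, ub
        z = max_biomass(system)
        self.n_lp += 1
        ok = z > self.eps
        self._cache[key] = ok
        return ok

    def viable_on_all(self, genotype) -> bool:
        return all(self.is_viable(genotype, k) for k in range(len(self.environments)))


def write_id_set(ids, path) -> None:
    """Emit a blocked/necessary set as one id per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid in sorted(ids):
            fh.write(f"{rid}\n")
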
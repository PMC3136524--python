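# Methods

## Model

A reaction universe is a set of N mass-action reactions with signed
rational stoichiometry, split into *metabolic* (swappable, gene-encoded)
reactions and a fixed *scaffold*: one exchange reaction per external
metabolite (coefficient −1; positive flux secretes, negative flux takes
up) and a single biomass reaction acting as the growth objective. A
genotype is a size-n subset of the metabolic reactions; the scaffold is
always present.

### Flux balance analysis

Growth capability is the linear program

    max Z = v_biomass   s.t.   S v = 0,   lb ≤ v ≤ ub

solved with HiGHS. Bounds: irreversible reactions [0, V], reversible
[−V, V] with V = 1000 flux units; exchanges allow uptake only for medium
members (carbon source −10, inorganic nutrients −1000 by default) and
secretion for every external metabolite. Only the sign of Z matters for
viability, so bound magnitudes are conventions, not fitted parameters.
A genotype is viable when Z > ε with ε = 1e−6 (absorbs LP round-off);
flux-variability "zero" means |v| ≤ 1e−9. v = 0 is always feasible,
so the LP can never be infeasible and Z ≥ 0.

*Blocked* reactions are found with every exchange open in both
directions: zero feasible flux in that most permissive polytope implies
zero flux in every environment, since each environment's feasible set is
a subset. Only metabolic reactions are assessed — the scaffold never
enters a genotype. The sweep is accelerated exactly: one LP maximizing a
random positive combination of fluxes first, then per-reaction FVA on
the remainder, marking every flux-carrying reaction of each LP solution
unblocked along the way. The result is provably identical to plain FVA.

*Necessary* reactions are single deletions from the unblocked universe
that abolish growth (Z ≤ ε) in at least one environment. The search
stores one optimal flux vector per environment and skips deletions of
reactions carrying zero flux in it — that solution remains feasible
after the deletion, so the reaction is provably non-essential there.

### Ensembles and MCMC

The ensembles R ⊃ RM ⊃ uRM ⊃ uRM-V1 ⊃ … ⊃ uRM-V10 are nested sets of
genotypes; each is sampled *uniformly*. R is direct sampling of
n-subsets. The rest use reaction-swap MCMC: remove one uniformly chosen
member, add one uniformly chosen non-member, accept iff every constraint
of the level holds. The proposal is symmetric (P(G→G′) = P(G′→G) =
1/(n·|pool∖G|), constant for fixed n and pool), so accept-iff-valid is
Metropolis for the uniform target; detailed balance holds by
construction. Defaults mirror standard practice for this chain: 10^5
attempted swaps of burn-in, then 10^6 more saving every 1000th genotype
(1000 saved). Rejected trials advance the step counter, and the
acceptance rate is reported over the sampling phase only. The metabolite
constraint is m ≤ m_cap (a range, not equality; the m = m_cap subsample
can be taken post hoc). The chain must start inside the ensemble
(reference genotype against real data, the generator's seed genotype for
synthetic runs); a start outside is an error, never silently repaired.

Ergodicity of the swap chain under viability constraints is assumed, not
proven; the uniformity tests on exhaustively enumerable spaces (both a
metabolite-cap and a viability constraint) support it empirically, and
multi-seed runs are the recommended diagnostic at scale. Chi-square
uniformity checks use visit counts thinned to every 100th step: raw
per-step counts are serially correlated, which inflates the chi-square
statistic regardless of whether the stationary distribution is uniform.

Implementation notes: the distinct-metabolite count is maintained
incrementally (a per-metabolite usage counter, O(reaction size) per
trial); viability results are cached per (genotype, environment) so
rejected moves revisiting a state cost no LP; each chain owns one named
`random.Random(seed)` stream and identical seeds reproduce the saved
genotype sequence exactly.

### Graph statistics

The metabolite graph removes the currency metabolites globally (a single
list, even though some carriers occasionally act as primary substrates)
and draws an arc from every non-currency reactant to every non-currency
product of each reaction, both directions for reversible reactions.
Self-loops are dropped, parallel arcs collapse, and isolated non-currency
metabolites remain nodes — the construction defines nodes by reaction
participation, so dangling metabolites legitimately dilute P_C and the
bow-tie fractions.

Clustering uses the transitivity convention C = 3NΔ/N₃ on the undirected
simplification; the factor-3-free variant is exposed because texts
differ on the normalization. L and P_C run over *ordered* pairs of
distinct nodes (the graph is directed): P_C is the reachable fraction, L
the mean shortest path length over reachable pairs (undefined, reported
as NaN, when no pair is reachable). The bow-tie takes the largest
strongly connected component (ties broken toward the lexicographically
smallest sorted member list, logged), IN = nodes reaching it, OUT =
nodes reached from it.

### Power-law fitting

Degree tails are fitted by exact discrete maximum likelihood,
γ̂ = argmax [−γ Σ ln k_i − n_tail ln ζ(γ, k_min)], ζ the Hurwitz zeta
(scipy), maximized on γ ∈ (1.01, 6) to 1e−6. k_min is either fixed or
chosen by scanning observed degrees ≥ 2 for the minimal KS distance
between empirical and fitted tail CDFs, ties toward smaller k_min (the
larger tail). With fewer than 10 tail points the fit refuses rather than
returning noise. Binned displays use multiplicative bins (ratio 2) with
width-normalized densities; binning is display-only and never feeds the
estimator.

## The synthetic-data generator

`synth.generate_universe` emulates the statistical anatomy of curated
reaction databases so every stage has provable ground truth:

* **Currency couples** (ATP/ADP-like pairs, 6 by default) attach to a
  reaction with probability 0.8 and, given one couple, a second with
  probability 0.2; each couple contributes one reactant and one product.
  The non-currency substrate count is 1–3 with probabilities
  {0.15, 0.60, 0.25} (mean ~2). This puts the reaction-degree mode at 4,
  rarely above 6, and at most 3 non-carrier species per reaction —
  matching curated databases.
* **Bulk reactions** draw non-currency metabolites from a growing pool by
  a Simon/preferential-attachment process (reuse weight degree^α, α = 1;
  new-metabolite probability adapted so the pool reaches its target
  size). Together with the carrier couples this yields a fat-tailed
  metabolite degree distribution; at database scale (≥5000 reactions,
  pool sized at ~0.35 of the substrate slots) the MLE exponent lands in
  the low-to-mid 2s, the empirically observed regime.
* **The backbone pathway** runs from each environment's carbon source
  through a linear chain of internal intermediates to the biomass
  precursors, so the seed genotype is viable by construction. Selected
  chain steps get two-step parallel bypasses; exactly the un-bypassed
  steps, the per-environment entry reactions and the precursor steps are
  essential, and nothing else can be (bulk reactions never touch
  backbone metabolites). Chain steps hand a *carrier* core metabolite
  from step to step (consumed by the next step, balanced at equal chain
  flux) — real biosynthesis is threaded through hub metabolites the same
  way, and these arcs embed the pathway in the core graph rather than
  leaving it a dangling appendage.
* **Dead-end reactions** touch a fresh metabolite used nowhere else and
  are blocked by mass balance alone — ground truth that needs no LP.
* Currency metabolites, carbon sources, inorganics and all bulk
  metabolites are external; currency and inorganics are medium members
  of every environment (their real analogues — water, protons,
  phosphate, ammonia — are freely exchanged in minimal media).

What the generator does **not** emulate: element/charge balance, real
stoichiometric coefficients beyond ±1 on most species, compartments,
gene–protein–reaction structure, and the correlated pathway mosaic of
real databases. Passing tests therefore demonstrate the correctness of
the algorithms (exact blocked/essential recovery, sampler uniformity,
statistic definitions), not biological conclusions about any organism.

Default sizes: 300 reactions (tests run in seconds per LP batch); the
`paper_scale()` preset builds ~5900 reactions with roughly half planted
as dead ends and 10 minimal environments.

## Design choices and numerical conventions

* Metabolite counting for the m-constraint covers the genotype's
  metabolic reactions only; scaffold pseudo-species are excluded.
* Stoichiometric coefficients are exact rationals (`Fraction`), rendered
  as decimals where exact (fallback `p/q`), so universe round-trips are
  lossless.
* Currency ids absent from a universe are warned about and dropped, not
  fatal — currency lists are shared across universes.
* Population SD (n denominator) in ensemble summaries; z =
  (reference − mean)/SD, reported missing when SD = 0.
* Per-genotype statistics are independent; results are identical however
  they are scheduled.
* Problem sizes in the test and acceptance runs: 20 universes of 200–500
  reactions for blocked recovery, 5 for essentiality, 10^6-step chains on
  10-reaction toys for uniformity, and 100 saved genotypes per level
  (burn-in 2000, thinning 50) for the hierarchy trend — sizes chosen so
  a full verification cycle stays in the minutes range on one CPU while
  every check remains exact or statistically powered.

## Known limitations

* Blocked detection assumes the "all exchanges open" polytope dominates
  every environment, which holds for bound-interval environments like
  the ones modeled, but would not cover constraints that *force* flux.
* The KS-scan k_min is data-driven; exponents fitted to small genotypes
  (few hundred metabolites) carry substantial variance, and `gamma` is
  NaN when fewer than 10 tail points exist.
* MCMC mixing time is not estimated; burn-in and thinning are
  conventions. For heavily constrained ensembles on large universes,
  run several seeds and compare.
* No SBML import; the TSV reaction table is the only universe format.
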
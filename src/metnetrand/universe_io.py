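"""Data model and I/O for reaction universes, genotypes and environments.

A *reaction universe* is the global pool of biochemically valid reactions
from which genotypes (reaction subsets) are drawn.  Reactions are either
*metabolic* (swappable, gene-encoded) or part of the fixed *scaffold*:
transport and exchange reactions moving metabolites across the cell
boundary, plus a single biomass reaction acting as the growth objective.

File formats are plain text: a TSV reaction table (``id  equation
reversible  category``), one-id-per-line currency and genotype lists, and
YAML/JSON environment files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

CATEGORIES = ("metabolic", "transport", "exchange", "biomass")

#: A genotype is simply a set of metabolic reaction ids; the binary-string
#: view (b_i = 1 iff reaction i is a member) is implicit in membership.
Genotype = frozenset


class UniverseError(ValueError):
    """Raised for malformed reaction tables, equations or genotypes."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str | None = None
    is_external: bool = False

    def __post_init__(self):
        if not self.id or re.search(r"\s", self.id):
            raise UniverseError(f"bad metabolite id {self.id!r}")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.

    ``stoich`` maps metabolite id to a signed rational coefficient:
    negative for reactants, positive for products.
    """

    id: str
    stoich: Mapping[str, Fraction]
    reversible: bool
    category: str = "metabolic"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise UniverseError(f"{self.id}: unknown category {self.category!r}")
        if not self.stoich or any(c == 0 for c in self.stoich.values()):
            raise UniverseError(f"{self.id}: zero or empty stoichiometry")
        if self.category == "exchange" and len(self.stoich) != 1:
            raise UniverseError(f"{self.id}: exchange must touch exactly one metabolite")
        if self.category in ("metabolic", "biomass"):
            has_reac = any(c < 0 for c in self.stoich.values())
            has_prod = any(c > 0 for c in self.stoich.values())
            if self.category == "metabolic" and not (has_reac and has_prod):
                raise UniverseError(f"{self.id}: metabolic reaction needs a reactant and a product")

    @property
    def reactants(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]

    @property
    def metabolite_ids(self) -> frozenset:
        return frozenset(self.stoich)


@dataclass
class Environment:
    """A minimal growth medium: one carbon source plus inorganic nutrients.

    Uptake (negative exchange flux) is allowed only for medium members;
    every external metabolite may always be secreted.
    """

    carbon_source: str
    inorganics: frozenset = frozenset()
    carbon_uptake_bound: float = 10.0
    inorganic_uptake_bound: float = 1000.0
    name: str = ""

    def __post_init__(self):
        self.inorganics = frozenset(self.inorganics)
        if self.carbon_uptake_bound <= 0 or self.inorganic_uptake_bound <= 0:
            raise UniverseError("uptake bounds must be positive")
        if not self.name:
            self.name = f"minimal-{self.carbon_source}"


@dataclass
class CurrencyList:
    """Ordered list of currency-metabolite ids (ATP/ADP-like carriers)."""

    ids: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise UniverseError("duplicate ids in currency list")

    def __iter__(self):
        return iter(self.ids)

    def __len__(self):
        return len(self.ids)

    def __contains__(self, mid):
        return mid in set(self.ids)

    def resolve(self, universe: "ReactionUniverse") -> "CurrencyList":
        """Drop (with a warning) ids that do not exist in ``universe``."""
        known, dropped = [], []
        for mid in self.ids:
            (known if mid in universe.metabolites else dropped).append(mid)
        if dropped:
            logger.warning("currency ids not in universe, ignored: %s", ", ".join(dropped))
        return CurrencyList(known)


class ReactionUniverse:
    """The global set of candidate reactions plus the fixed scaffold."""

    def __init__(self, reactions: Iterable[Reaction], metabolite_names: Mapping[str, str] | None = None):
        self.reactions: dict = {}
        for r in reactions:
            if r.id in self.reactions:
                raise UniverseError(f"duplicate reaction id {r.id}")
            self.reactions[r.id] = r
        n_biomass = sum(1 for r in self.reactions.values() if r.category == "biomass")
        if n_biomass != 1:
            raise UniverseError(f"universe needs exactly one biomass reaction, found {n_biomass}")
        # externality: a metabolite is external iff an exchange reaction touches it
        external = {next(iter(r.stoich)) for r in self.reactions.values() if r.category == "exchange"}
        names = metabolite_names or {}
        self.metabolites: dict = {}
        for r in self.reactions.values():
            for mid in r.stoich:
                if mid not in self.metabolites:
                    self.metabolites[mid] = Metabolite(mid, names.get(mid), mid in external)

    @property
    def metabolic_ids(self) -> frozenset:
        return frozenset(rid for rid, r in self.reactions.items() if r.category == "metabolic")

    @property
    def N(self) -> int:
        """Number of swappable (metabolic) reactions."""
        return len(self.metabolic_ids)

    @property
    def scaffold(self) -> list:
        """Non-swappable transport/exchange/biomass reactions."""
        return [r for r in self.reactions.values() if r.category != "metabolic"]

    @property
    def biomass_reaction(self) -> Reaction:
        return next(r for r in self.reactions.values() if r.category == "biomass")

    @property
    def external_ids(self) -> frozenset:
        return frozenset(m.id for m in self.metabolites.values() if m.is_external)

    def __len__(self):
        return len(self.reactions)

    def validate_genotype(self, genotype) -> None:
        unknown = set(genotype) - self.metabolic_ids
        if unknown:
            raise UniverseError(f"genotype contains non-metabolic/unknown ids: {sorted(unknown)[:5]}")

    def restrict(self, keep_metabolic) -> "ReactionUniverse":
        """Universe with metabolic reactions limited to ``keep_metabolic``; scaffold kept."""
        keep = set(keep_metabolic)
        rxns = [r for r in self.reactions.values() if r.category != "metabolic" or r.id in keep]
        return ReactionUniverse(rxns, {m.id: m.name for m in self.metabolites.values() if m.name})


# ---------------------------------------------------------------------------
# equation parsing / rendering

_ARROWS = ("<=>", "->")
_COEF_RE = re.compile(r"^\d+(\.\d+)?$|^\d+/\d+$")


def _parse_side(side: str, sign: int, stoich: dict, text: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        tokens = term.split()
        if not tokens:
            raise UniverseError(f"malformed equation (empty term) in {text!r}")
        if len(tokens) == 2:
            coef_s, met = tokens
            if not _COEF_RE.match(coef_s):
                raise UniverseError(f"malformed coefficient {coef_s!r} in {text!r}")
            coef = Fraction(coef_s)
        elif len(tokens) == 1:
            met, coef = tokens[0], Fraction(1)
            if _COEF_RE.match(met):
                raise UniverseError(f"coefficient {met!r} without metabolite in {text!r}")
        else:
            raise UniverseError(f"malformed term {term.strip()!r} in {text!r}")
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coef


def parse_reaction_equation(text: str, rid: str = "R", category: str = "metabolic") -> Reaction:
    """Parse ``"glc-D + atp -> g6p + adp + h"`` into a :class:`Reaction`.

    ``->`` marks an irreversible and ``<=>`` a reversible reaction; an
    omitted coefficient means 1; a metabolite appearing on both sides nets
    its coefficients (net zero is an error).
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise UniverseError(f"no arrow in equation {text!r}")
    left, right = text.split(arrow, 1)
    stoich: dict = {}
    _parse_side(left, -1, stoich, text)
    _parse_side(right, +1, stoich, text)
    net_zero = [m for m, c in stoich.items() if c == 0]
    if net_zero:
        raise UniverseError(f"metabolite(s) {net_zero} net to zero in {text!r}")
    if category == "metabolic" and (not any(c < 0 for c in stoich.values()) or not any(c > 0 for c in stoich.values())):
        raise UniverseError(f"metabolic equation with an empty side: {text!r}")
    return Reaction(rid, stoich, reversible=(arrow == "<=>"), category=category)


def _coef_str(c: Fraction) -> str:
    if c.denominator == 1:
        return str(c.numerator)
    f = float(c)
    if Fraction(str(f)) == c:  # exact decimal
        return str(f)
    return f"{c.numerator}/{c.denominator}"


def render_equation(reaction: Reaction) -> str:
    """Inverse of :func:`parse_reaction_equation` (round-trip exact)."""

    def side(items):
        out = []
        for m, c in items:
            c = abs(c)
            out.append(m if c == 1 else f"{_coef_str(c)} {m}")
        return " + ".join(out)

    lhs = [(m, c) for m, c in reaction.stoich.items() if c < 0]
    rhs = [(m, c) for m, c in reaction.stoich.items() if c > 0]
    arrow = "<=>" if reaction.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# file I/O (TSV tables, id lists, YAML/JSON environments)


def load_universe(reaction_table_path, currency_path=None):
    """Load a reaction-table TSV (and optionally a currency list).

    Returns ``(universe, currency_list)``; ``currency_list`` is ``None``
    when no path is given.  The redundant reversible flag column must
    agree with the equation's arrow marker.
    """
    path = Path(reaction_table_path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:4] != ["id", "equation", "reversible", "category"]:
                    raise UniverseError(f"bad header in {path}: {header}")
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise UniverseError(f"no reactions in {path}")
    reactions = []
    for row in rows:
        if len(row) < 4:
            raise UniverseError(f"short row in {path}: {row}")
        rid, eqn, rev_flag, category = row[0], row[1], row[2], row[3]
        if rev_flag not in ("0", "1"):
            raise UniverseError(f"{rid}: reversible flag must be 0/1, got {rev_flag!r}")
        rxn = parse_reaction_equation(eqn, rid=rid, category=category)
        if rxn.reversible != (rev_flag == "1"):
            raise UniverseError(f"{rid}: reversible flag disagrees with equation marker")
        reactions.append(rxn)
    uni = ReactionUniverse(reactions)
    by_cat = {c: sum(1 for r in reactions if r.category == c) for c in CATEGORIES}
    logger.info(
        "loaded %d reactions (%s), %d reversible, %d metabolites",
        len(reactions),
        ", ".join(f"{v} {k}" for k, v in by_cat.items()),
        sum(r.reversible for r in reactions),
        len(uni.metabolites),
    )
    currency = None
    if currency_path is not None:
        currency = load_currency(currency_path).resolve(uni)
    return uni, currency


def write_universe(universe: ReactionUniverse, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tequation\treversible\tcategory\n")
        for r in universe.reactions.values():
            fh.write(f"{r.id}\t{render_equation(r)}\t{int(r.reversible)}\t{r.category}\n")


def load_currency(path) -> CurrencyList:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return CurrencyList(ids)


def write_currency(currency: CurrencyList, path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in currency), encoding="utf-8")


def load_genotype(path) -> Genotype:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return frozenset(ids)


def write_genotype(genotype, path) -> None:
    Path(path).write_text("".join(f"{r}\n" for r in sorted(genotype)), encoding="utf-8")


def load_environment(path) -> Environment:
    """Read an environment from YAML or JSON (keys: carbon_source, inorganics, bounds)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return Environment(
        carbon_source=data["carbon_source"],
        inorganics=frozenset(data.get("inorganics", [])),
        carbon_uptake_bound=float(data.get("carbon_uptake_bound", 10.0)),
        inorganic_uptake_bound=float(data.get("inorganic_uptake_bound", 1000.0)),
        name=data.get("name", ""),
    )


def write_environment(env: Environment, path) -> None:
    data = {
        "name": env.name,
        "carbon_source": env.carbon_source,
        "inorganics": sorted(env.inorganics),
        "carbon_uptake_bound": env.carbon_uptake_bound,
        "inorganic_uptake_bound": env.inorganic_uptake_bound,
    }
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith((".yml", ".yaml")):
            yaml.safe_dump(data, fh)
        else:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# genotype-level quantities


def distinct_metabolite_count(genotype, universe: ReactionUniverse) -> int:
    """Number of distinct metabolites touched by the genotype's metabolic reactions.

    Scaffold reactions (exchange/transport/biomass) are excluded: the
    metabolite count constrains the gene-encoded metabolism only.
    """
    universe.validate_genotype(genotype)
    mets: set = set()
    for rid in genotype:
        mets.update(universe.reactions[rid].stoich)
    return len(mets)


def dissimilarity(g1, g2) -> float:
    """Fraction of ``g2``'s reactions absent from ``g1``: ``|g2 - g1| / |g2|``."""
    if not g2:
        raise UniverseError("dissimilarity undefined for empty second genotype")
    g1 = set(g1)
    return sum(1 for r in g2 if r not in g1) / len(g2)
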
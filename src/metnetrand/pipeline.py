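"""End-to-end orchestration: blocked filtering -> sampling -> statistics -> comparison.

A run is described by a single YAML/JSON config (paths, levels, chain
parameters, seed).  For every requested ensemble level the pipeline
samples genotypes, computes per-genotype graph statistics, fits the
degree tail, and writes per-level summary rows (mean and population SD
per statistic) next to the reference genotype's own values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metnetrand import ensembles, fba_core, netgraph
from metnetrand.universe_io import (
    distinct_metabolite_count,
    load_environment,
    load_genotype,
    load_universe,
)

logger = logging.getLogger(__name__)

LEVEL_ORDER = ["R", "RM", "uRM", "uRM-V1", "uRM-V5", "uRM-V10"]
STATISTICS = ["C", "L", "P_C", "f_LSC", "f_bowtie", "gamma"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    universe_path: str
    currency_path: str
    reference_genotype_path: str
    environment_paths: list
    output_dir: str
    levels: list = field(default_factory=lambda: ["R", "RM"])
    burn_in: int = 100_000
    thin: int = 1_000
    n_save: int = 1_000
    seed: int = 0
    viability_eps: float = fba_core.VIABILITY_EPS
    zero_tol: float = fba_core.ZERO_TOL
    modified_currency_path: str | None = None

    def __post_init__(self):
        known = [lv for lv in self.levels if lv in LEVEL_ORDER]
        if known != self.levels:
            raise PipelineError(f"levels must be drawn from {LEVEL_ORDER}, got {self.levels}")
        order = [LEVEL_ORDER.index(lv) for lv in self.levels]
        if order != sorted(order) or order != list(range(len(order))):
            raise PipelineError("levels must be a prefix of the nesting order " + "->".join(LEVEL_ORDER))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls(**data)


def _env_count(level: str) -> int:
    return int(level.split("-V")[1]) if "-V" in level else 0


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested levels; returns {level: stats DataFrame} plus paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe, currency = load_universe(config.universe_path, config.currency_path)
    reference = load_genotype(config.reference_genotype_path)
    environments = [load_environment(p) for p in config.environment_paths]
    n_ref = len(reference)
    m_ref = distinct_metabolite_count(reference, universe)
    logger.info("reference genotype: %d reactions, %d metabolites", n_ref, m_ref)

    needs_unblocked = any(lv.startswith("uRM") for lv in config.levels)
    unblocked = None
    if needs_unblocked:
        blocked = fba_core.find_blocked(universe, zero_tol=config.zero_tol, rng=config.seed)
        unblocked = universe.metabolic_ids - blocked
        fba_core.write_id_set(blocked, out / "blocked.txt")

    ref_stats = netgraph.genotype_stats(reference, universe, currency)
    ref_row = pd.Series(ref_stats.as_dict())

    params_base = dict(burn_in=config.burn_in, thin=config.thin, n_save=config.n_save)
    tables: dict = {}
    start = reference
    for stage, level in enumerate(config.levels):
        try:
            k = _env_count(level)
            spec = ensembles.EnsembleSpec.build(
                level, universe, n_ref,
                max_metabolites=m_ref,
                environments=environments[:k],
                unblocked=unblocked,
            )
            if level == "R":
                genotypes = ensembles.sample_R(universe, n_ref, config.n_save, seed=config.seed)
                acc = 1.0
            else:
                chain_start = start if start <= spec.pool else None
                if chain_start is None or not ensembles.satisfies(chain_start, spec, universe):
                    raise PipelineError(f"{level}: reference start genotype is outside the ensemble")
                params = ensembles.ChainParams(seed=config.seed + stage, **params_base)
                sample = ensembles.run_mcmc(spec, chain_start, params, universe)
                genotypes, acc = sample.genotypes, sample.acceptance_rate
                ensembles.write_sample(sample, out / f"sample_{level}.jsonl")
            stats = netgraph.stats_frame(genotypes, universe, currency)
            stats.to_csv(out / f"stats_{level}.tsv", sep="\t", index=False)
            tables[level] = stats
            logger.info("%s: %d genotypes, acceptance %.3f", level, len(genotypes), acc)
        except Exception as exc:
            raise PipelineError(f"stage {level} failed: {exc}") from exc

    comparison = compare_reference(tables, ref_row)
    comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    ref_frame = pd.DataFrame([{"genotype": "reference", **ref_stats.as_dict()}])
    ref_frame.to_csv(out / "stats_reference.tsv", sep="\t", index=False)
    _write_summary(out / "summary.tsv", tables, ref_row)
    return {"tables": tables, "reference": ref_row, "comparison": comparison, "output_dir": out}


def compare_reference(tables: dict, reference_row: pd.Series) -> pd.DataFrame:
    """Per level and statistic: ensemble mean, population SD, reference value, z-score.

    z = (reference - mean) / SD; reported as NaN when the SD is zero.
    """
    if not tables:
        raise PipelineError("no ensemble statistics to compare")
    rows = []
    for level, df in tables.items():
        for stat in STATISTICS:
            vals = df[stat].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            mean = float(vals.mean()) if vals.size else float("nan")
            sd = float(vals.std(ddof=0)) if vals.size else float("nan")
            ref = float(reference_row[stat])
            z = (ref - mean) / sd if sd > 0 else float("nan")
            rows.append({
                "level": level, "statistic": stat, "mean": mean, "sd": sd,
                "reference": ref, "z": z, "n": int(vals.size),
            })
    return pd.DataFrame(rows)


def cloud_table(tables: dict) -> pd.DataFrame:
    """Per-genotype (P_C, gamma, f_bowtie) triplets, one row per genotype per level."""
    frames = []
    for level, df in tables.items():
        frames.append(df[["genotype", "P_C", "gamma", "f_bowtie"]].assign(level=level))
    return pd.concat(frames, ignore_index=True)


def _write_summary(path, tables: dict, ref_row: pd.Series) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ensemble summary: mean and population SD (n denominator) per statistic\n")
        fh.write("level\t" + "\t".join(f"{s}_mean\t{s}_sd" for s in STATISTICS) + "\n")
        for level, df in tables.items():
            cells = [level]
            for s in STATISTICS:
                v = df[s].to_numpy(dtype=float)
                v = v[~np.isnan(v)]
                cells += [f"{v.mean():.6g}" if v.size else "nan",
                          f"{v.std(ddof=0):.6g}" if v.size else "nan"]
            fh.write("\t".join(cells) + "\n")
        fh.write("reference\t" + "\t".join(f"{float(ref_row[s]):.6g}\t0" for s in STATISTICS) + "\n")
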
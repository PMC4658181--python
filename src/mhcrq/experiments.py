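"""Replicate orchestration: plans, presets, fixtures, and tidy TSV output.

A plan is a grid of scenario cells, each run for a number of replicates with
independently derived seeds.  Replicate-level metrics are aggregated into
means with percentile-bootstrap 95% confidence intervals, resampling
replicates — the aggregation used for the population-size sweeps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .engine import SimulationResult, run_simulation
from .genealogy import GenealogyForest, coalescence_summary, oldest_lineage_age
from .populations import (
    AlleleRegistry,
    HostPopulation,
    PathogenSpeciesPop,
    Scenario,
    ScenarioConfig,
)
from .recognition import MatchRule, str_to_seq
from .summaries import (
    UndefinedStatisticError,
    bootstrap_ci,
    frequency_dependence_trend,
    heterozygote_advantage_from_summaries,
    recruitment_probability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentPlan",
    "derive_seed",
    "summarize_replicate",
    "run_plan",
    "preset_plan",
    "make_fixture",
    "write_config_echo",
    "read_config_echo",
    "write_run",
]

CELL_KEYS = ["scenario", "n_hosts", "mu_pathogen"]


def derive_seed(base_seed: int, cell_index: int) -> int:
    """Independent 31-bit stream seed for one plan cell."""
    return int(np.random.SeedSequence([base_seed, cell_index]).generate_state(1)[0] % (2**31))


@dataclass
class ExperimentPlan:
    """A grid of scenario cells times replicates, reproducible from base_seed."""

    cells: list
    replicates: int = 10
    base_seed: int = 0
    coalescence_window: Optional[int] = None  # enables genealogy analysis per replicate

    def configs(self):
        """Yield (cell_index, replicate_index, fully seeded config)."""
        for ci, template in enumerate(self.cells):
            seed = derive_seed(self.base_seed, ci)
            for rep in range(self.replicates):
                yield ci, rep, template.with_updates(seed=seed, replicate_index=rep)


def summarize_replicate(
    result: SimulationResult, coalescence_window: Optional[int] = None
) -> dict:
    """Flatten one run into the replicate-level metrics of the figure families."""
    cfg = result.config
    s = result.summaries
    row = {
        "scenario": cfg.scenario,
        "n_hosts": cfg.n_hosts,
        "mu_pathogen": cfg.mu_pathogen,
        "replicate": cfg.replicate_index,
        "seed": cfg.seed,
        "mean_n_alleles": float(s["n_distinct_alleles"].mean()),
        "mean_heterozygosity": float(s["observed_heterozygosity"].mean()),
        "mean_fitness": float(s["mean_fitness"].mean()),
        "n_originations": int(len(result.fates)),
        "n_uniform_fallbacks": int(result.n_uniform_fallbacks),
    }
    try:
        row["het_advantage_ratio"] = heterozygote_advantage_from_summaries(s)
    except (UndefinedStatisticError, KeyError):
        row["het_advantage_ratio"] = np.nan
    try:
        row["recruitment_probability"] = recruitment_probability(result.fates)
    except UndefinedStatisticError:
        row["recruitment_probability"] = np.nan
    spectra = result.fates["spectrum_at_birth"]
    row["median_spectrum_at_birth"] = (
        float(spectra.median()) if spectra.notna().any() else np.nan
    )
    if result.freq_dep_points is not None and len(result.freq_dep_points) >= 3:
        slope, _, pval = frequency_dependence_trend(result.freq_dep_points)
        row["freq_dep_slope"], row["freq_dep_pvalue"] = slope, pval
    else:
        row["freq_dep_slope"] = row["freq_dep_pvalue"] = np.nan
    if coalescence_window is not None:
        forest = GenealogyForest.from_registry(result.registry)
        summ = coalescence_summary(
            forest,
            result.final_hosts.origin_ids,
            result.final_hosts.generation,
            coalescence_window,
        )
        row["coal_window"] = summ.window_t
        row["coal_fraction_no_ancestor"] = summ.fraction_no_common_ancestor
        row["coal_mean_time"] = summ.mean_time
        row["coal_median_time"] = summ.median_time
        row["oldest_lineage_age"] = oldest_lineage_age(
            result.registry.birth_generations,
            result.final_hosts.origin_ids,
            result.final_hosts.generation,
        )
    return row


def run_plan(plan: ExperimentPlan, out_dir=None, log_every: Optional[int] = None):
    """Run every cell x replicate; return (replicates_df, aggregate_df).

    Aggregation is per cell: the replicate mean of each metric with a
    percentile-bootstrap 95% CI over replicates.  Tables are written as tidy
    TSVs when ``out_dir`` is given.
    """
    rows = []
    t0 = time.time()
    for ci, rep, cfg in plan.configs():
        result = run_simulation(cfg)
        rows.append(summarize_replicate(result, plan.coalescence_window))
        if log_every and len(rows) % log_every == 0:
            logger.info("finished %d runs in %.1fs", len(rows), time.time() - t0)
    replicates = pd.DataFrame(rows)

    metric_cols = [
        c
        for c in replicates.columns
        if c not in CELL_KEYS + ["replicate", "seed"]
        and pd.api.types.is_numeric_dtype(replicates[c])
    ]
    boot_rng = np.random.default_rng([plan.base_seed, 2**20])
    agg_rows = []
    for key, grp in replicates.groupby(CELL_KEYS, sort=False):
        row = dict(zip(CELL_KEYS, key))
        row["n_replicates"] = len(grp)
        for col in metric_cols:
            vals = grp[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            row[f"{col}_mean"] = float(finite.mean()) if finite.size else np.nan
            if finite.size:
                lo, hi = bootstrap_ci(finite, boot_rng)
            else:
                lo = hi = np.nan
            row[f"{col}_ci_low"], row[f"{col}_ci_high"] = lo, hi
        agg_rows.append(row)
    aggregate = pd.DataFrame(agg_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        replicates.to_csv(out / "replicates.tsv", sep="\t", index=False)
        aggregate.to_csv(out / "aggregate.tsv", sep="\t", index=False)
        for ci, template in enumerate(plan.cells):
            echo = template.with_updates(seed=derive_seed(plan.base_seed, ci))
            write_config_echo(echo, out / f"cell_{ci:03d}.config.txt")
    return replicates, aggregate


def preset_plan(name: str, base_seed: int = 0) -> ExperimentPlan:
    """Named experiment presets.

    ``polymorphism``: the population-size sweep (three scenarios x N in
    {100, 500, 1000, 2500, 5000} x three pathogen mutation rates, 10
    replicates, 2000 + 6000 host generations).
    ``coalescence``: N = 2500, all four scenarios, 3 replicates, 40 000
    generations with a 40 000-generation coalescence window.
    ``desk``: a scaled-down grid (N = 100, 300 + 500 generations, elevated
    host mutation) that reproduces the qualitative scenario contrasts on a
    single core in minutes.
    """
    rates = (2e-4, 1e-3, 5e-3)
    if name == "polymorphism":
        cells = [
            ScenarioConfig(scenario=sc, n_hosts=n, mu_pathogen=mu)
            for mu in rates
            for sc in (Scenario.HA, Scenario.RQ, Scenario.HA_RQ)
            for n in (100, 500, 1000, 2500, 5000)
        ]
        return ExperimentPlan(cells=cells, replicates=10, base_seed=base_seed)
    if name == "coalescence":
        cells = [
            ScenarioConfig(
                scenario=sc, n_hosts=2500, mu_pathogen=mu,
                burn_in=0, recorded_generations=40_000,
            )
            for mu in rates
            for sc in Scenario.ALL
        ]
        return ExperimentPlan(
            cells=cells, replicates=3, base_seed=base_seed, coalescence_window=40_000
        )
    if name == "desk":
        cells = [
            ScenarioConfig(
                scenario=sc, n_hosts=100, mu_pathogen=mu,
                burn_in=300, recorded_generations=500,
                host_site_mutation_rate=1e-5,
            )
            for mu in rates
            for sc in (Scenario.HA, Scenario.RQ, Scenario.HA_RQ)
        ] + [
            ScenarioConfig(
                scenario=Scenario.DRIFT, n_hosts=100,
                burn_in=300, recorded_generations=500,
                host_site_mutation_rate=1e-5,
            )
        ]
        return ExperimentPlan(
            cells=cells, replicates=5, base_seed=base_seed, coalescence_window=700
        )
    raise ValueError(f"unknown preset {name!r}")


# --------------------------------------------------------------------------
# fixtures: deterministic miniature worlds with hand-checkable outcomes
# --------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0):
    """Named micro-scenarios for tests and examples.

    ``monomorphic``  — every host homozygous for one allele (heterozygosity 0).
    ``parity``       — a mutant whose presentation spectrum is exactly 1.
    ``two-lineage``  — a three-node genealogy with known coalescence times.
    """
    rule = MatchRule(string_length=8, match_threshold=4)
    if kind == "monomorphic":
        config = ScenarioConfig(
            scenario=Scenario.HA, n_hosts=4, n_species=2, antigens_per_pathogen=2,
            rule=rule, burn_in=0, recorded_generations=1, seed=seed,
        )
        registry = AlleleRegistry()
        seq = str_to_seq("10110010", rule)
        oid = registry.register(seq, None, 0)
        n = config.n_hosts
        hosts = HostPopulation(
            seqs=np.full((n, 2), seq, dtype=np.uint32),
            origin_ids=np.full((n, 2), oid, dtype=np.int64),
        )
        rng = np.random.default_rng(seed)
        pops = [
            PathogenSpeciesPop(
                sp,
                rng.integers(0, 256, size=(n, config.antigens_per_pathogen)).astype(np.uint32),
            )
            for sp in range(config.n_species)
        ]
        return config, hosts, pops, registry
    if kind == "parity":
        # Two resident alleles at frequency 1/2, recognizing 2 pathogens each;
        # the mutant also recognizes exactly 2, so spectrum = 2 / 2 = 1.
        res_a = str_to_seq("11110000", rule)
        res_b = str_to_seq("00001111", rule)
        mutant = str_to_seq("11000011", rule)
        blank_for_all = str_to_seq("01010101", rule)  # matches none of the three
        pathogens = [
            PathogenSpeciesPop(
                0,
                np.array(
                    [
                        [res_a, blank_for_all],      # recognized by res_a only
                        [res_a ^ 1, blank_for_all],  # res_a only (7-bit run kept)
                        [res_b, blank_for_all],      # res_b only
                        [res_b ^ 128, mutant],       # res_b and mutant
                        [mutant ^ 1, blank_for_all], # mutant only
                        [blank_for_all, blank_for_all],
                    ],
                    dtype=np.uint32,
                ),
            )
        ]
        return {
            "rule": rule,
            "mutant": mutant,
            "resident_sequences": [res_a, res_b],
            "resident_frequencies": [0.5, 0.5],
            "pathogen_pops": pathogens,
        }
    if kind == "two-lineage":
        registry = AlleleRegistry()
        rng = np.random.default_rng(seed)
        founder = registry.register(int(rng.integers(0, 256)), None, 0)
        child_1 = registry.register(int(rng.integers(0, 256)), founder, 10)
        child_2 = registry.register(int(rng.integers(0, 256)), founder, 20)
        return {
            "registry": registry,
            "founder": founder,
            "children": (child_1, child_2),
            # queried at generation 30: divergence at the younger child's birth
            "expected_pair_time_at_30": 10,
        }
    raise ValueError(f"unknown fixture {kind!r}")


# --------------------------------------------------------------------------
# flat key=value config echo and per-run output
# --------------------------------------------------------------------------

_CONFIG_FIELDS = [
    "scenario", "n_hosts", "n_species", "antigens_per_pathogen",
    "pathogen_generations", "mu_pathogen", "host_site_mutation_rate",
    "host_macro_mutation", "pathogen_mutation_model", "burn_in",
    "recorded_generations", "seed", "replicate_index", "fitness_window",
    "recruitment_cutoff", "mutant_window", "track_mutant_spectra",
]


def write_config_echo(config: ScenarioConfig, path) -> None:
    lines = [f"{k}={getattr(config, k)}" for k in _CONFIG_FIELDS]
    lines.append(f"string_length={config.rule.string_length}")
    lines.append(f"match_threshold={config.rule.match_threshold}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config_echo(path) -> ScenarioConfig:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    rule = MatchRule(int(kv.pop("string_length")), int(kv.pop("match_threshold")))
    casts = {
        "n_hosts": int, "n_species": int, "antigens_per_pathogen": int,
        "pathogen_generations": int, "burn_in": int, "recorded_generations": int,
        "seed": int, "replicate_index": int, "recruitment_cutoff": int,
        "mutant_window": int, "mu_pathogen": float, "host_site_mutation_rate": float,
        "host_macro_mutation": lambda s: s == "True",
        "track_mutant_spectra": lambda s: s == "True",
    }
    kwargs = {k: casts.get(k, str)(v) for k, v in kv.items() if k in _CONFIG_FIELDS}
    return ScenarioConfig(rule=rule, **kwargs)


def write_run(result: SimulationResult, out_dir) -> Path:
    """Write one run's tables: summaries, fates, registry, final state, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    result.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
    fates = result.fates.copy()
    fates["frequency_trajectory"] = fates["frequency_trajectory"].map(
        lambda t: ",".join(f"{f:.6g}" for f in t)
    )
    fates.to_csv(out / "fates.tsv", sep="\t", index=False)
    result.registry.write_tsv(out / "registry.tsv", cfg.rule)
    final = pd.DataFrame(
        {
            "host": np.arange(cfg.n_hosts),
            "origin_id_a": result.final_hosts.origin_ids[:, 0],
            "origin_id_b": result.final_hosts.origin_ids[:, 1],
            "sequence_a": [
                format(s, f"0{cfg.rule.string_length}b") for s in result.final_hosts.seqs[:, 0]
            ],
            "sequence_b": [
                format(s, f"0{cfg.rule.string_length}b") for s in result.final_hosts.seqs[:, 1]
            ],
        }
    )
    final.to_csv(out / "final_hosts.tsv", sep="\t", index=False)
    if result.freq_dep_points is not None:
        result.freq_dep_points.to_csv(out / "freq_dep_points.tsv", sep="\t", index=False)
    write_config_echo(cfg, out / "config.txt")
    (out / "run_meta.txt").write_text(
        f"final_generation={result.final_hosts.generation}\n"
        f"n_uniform_fallbacks={result.n_uniform_fallbacks}\n"
    )
    return out
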
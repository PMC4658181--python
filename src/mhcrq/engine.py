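"""The coevolutionary generation cycle.

One host generation consists of ``G_p`` pathogen generations (default 10).
In each pathogen generation every host is attacked by one randomly drawn
individual of each pathogen species (with replacement, so one pathogen can
attack several hosts).  An attack is blocked when the host presents the
pathogen; the host's fitness is the proportion of the ``S * G_p`` encounters
it presented, with dominant resistance (either allele suffices for full
credit — heterozygote advantage) or additive resistance (0.5 credit per
recognizing allele copy — no heterozygote advantage).  Pathogens reproduce
every pathogen generation: proportionally to the number of hosts they
infected (Red Queen selection on) or uniformly at random (pathogen drift),
followed by antigen mutation.  After ``G_p`` pathogen generations hosts
reproduce sexually: for each of the N offspring two distinct parents are
drawn with probability proportional to fitness, each transmits one of its
two alleles, and transmitted copies pass through MHC mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .populations import (
    AlleleRegistry,
    HostGenotype,
    HostPopulation,
    PathogenHaplotype,
    PathogenSpeciesPop,
    ScenarioConfig,
    init_populations,
    mutate_host_gametes,
    mutate_pathogen_pops,
)
from .recognition import MatchRule, recognition_lut
from ._kernels import encounter_kernel
from . import summaries as _summaries

logger = logging.getLogger(__name__)

__all__ = [
    "EncounterLedger",
    "SimulationResult",
    "assign_encounters",
    "encounter_credit",
    "run_pathogen_generation",
    "host_fitness",
    "reproduce_hosts",
    "run_simulation",
]


@dataclass
class EncounterLedger:
    """Attacker indices for one pathogen generation: shape (S, N_hosts)."""

    attackers: np.ndarray

    @property
    def n_species(self) -> int:
        return self.attackers.shape[0]


def assign_encounters(hosts: HostPopulation, pathogen_pops, rng: np.random.Generator) -> EncounterLedger:
    """Draw one attacker per host per species, uniformly with replacement."""
    if not pathogen_pops:
        raise ValueError("no pathogen populations to draw attackers from")
    n_hosts = hosts.n_hosts
    attackers = np.empty((len(pathogen_pops), n_hosts), dtype=np.int64)
    for i, pop in enumerate(pathogen_pops):
        attackers[i] = rng.integers(0, pop.n_individuals, size=n_hosts)
    return EncounterLedger(attackers=attackers)


def _credit_pair(pres_a: bool, pres_b: bool, dominance_mode: str) -> float:
    if dominance_mode == "dominant":
        return 1.0 if (pres_a or pres_b) else 0.0
    if dominance_mode == "additive":
        return 0.5 * (pres_a + pres_b)
    raise ValueError(f"unknown dominance mode {dominance_mode!r}")


def encounter_credit(genotype, attacker, dominance_mode: str, rule: MatchRule) -> float:
    """Fitness credit of one host-pathogen encounter: 0, 0.5 or 1.

    Dominant resistance: full credit if at least one allele presents the
    pathogen.  Additive resistance: 0.5 per allele *copy* whose sequence
    presents, so a presenting homozygote still earns 1.
    """
    if isinstance(genotype, HostGenotype):
        seq_a, seq_b = genotype.allele_a.sequence, genotype.allele_b.sequence
    else:
        seq_a, seq_b = (int(s) for s in genotype)
    antigens = np.asarray(
        attacker.antigens if isinstance(attacker, PathogenHaplotype) else attacker,
        dtype=np.uint32,
    )
    lut = recognition_lut(rule)
    pres_a = bool(lut[antigens ^ np.uint32(seq_a)].any())
    pres_b = bool(lut[antigens ^ np.uint32(seq_b)].any())
    return _credit_pair(pres_a, pres_b, dominance_mode)


# --------------------------------------------------------------------------
# vectorised kernels (operate on the stacked (S, N, A) antigen array)
# --------------------------------------------------------------------------

def _encounter_step(host_seqs, stacked, attackers, dominance_mode, lut):
    """Presentation outcomes of one pathogen generation.

    Returns (credits_per_host, presented_any) with shapes (N,) and (S, N).
    """
    s_idx = np.arange(stacked.shape[0])[:, None]
    att = stacked[s_idx, attackers]  # (S, N, A)
    pres_a = lut[att ^ host_seqs[:, 0][None, :, None]].any(axis=2)
    pres_b = lut[att ^ host_seqs[:, 1][None, :, None]].any(axis=2)
    pres_any = pres_a | pres_b
    if dominance_mode == "dominant":
        credits = pres_any.sum(axis=0).astype(np.float64)
    else:
        credits = 0.5 * (pres_a.sum(axis=0) + pres_b.sum(axis=0)).astype(np.float64)
    return credits, pres_any


def _infection_counts(attackers, pres_any):
    """Hosts infected (not presented) per (species, pathogen individual)."""
    n_species, n = pres_any.shape[0], int(attackers.max(initial=0)) + 1
    n = max(n, attackers.shape[1])  # species populations share size N
    flat_idx = (attackers + (np.arange(n_species)[:, None] * n))[~pres_any]
    return np.bincount(flat_idx, minlength=n_species * n).reshape(n_species, n)


def _select_parents(counts, selection, rng):
    """Fitness-proportional (or uniform) parent index per next-gen pathogen.

    Species where no individual infected any host fall back to uniform
    resampling; the number of such fallbacks is returned.
    """
    n_species, n = counts.shape
    if not selection:
        return rng.integers(0, n, size=(n_species, n)), 0
    row_tot = counts.sum(axis=1)
    fallback = row_tot == 0
    n_fallback = int(fallback.sum())
    p = counts / np.where(fallback, 1, row_tot)[:, None]
    if n_fallback:
        p[fallback] = 1.0 / n
    cdf = np.cumsum(p, axis=1)
    cdf /= cdf[:, -1:]
    glob = cdf + np.arange(n_species)[:, None]
    u = rng.random((n_species, n)) + np.arange(n_species)[:, None]
    parents = (np.searchsorted(glob.ravel(), u.ravel()) % n).reshape(n_species, n)
    return parents, n_fallback


def _resample_stacked(stacked, attackers, pres_any, selection, rng):
    """Next pathogen generation; returns (new_stacked, n_uniform_fallbacks)."""
    counts = _infection_counts(attackers, pres_any)
    parents, n_fallback = _select_parents(counts, selection, rng)
    new = stacked[np.arange(stacked.shape[0])[:, None], parents]
    return new, n_fallback


def run_pathogen_generation(
    hosts: HostPopulation,
    pathogen_pops: list,
    ledger: EncounterLedger,
    config: ScenarioConfig,
    rng: np.random.Generator,
):
    """One pathogen generation on species-population objects (test-friendly API).

    Accumulates per-host encounter credits, then replaces each species'
    individuals by fitness-proportional resampling (selection on) or uniform
    resampling (selection off), followed by mutation.  A species in which no
    individual infected any host falls back to uniform resampling.

    Returns ``(credits, n_uniform_fallbacks)``; ``pathogen_pops`` is updated
    in place.
    """
    stacked = np.stack([pop.antigens for pop in pathogen_pops])
    lut = recognition_lut(config.rule)
    credits, pres_any = _encounter_step(
        hosts.seqs, stacked, ledger.attackers, config.dominance_mode, lut
    )
    new, n_fallback = _resample_stacked(
        stacked, ledger.attackers, pres_any, config.pathogen_selection, rng
    )
    mutate_pathogen_pops(new, config.mu_pathogen, rng, config.rule,
                         model=config.pathogen_mutation_model)
    for i, pop in enumerate(pathogen_pops):
        pop.antigens = new[i]
    if n_fallback:
        logger.warning("uniform fallback for %d pathogen species with zero fitness", n_fallback)
    return credits, n_fallback


def host_fitness(credits: np.ndarray, n_species: int, pathogen_generations: int) -> np.ndarray:
    """Normalise accumulated credits to the proportion of pathogens presented."""
    fitness = np.asarray(credits, dtype=np.float64) / (n_species * pathogen_generations)
    if fitness.size and (fitness.min() < -1e-12 or fitness.max() > 1 + 1e-12):
        raise ValueError("fitness outside [0, 1]; credits inconsistent with window")
    return np.clip(fitness, 0.0, 1.0)


def _sample_parent_pairs(fitness, rng):
    """Two distinct parents per offspring, probability proportional to fitness."""
    n = fitness.size
    tot = float(fitness.sum())
    p = None if tot <= 0 else fitness / tot
    if p is None:
        logger.warning("all host fitnesses zero; uniform parent sampling")

    def draw(size, uniform=False):
        if p is None or uniform:
            return rng.integers(0, n, size=size)
        return rng.choice(n, size=size, p=p)

    # With a single positive-weight host the distinct co-parent is drawn
    # uniformly from the rest (proportional sampling would never terminate).
    second_uniform = p is not None and np.count_nonzero(p) < 2
    p1 = draw(n)
    p2 = draw(n, uniform=second_uniform)
    clash = p1 == p2
    while clash.any():
        p2[clash] = draw(int(clash.sum()), uniform=second_uniform)
        clash = p1 == p2
    return p1, p2


def reproduce_hosts(
    hosts: HostPopulation,
    fitness: np.ndarray,
    config: ScenarioConfig,
    registry: AlleleRegistry,
    rng: np.random.Generator,
) -> HostPopulation:
    """Sexual reproduction with fitness-proportional parent sampling.

    Each parent transmits one of its two alleles with probability 1/2;
    transmitted copies then pass through MHC mutation.  Population size is
    conserved.
    """
    n = hosts.n_hosts
    if n < 2:
        raise ValueError("sexual reproduction requires at least two hosts")
    fitness = np.ones(n) if fitness is None else np.asarray(fitness, dtype=np.float64)
    p1, p2 = _sample_parent_pairs(fitness, rng)
    gametes = rng.integers(0, 2, size=(n, 2))
    rows = np.arange(n)
    child_seqs = np.stack(
        [hosts.seqs[p1, gametes[rows, 0]], hosts.seqs[p2, gametes[rows, 1]]], axis=1
    )
    child_ids = np.stack(
        [hosts.origin_ids[p1, gametes[rows, 0]], hosts.origin_ids[p2, gametes[rows, 1]]],
        axis=1,
    )
    next_gen = hosts.generation + 1
    child_seqs, child_ids = mutate_host_gametes(
        child_seqs,
        child_ids,
        config.host_site_mutation_rate,
        registry,
        rng,
        next_gen,
        config.rule,
        macro=config.host_macro_mutation,
    )
    return HostPopulation(seqs=child_seqs, origin_ids=child_ids, generation=next_gen)


# --------------------------------------------------------------------------
# full simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything one run produces."""

    config: ScenarioConfig
    summaries: pd.DataFrame          # one row per recorded host generation
    registry: AlleleRegistry
    counts_history: dict             # generation -> (origination ids, copy counts)
    mutant_spectra: dict             # origination id -> presentation spectrum at birth
    fates: pd.DataFrame              # one row per origination in the recorded window
    freq_dep_points: Optional[pd.DataFrame]
    final_hosts: HostPopulation
    final_pathogens: list = field(default_factory=list)
    n_uniform_fallbacks: int = 0


def _summary_row(config, gen, hosts, fitness, n_new):
    seq_a, seq_b = hosts.seqs[:, 0], hosts.seqs[:, 1]
    het = seq_a != seq_b
    _, counts = np.unique(hosts.seqs, return_counts=True)
    freqs = counts / hosts.seqs.size
    if config.has_pathogens:
        het_rec = float(fitness[het].mean()) if het.any() else np.nan
        hom_rec = float(fitness[~het].mean()) if (~het).any() else np.nan
    else:
        het_rec = hom_rec = np.nan
    return {
        "generation": gen,
        "scenario": config.scenario,
        "n_distinct_alleles": int(freqs.size),
        "observed_heterozygosity": float(het.mean()),
        "expected_heterozygosity": float(1.0 - np.square(freqs).sum()),
        "mean_fitness": float(fitness.mean()),
        "het_mean_recognition": het_rec,
        "hom_mean_recognition": hom_rec,
        "n_new_originations": int(n_new),
    }


def run_simulation(config: ScenarioConfig) -> SimulationResult:
    """Run ``burn_in + recorded_generations`` host generations.

    Fully reproducible from ``(seed, replicate_index)``.  Statistics are
    recorded only after burn-in; the allele registry and per-generation
    copy counts are kept for the whole run so genealogies reach the founders.
    """
    rng = np.random.default_rng([config.seed, config.replicate_index])
    hosts, pathogen_pops, registry = init_populations(config, rng)
    n, n_species = config.n_hosts, config.n_species
    g_p = config.pathogen_generations
    lut = recognition_lut(config.rule) if config.has_pathogens else None
    stacked = (
        np.stack([pop.antigens for pop in pathogen_pops]) if config.has_pathogens else None
    )
    snapshot_gens = set(
        config.freq_dep_snapshots
        if config.freq_dep_snapshots is not None
        else (config.burn_in,)
    )

    counts_history: dict = {}
    mutant_spectra: dict = {}
    freq_point_frames = []
    rows = []
    n_fallback_total = 0

    def record_counts(gen):
        ids, cnts = np.unique(hosts.origin_ids, return_counts=True)
        counts_history[gen] = (ids.astype(np.int64), cnts.astype(np.int64))

    record_counts(0)
    total = config.total_generations
    for gen in range(total):
        if config.has_pathogens:
            credits = np.zeros(n, dtype=np.float64)
            seq_a = np.ascontiguousarray(hosts.seqs[:, 0])
            seq_b = np.ascontiguousarray(hosts.seqs[:, 1])
            s_rows = np.arange(n_species)[:, None]
            for _pg in range(g_p):
                attackers = rng.integers(0, n, size=(n_species, n))
                step_credits, counts = encounter_kernel(
                    stacked, attackers, seq_a, seq_b, lut,
                    config.dominance_mode == "dominant",
                )
                if config.fitness_window == "all" or _pg == g_p - 1:
                    credits += step_credits
                parents, n_fb = _select_parents(counts, config.pathogen_selection, rng)
                n_fallback_total += n_fb
                stacked = stacked[s_rows, parents]
                mutate_pathogen_pops(stacked, config.mu_pathogen, rng, config.rule,
                                     model=config.pathogen_mutation_model)
            denom = n_species * (g_p if config.fitness_window == "all" else 1)
            fitness = credits / denom
        else:
            fitness = np.ones(n, dtype=np.float64)

        if gen in snapshot_gens and config.has_pathogens:
            pops = [PathogenSpeciesPop(i, stacked[i]) for i in range(n_species)]
            pts = _summaries.frequency_dependence_points(hosts, pops, config.rule)
            pts.insert(0, "generation", gen)
            freq_point_frames.append(pts)

        record = gen >= config.burn_in
        if record:
            row = _summary_row(config, gen, hosts, fitness, 0)
        n_before = len(registry)
        hosts = reproduce_hosts(hosts, fitness, config, registry, rng)
        new_ids = range(n_before, len(registry))
        record_counts(hosts.generation)

        if record:
            row["n_new_originations"] = len(registry) - n_before
            rows.append(row)
            if (
                config.track_mutant_spectra
                and config.has_pathogens
                and n_before < len(registry)
            ):
                pops = [PathogenSpeciesPop(i, stacked[i]) for i in range(n_species)]
                mutant_spectra.update(
                    _summaries.mutant_presentation_spectra(
                        list(new_ids), hosts, registry, pops, config.rule
                    )
                )

    final_pops = (
        [PathogenSpeciesPop(i, stacked[i]) for i in range(n_species)]
        if config.has_pathogens
        else []
    )
    summaries_df = pd.DataFrame(
        rows,
        columns=[
            "generation", "scenario", "n_distinct_alleles", "observed_heterozygosity",
            "expected_heterozygosity", "mean_fitness", "het_mean_recognition",
            "hom_mean_recognition", "n_new_originations",
        ],
    )
    fates = _summaries.track_mutants(
        registry,
        counts_history,
        first_generation=config.burn_in + 1,
        last_generation=total,
        n_hosts=n,
        cutoff=config.recruitment_cutoff,
        window=config.mutant_window,
        spectra=mutant_spectra,
    )
    return SimulationResult(
        config=config,
        summaries=summaries_df,
        registry=registry,
        counts_history=counts_history,
        mutant_spectra=mutant_spectra,
        fates=fates,
        freq_dep_points=pd.concat(freq_point_frames, ignore_index=True)
        if freq_point_frames
        else None,
        final_hosts=hosts,
        final_pathogens=final_pops,
        n_uniform_fallbacks=n_fallback_total,
    )
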
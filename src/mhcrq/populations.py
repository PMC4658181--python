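"""Host and pathogen population state, initialization, and mutation models.

Hosts are diploid at a single MHC locus; each of the ``2N`` allele copies is a
packed bit-string plus an *origination identity* — a pointer into an
append-only registry that records, for every allele ever created, its
sequence, the allele it mutated from, and the host generation of its birth.
Polymorphism statistics count distinct sequences; the genealogy operates on
origination identities (a back-mutation that recreates an existing sequence
founds a new lineage node).

Pathogens are haploid and asexual: 50 species by default, each with one
individual per host, each individual expressing 20 antigens.  A pathogen
offspring is identical to its parent except for mutation: each antigen
independently mutates with the per-antigen rate, and a mutating antigen has
exactly one uniformly chosen bit flipped (an optional per-bit model spreads
the same rate over the bits instead).

Host MHC mutation is per-site: each bit of a transmitted allele copy flips
independently with probability ``p_t`` (default 6.25e-7 per site per host
generation, i.e. ~1e-5 per molecule).  A macro-mutation mode replaces the
whole string with a fresh random one at the equivalent per-molecule rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .recognition import MatchRule, random_sequences

__all__ = [
    "Scenario",
    "MhcAllele",
    "HostGenotype",
    "HostPopulation",
    "PathogenHaplotype",
    "PathogenSpeciesPop",
    "ScenarioConfig",
    "AlleleRegistry",
    "init_populations",
    "expected_new_allele_rate",
    "mutate_host_gametes",
    "mutate_pathogen",
    "mutate_pathogen_pops",
]


class Scenario:
    """The four selection scenarios."""

    HA_RQ = "HA+RQ"  # dominant resistance, pathogen selection on
    HA = "HA"        # dominant resistance, pathogen drift
    RQ = "RQ"        # additive resistance, pathogen selection on
    DRIFT = "DRIFT"  # no pathogens; hosts drift

    ALL = (HA_RQ, HA, RQ, DRIFT)

    _ALIASES = {"HARQ": HA_RQ, "HA+RQ": HA_RQ, "RQ+HA": HA_RQ,
                "HA": HA, "RQ": RQ, "DRIFT": DRIFT, "NEUTRAL": DRIFT}

    @classmethod
    def normalize(cls, name: str) -> str:
        key = str(name).strip().upper().replace(" ", "")
        try:
            return cls._ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}; expected one of {cls.ALL}")


@dataclass(frozen=True)
class MhcAllele:
    """One origination record: the atom of the allele genealogy."""

    origination_id: int
    sequence: int
    parent_id: Optional[int]  # None for founders
    birth_generation: int


@dataclass(frozen=True)
class HostGenotype:
    allele_a: MhcAllele
    allele_b: MhcAllele

    @property
    def heterozygous(self) -> bool:
        return self.allele_a.sequence != self.allele_b.sequence


@dataclass
class HostPopulation:
    """N diploid hosts, stored column-wise for vectorised work.

    ``seqs`` and ``origin_ids`` have shape ``(N, 2)``.
    """

    seqs: np.ndarray
    origin_ids: np.ndarray
    generation: int = 0

    @property
    def n_hosts(self) -> int:
        return self.seqs.shape[0]

    @property
    def heterozygous(self) -> np.ndarray:
        return self.seqs[:, 0] != self.seqs[:, 1]

    def genotype(self, i: int, registry: "AlleleRegistry") -> HostGenotype:
        return HostGenotype(
            registry.allele(int(self.origin_ids[i, 0])),
            registry.allele(int(self.origin_ids[i, 1])),
        )

    def allele_frequencies(self) -> pd.Series:
        """Frequency of each distinct sequence among the 2N copies."""
        seqs, counts = np.unique(self.seqs, return_counts=True)
        return pd.Series(counts / self.seqs.size, index=seqs.astype(int))


@dataclass(frozen=True)
class PathogenHaplotype:
    """One haploid pathogen individual: an ordered antigen repertoire."""

    antigens: tuple

    @classmethod
    def from_array(cls, arr) -> "PathogenHaplotype":
        return cls(tuple(int(a) for a in np.asarray(arr).ravel()))


@dataclass
class PathogenSpeciesPop:
    """One pathogen species: ``antigens`` has shape (N, antigens_per_pathogen)."""

    species_id: int
    antigens: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.antigens.shape[0]


@dataclass(frozen=True)
class ScenarioConfig:
    """All model parameters and scenario toggles for one simulation run."""

    scenario: str = Scenario.HA_RQ
    n_hosts: int = 1000                     # N
    n_species: int = 50                     # S
    antigens_per_pathogen: int = 20
    rule: MatchRule = field(default_factory=MatchRule)
    pathogen_generations: int = 10          # pathogen generations per host generation
    mu_pathogen: float = 1e-3               # per antigen per pathogen generation
    host_site_mutation_rate: float = 6.25e-7  # p_t, per bit per host generation
    host_macro_mutation: bool = False
    pathogen_mutation_model: str = "per_antigen"  # or "per_bit"
    burn_in: int = 2000
    recorded_generations: int = 6000
    seed: int = 0
    replicate_index: int = 0
    fitness_window: str = "all"             # or "last" (final pathogen generation only)
    freq_dep_snapshots: Optional[tuple] = None  # host generations; default: end of burn-in
    recruitment_cutoff: int = 10
    mutant_window: int = 25
    track_mutant_spectra: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario.normalize(self.scenario))
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be >= 2 for sexual reproduction")
        if self.has_pathogens and (self.n_species < 1 or self.antigens_per_pathogen < 1):
            raise ValueError("pathogen counts must be >= 1")
        for p, name in ((self.mu_pathogen, "mu_pathogen"),
                        (self.host_site_mutation_rate, "host_site_mutation_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.pathogen_generations < 1:
            raise ValueError("pathogen_generations must be >= 1")
        if self.burn_in < 0 or self.recorded_generations < 0:
            raise ValueError("durations must be non-negative")
        if self.fitness_window not in ("all", "last"):
            raise ValueError("fitness_window must be 'all' or 'last'")
        if self.pathogen_mutation_model not in ("per_antigen", "per_bit"):
            raise ValueError("pathogen_mutation_model must be 'per_antigen' or 'per_bit'")

    # scenario-derived toggles -------------------------------------------------
    @property
    def has_pathogens(self) -> bool:
        return self.scenario != Scenario.DRIFT

    @property
    def dominance_mode(self) -> str:
        """'dominant' resistance gives heterozygote advantage; 'additive' removes it."""
        return "additive" if self.scenario == Scenario.RQ else "dominant"

    @property
    def pathogen_selection(self) -> bool:
        return self.scenario in (Scenario.HA_RQ, Scenario.RQ)

    @property
    def total_generations(self) -> int:
        return self.burn_in + self.recorded_generations

    def with_updates(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


class AlleleRegistry:
    """Append-only log of allele origination events.

    Row ``i`` of the internal arrays describes origination id ``i``; parents
    are stored as ``-1`` for founders.
    """

    def __init__(self) -> None:
        self.sequences: list[int] = []
        self.parent_ids: list[int] = []
        self.birth_generations: list[int] = []

    def __len__(self) -> int:
        return len(self.sequences)

    def register(self, sequence: int, parent_id: Optional[int], birth_generation: int) -> int:
        if parent_id is not None:
            if not 0 <= parent_id < len(self):
                raise ValueError(f"unknown parent id {parent_id}")
            if self.birth_generations[parent_id] > birth_generation:
                raise ValueError("parent must predate child")
        new_id = len(self)
        self.sequences.append(int(sequence))
        self.parent_ids.append(-1 if parent_id is None else int(parent_id))
        self.birth_generations.append(int(birth_generation))
        return new_id

    def allele(self, origination_id: int) -> MhcAllele:
        if not 0 <= origination_id < len(self):
            raise KeyError(f"unknown origination id {origination_id}")
        parent = self.parent_ids[origination_id]
        return MhcAllele(
            origination_id=origination_id,
            sequence=self.sequences[origination_id],
            parent_id=None if parent < 0 else parent,
            birth_generation=self.birth_generations[origination_id],
        )

    def to_dataframe(self, rule: Optional[MatchRule] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "origination_id": np.arange(len(self), dtype=int),
                "parent_id": np.asarray(self.parent_ids, dtype=int),
                "birth_generation": np.asarray(self.birth_generations, dtype=int),
                "sequence": np.asarray(self.sequences, dtype=int),
            }
        )
        if rule is not None:
            df["sequence"] = [format(s, f"0{rule.string_length}b") for s in df["sequence"]]
        return df

    def write_tsv(self, path, rule: Optional[MatchRule] = None) -> None:
        self.to_dataframe(rule).to_csv(path, sep="\t", index=False)


def init_populations(config: ScenarioConfig, rng: np.random.Generator):
    """Random initial populations: maximal host polymorphism at the outset.

    Every one of the 2N host allele copies is an independent uniform random
    sequence registered as a founder; each pathogen species gets N individuals
    with uniform random antigens.  The drift scenario has no pathogens.
    """
    n, rule = config.n_hosts, config.rule
    seqs = random_sequences(rng, (n, 2), rule)
    registry = AlleleRegistry()
    origin_ids = np.empty((n, 2), dtype=np.int64)
    flat_ids = [registry.register(int(s), None, 0) for s in seqs.ravel()]
    origin_ids[:] = np.asarray(flat_ids, dtype=np.int64).reshape(n, 2)
    hosts = HostPopulation(seqs=seqs, origin_ids=origin_ids, generation=0)

    pathogen_pops: list[PathogenSpeciesPop] = []
    if config.has_pathogens:
        for sp in range(config.n_species):
            antigens = random_sequences(rng, (n, config.antigens_per_pathogen), rule)
            pathogen_pops.append(PathogenSpeciesPop(species_id=sp, antigens=antigens))
    return hosts, pathogen_pops, registry


def expected_new_allele_rate(p_t: float, string_length: int) -> float:
    """Per-molecule per-generation probability of at least one site mutating.

    Exactly ``1 - (1 - p_t)**L``; approximately ``L * p_t`` for small rates.
    """
    if not 0.0 <= p_t <= 1.0:
        raise ValueError("p_t must be a probability")
    if string_length < 1:
        raise ValueError("string_length must be >= 1")
    return -np.expm1(string_length * np.log1p(-p_t)) if p_t < 1.0 else 1.0


def mutate_host_gametes(
    seqs: np.ndarray,
    origin_ids: np.ndarray,
    p_t: float,
    registry: AlleleRegistry,
    rng: np.random.Generator,
    generation: int,
    rule: MatchRule,
    macro: bool = False,
):
    """Apply MHC mutation to an array of transmitted allele copies.

    Point-mutation mode flips each bit independently with probability ``p_t``;
    any copy with at least one flipped bit becomes a new origination record
    whose parent is the transmitted allele.  Macro-mutation mode replaces the
    whole string with a fresh uniform random one at the equivalent
    per-molecule rate.

    Returns ``(seqs, origin_ids)`` — new arrays; inputs are not modified.
    """
    shape = seqs.shape
    flat_seqs = np.asarray(seqs, dtype=np.uint32).ravel().copy()
    flat_ids = np.asarray(origin_ids, dtype=np.int64).ravel().copy()
    m = flat_seqs.size
    length = rule.string_length

    if macro:
        rate = expected_new_allele_rate(p_t, length)
        hit = np.flatnonzero(rng.random(m) < rate)
        new_seqs = random_sequences(rng, hit.size, rule)
        for j, idx in enumerate(hit):
            seq = int(new_seqs[j])
            flat_ids[idx] = registry.register(seq, int(flat_ids[idx]), generation)
            flat_seqs[idx] = seq
    elif p_t > 0.0:
        flips = rng.random((m, length)) < p_t
        hit = np.flatnonzero(flips.any(axis=1))
        if hit.size:
            weights = (np.uint32(1) << np.arange(length, dtype=np.uint32))[::-1]
            masks = (flips[hit] * weights).sum(axis=1, dtype=np.uint64).astype(np.uint32)
            for idx, mask in zip(hit, masks):
                seq = int(flat_seqs[idx] ^ mask)
                flat_ids[idx] = registry.register(seq, int(flat_ids[idx]), generation)
                flat_seqs[idx] = seq
    return flat_seqs.reshape(shape), flat_ids.reshape(shape)


def _uniform_subset(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform k-subset of range(total), cheap for k << total."""
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    if k * 8 >= total:
        return rng.permutation(total)[:k].astype(np.int64)
    chosen = np.unique(rng.integers(0, total, size=k))
    while chosen.size < k:
        extra = rng.integers(0, total, size=k - chosen.size)
        chosen = np.unique(np.concatenate([chosen, extra]))
    return chosen.astype(np.int64)


def mutate_pathogen(
    haplotype: PathogenHaplotype,
    mu_pathogen: float,
    rng: np.random.Generator,
    rule: MatchRule,
    model: str = "per_antigen",
) -> PathogenHaplotype:
    """Mutate one pathogen individual (scalar API over the vectorised kernel)."""
    arr = np.asarray(haplotype.antigens, dtype=np.uint32).reshape(1, 1, -1)
    out = mutate_pathogen_pops(arr, mu_pathogen, rng, rule, model=model)
    return PathogenHaplotype.from_array(out)


def mutate_pathogen_pops(
    antigens: np.ndarray,
    mu_pathogen: float,
    rng: np.random.Generator,
    rule: MatchRule,
    model: str = "per_antigen",
) -> np.ndarray:
    """Mutate an antigen array of shape (..., antigens_per_pathogen) in place.

    per_antigen: each antigen mutates with probability ``mu_pathogen`` and a
    mutating antigen has exactly one uniformly chosen bit flipped.
    per_bit: each bit flips independently with ``mu_pathogen / string_length``.
    """
    if not 0.0 <= mu_pathogen <= 1.0:
        raise ValueError("mu_pathogen must be a probability")
    if mu_pathogen == 0.0:
        return antigens
    length = rule.string_length
    if model == "per_antigen":
        # Bernoulli(mu) per antigen == Binomial count, then a uniform subset
        # of positions; sampled that way to avoid a full random array.
        total = antigens.size
        k = int(rng.binomial(total, mu_pathogen))
        hit = _uniform_subset(total, k, rng)
        if hit.size:
            bits = rng.integers(0, length, size=hit.size, dtype=np.uint32)
            flat = antigens.reshape(-1)
            flat[hit] ^= np.uint32(1) << bits
    elif model == "per_bit":
        per_bit = mu_pathogen / length
        flips = rng.random(antigens.shape + (length,)) < per_bit
        weights = (np.uint32(1) << np.arange(length, dtype=np.uint32))[::-1]
        masks = (flips * weights).sum(axis=-1, dtype=np.uint64).astype(np.uint32)
        antigens ^= masks
    else:
        raise ValueError(f"unknown pathogen mutation model {model!r}")
    return antigens
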
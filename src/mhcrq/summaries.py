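"""Derived statistics: polymorphism, heterozygote advantage, frequency
dependence, and the fate of new mutant alleles.

Recognition ability of an allele is measured against *all* pathogen
individuals of all species (an expected proportion, not the realized
encounters).  Host-level recognition classes (heterozygote vs homozygote)
use the realized fitness credits, which estimate the same expectation and
are already accumulated by the engine.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .populations import AlleleRegistry, HostPopulation
from .recognition import MatchRule, presentation_matrix

__all__ = [
    "UndefinedStatisticError",
    "allele_recognition_ability",
    "heterozygote_advantage",
    "heterozygote_advantage_from_summaries",
    "frequency_dependence_points",
    "frequency_dependence_trend",
    "track_mutants",
    "recruitment_probability",
    "presentation_spectrum",
    "mutant_presentation_spectra",
    "bootstrap_ci",
]


class UndefinedStatisticError(ValueError):
    """A statistic whose defining classes or populations are empty."""


def _stack(pathogen_pops) -> np.ndarray:
    if not pathogen_pops:
        raise UndefinedStatisticError("no pathogen populations (drift scenario?)")
    return np.stack([pop.antigens for pop in pathogen_pops])


def allele_recognition_ability(sequence: int, pathogen_pops, rule: MatchRule) -> float:
    """Fraction of all S*N pathogen individuals presented by this sequence."""
    stacked = _stack(pathogen_pops)
    pres = presentation_matrix(np.asarray([sequence]), stacked, rule)
    return float(pres.mean())


def heterozygote_advantage(hosts: HostPopulation, recognition: np.ndarray) -> float:
    """Ratio of mean recognition of heterozygous hosts to homozygous hosts."""
    recognition = np.asarray(recognition, dtype=np.float64)
    het = hosts.heterozygous
    if not het.any() or het.all():
        raise UndefinedStatisticError("need at least one heterozygote and one homozygote")
    return float(recognition[het].mean() / recognition[~het].mean())


def heterozygote_advantage_from_summaries(summaries: pd.DataFrame) -> float:
    """Generation-averaged heterozygote/homozygote recognition ratio."""
    het = summaries["het_mean_recognition"].to_numpy(dtype=float)
    hom = summaries["hom_mean_recognition"].to_numpy(dtype=float)
    ok = np.isfinite(het) & np.isfinite(hom) & (hom > 0)
    if not ok.any():
        raise UndefinedStatisticError("no generation with both host classes present")
    return float(het[ok].mean() / hom[ok].mean())


def frequency_dependence_points(
    hosts: HostPopulation, pathogen_pops, rule: MatchRule
) -> pd.DataFrame:
    """One row per distinct allele: frequency and expected recognition ability."""
    stacked = _stack(pathogen_pops)
    seqs, counts = np.unique(hosts.seqs, return_counts=True)
    pres = presentation_matrix(seqs.astype(np.uint32), stacked, rule)  # (A, S, N)
    ability = pres.reshape(pres.shape[0], -1).mean(axis=1)
    return pd.DataFrame(
        {
            "sequence": seqs.astype(int),
            "frequency": counts / hosts.seqs.size,
            "recognition_ability": ability,
        }
    )


def frequency_dependence_trend(points: pd.DataFrame):
    """OLS slope of recognition ability on allele frequency, with a t-test.

    Returns ``(slope, t_statistic, p_value)`` for the two-sided test of a
    zero slope.
    """
    if len(points) < 3:
        raise UndefinedStatisticError("need at least 3 alleles for a trend")
    res = stats.linregress(points["frequency"], points["recognition_ability"])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = res.slope / res.stderr if res.stderr > 0 else np.nan
    return float(res.slope), float(tstat), float(res.pvalue)


def _copies(counts_history: dict, generation: int, origination_id: int) -> int:
    entry = counts_history.get(generation)
    if entry is None:
        return 0
    ids, counts = entry
    i = np.searchsorted(ids, origination_id)
    if i < ids.size and ids[i] == origination_id:
        return int(counts[i])
    return 0


def track_mutants(
    registry: AlleleRegistry,
    counts_history: dict,
    first_generation: int,
    last_generation: int,
    n_hosts: int,
    cutoff: int = 10,
    window: int = 25,
    spectra: Optional[dict] = None,
) -> pd.DataFrame:
    """Fate of every origination event born in the observation window.

    ``lifespan`` counts host generations with at least one copy (starting at
    birth; alleles cannot re-enter after extinction).  ``recruited`` means the
    lifespan reached ``cutoff`` generations; records still alive at the end of
    the run with an as-yet undecided fate are flagged ``censored``.
    """
    spectra = spectra or {}
    births = np.asarray(registry.birth_generations)
    candidates = np.flatnonzero((births >= first_generation) & (births <= last_generation))
    rows = []
    for oid in candidates:
        birth = int(births[oid])
        gen = birth
        while gen <= last_generation and _copies(counts_history, gen, oid) > 0:
            gen += 1
        alive_at_end = gen > last_generation
        lifespan = (gen - birth) if not alive_at_end else (last_generation - birth + 1)
        censored = alive_at_end and lifespan < cutoff
        traj = [
            _copies(counts_history, g, oid) / (2 * n_hosts)
            for g in range(birth, min(birth + window, last_generation + 1))
        ]
        rows.append(
            {
                "origination_id": int(oid),
                "birth_generation": birth,
                "lifespan": int(lifespan),
                "extinct": not alive_at_end,
                "censored": bool(censored),
                "recruited": bool(lifespan >= cutoff),
                "spectrum_at_birth": float(spectra.get(oid, np.nan)),
                "frequency_trajectory": traj,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "origination_id", "birth_generation", "lifespan", "extinct",
            "censored", "recruited", "spectrum_at_birth", "frequency_trajectory",
        ],
    )


def recruitment_probability(fates: pd.DataFrame, cutoff: Optional[int] = None) -> float:
    """Fraction of (uncensored) origination events that persisted >= cutoff."""
    if cutoff is None:
        usable = fates[~fates["censored"]]
        if usable.empty:
            raise UndefinedStatisticError("no uncensored origination events")
        return float(usable["recruited"].mean())
    reached = fates["lifespan"] >= cutoff
    censored = ~fates["extinct"] & ~reached
    usable = fates[~censored]
    if usable.empty:
        raise UndefinedStatisticError("no uncensored origination events")
    return float((usable["lifespan"] >= cutoff).mean())


def presentation_spectrum(
    mutant_sequence: int,
    resident_sequences,
    resident_frequencies,
    pathogen_pops,
    rule: MatchRule,
) -> float:
    """Mutant recognition relative to the frequency-weighted resident mean.

    A value of 1 means the mutant presents, on average, the same number of
    pathogens as the resident alleles do.
    """
    stacked = _stack(pathogen_pops)
    freqs = np.asarray(resident_frequencies, dtype=np.float64)
    if freqs.size == 0:
        raise UndefinedStatisticError("no resident alleles")
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("resident frequencies must sum to 1")
    seqs = np.asarray([mutant_sequence, *np.asarray(resident_sequences, dtype=int)])
    pres = presentation_matrix(seqs.astype(np.uint32), stacked, rule)
    counts = pres.reshape(pres.shape[0], -1).sum(axis=1)
    resident_mean = float(np.dot(freqs, counts[1:]))
    if resident_mean <= 0:
        raise UndefinedStatisticError("resident alleles recognize no pathogens")
    return float(counts[0] / resident_mean)


def mutant_presentation_spectra(
    new_ids, hosts: HostPopulation, registry: AlleleRegistry, pathogen_pops, rule: MatchRule
) -> dict:
    """Presentation spectrum at birth for a batch of new origination ids.

    Residents are all allele copies in the population other than the mutant's
    own; undefined spectra (no residents recognizing anything) are omitted.
    """
    out: dict = {}
    if not new_ids:
        return out
    stacked = _stack(pathogen_pops)
    seqs, inverse = np.unique(hosts.seqs.ravel(), return_inverse=True)
    pres = presentation_matrix(seqs.astype(np.uint32), stacked, rule)
    counts_recognized = pres.reshape(pres.shape[0], -1).sum(axis=1)
    copy_counts = np.bincount(inverse, minlength=seqs.size)
    flat_ids = hosts.origin_ids.ravel()
    for oid in new_ids:
        mutant_seq = registry.sequences[oid]
        mutant_copies = int((flat_ids == oid).sum())
        if mutant_copies == 0:
            continue  # mutant already lost (cannot happen at birth, but be safe)
        seq_pos = np.searchsorted(seqs, mutant_seq)
        resident_counts = copy_counts.astype(np.float64).copy()
        resident_counts[seq_pos] -= mutant_copies
        total = resident_counts.sum()
        if total <= 0:
            continue
        resident_mean = float(np.dot(resident_counts / total, counts_recognized))
        if resident_mean <= 0:
            continue
        out[int(oid)] = float(counts_recognized[seq_pos] / resident_mean)
    return out


def bootstrap_ci(
    values,
    rng: np.random.Generator,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple:
    """Percentile bootstrap CI for the mean of replicate-level values."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise UndefinedStatisticError("no finite replicate values")
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha))
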
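"""Allele-origination forest and coalescence analysis.

Every allele ever created is a node with a pointer to the allele it mutated
from (founders are roots), so the registry forms a forest over origination
events.  Two allele lineages *coalesce* at the divergence event that
separated them: the birth of the younger of the two branch nodes immediately
below their most recent shared ancestor.  For a parent-child pair that is the
child's birth — the two lineages were a single allele until the mutation
occurred.  Two copies of the same allele have coalescence time 0.

Pairs whose divergence lies further back than the scanning window (or which
descend from different founders) count as having no common ancestor within
the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .populations import AlleleRegistry

__all__ = [
    "GenealogyForest",
    "CoalescenceSummary",
    "common_ancestor_time",
    "coalescence_summary",
    "pairwise_coalescence_times",
    "oldest_lineage_age",
]


class GenealogyForest:
    """Parent-pointer forest over origination events, with chain caching."""

    def __init__(self, parent_ids, birth_generations):
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.birth_generations = np.asarray(birth_generations, dtype=np.int64)
        if self.parent_ids.shape != self.birth_generations.shape:
            raise ValueError("parent and birth arrays must align")
        self._chains: dict = {}

    @classmethod
    def from_registry(cls, registry: AlleleRegistry) -> "GenealogyForest":
        return cls(registry.parent_ids, registry.birth_generations)

    def __len__(self) -> int:
        return len(self.parent_ids)

    def _check(self, oid: int) -> None:
        if not 0 <= oid < len(self):
            raise KeyError(f"unknown origination id {oid}")

    def ancestor_chain(self, oid: int) -> list:
        """Ids from ``oid`` up to its founder, inclusive."""
        self._check(oid)
        cached = self._chains.get(oid)
        if cached is not None:
            return cached
        chain = []
        node = oid
        while node >= 0:
            hit = self._chains.get(node)
            if hit is not None:
                chain.extend(hit)
                break
            chain.append(node)
            node = int(self.parent_ids[node])
        self._chains[oid] = chain
        return chain

    def ancestor_index(self, oid: int) -> dict:
        """Map ancestor id -> the chain node immediately below it (or None)."""
        chain = self.ancestor_chain(oid)
        below: dict = {chain[0]: None}
        for above, child in zip(chain[1:], chain[:-1]):
            below[above] = child
        return below


def common_ancestor_time(
    forest: GenealogyForest,
    id_x: int,
    id_y: int,
    current_generation: int,
    window_t: Optional[int] = None,
) -> Optional[int]:
    """Coalescence time of two allele lineages, or None.

    Time is ``current_generation - divergence_generation`` where the
    divergence generation is the birth of the younger branch node immediately
    below the most recent common ancestor.  Returns None when the lineages
    share no ancestor, or when the time exceeds ``window_t``.
    """
    forest._check(id_x)
    forest._check(id_y)
    if id_x == id_y:
        return 0
    below_x = forest.ancestor_index(id_x)
    mrca = None
    child_y = None
    node = id_y
    while node >= 0:
        if node in below_x:
            mrca = node
            break
        child_y = node
        node = int(forest.parent_ids[node])
    if mrca is None:
        return None
    child_x = below_x[mrca]
    births = [
        int(forest.birth_generations[c]) for c in (child_x, child_y) if c is not None
    ]
    divergence = max(births)  # at least one side has a branch node (id_x != id_y)
    time = current_generation - divergence
    if window_t is not None and time > window_t:
        return None
    return time


@dataclass(frozen=True)
class CoalescenceSummary:
    window_t: int
    n_pairs: int
    fraction_no_common_ancestor: float
    mean_time: float    # over coalescing pairs; NaN if none
    median_time: float
    max_time: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def pairwise_coalescence_times(
    forest: GenealogyForest,
    origin_ids: np.ndarray,
    current_generation: int,
    window_t: int,
):
    """Times and multiplicities over all unordered pairs of allele copies.

    Distinct origination ids are weighted by copy-count products; pairs of
    copies of the same allele coalesce at time 0.  Returns
    ``(times, weights, n_no_ancestor_pairs, n_pairs_total)`` where ``times``
    holds coalescing pairs only.
    """
    flat = np.asarray(origin_ids, dtype=np.int64).ravel()
    if flat.size < 2:
        raise ValueError("need at least two allele copies")
    ids, counts = np.unique(flat, return_counts=True)
    total_pairs = flat.size * (flat.size - 1) // 2
    times, weights = [], []
    no_ca = 0
    within = counts * (counts - 1) // 2
    if within.sum():
        times.append(0)
        weights.append(int(within.sum()))
    for i in range(ids.size):
        for j in range(i + 1, ids.size):
            t = common_ancestor_time(
                forest, int(ids[i]), int(ids[j]), current_generation, window_t
            )
            w = int(counts[i] * counts[j])
            if t is None:
                no_ca += w
            else:
                times.append(t)
                weights.append(w)
    return np.asarray(times), np.asarray(weights), no_ca, total_pairs


def oldest_lineage_age(
    birth_generations, origin_ids: np.ndarray, current_generation: int
) -> int:
    """Age of the oldest origination event still segregating.

    Generations since the birth of the oldest allele (by origination
    identity) present in the population; founders that survive — or fix —
    keep age equal to the elapsed run length, while rapid lineage turnover
    drives the age down.  No pair of current allele copies can coalesce
    deeper than this.
    """
    births = np.asarray(birth_generations, dtype=np.int64)
    ids = np.unique(np.asarray(origin_ids, dtype=np.int64))
    if ids.size == 0:
        raise ValueError("empty population")
    return int(current_generation - births[ids].min())


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(q * w.sum(), cum, v))


def coalescence_summary(
    forest: GenealogyForest,
    origin_ids: np.ndarray,
    current_generation: int,
    window_t: int,
) -> CoalescenceSummary:
    """Coalescence statistics over all pairs of allele copies in a population."""
    times, weights, no_ca, total = pairwise_coalescence_times(
        forest, origin_ids, current_generation, window_t
    )
    if times.size:
        mean = float(np.average(times, weights=weights))
        median = _weighted_quantile(times.astype(float), weights.astype(float), 0.5)
        tmax = float(times.max())
    else:
        mean = median = tmax = float("nan")
    return CoalescenceSummary(
        window_t=int(window_t),
        n_pairs=int(total),
        fraction_no_common_ancestor=no_ca / total,
        mean_time=mean,
        median_time=median,
        max_time=tmax,
    )
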
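"""Jitted inner loop of the encounter phase.

The kernel is deterministic — all randomness (attacker indices) is drawn by
the caller — so its output can be checked exactly against the plain numpy
implementation in :mod:`mhcrq.engine`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encounter_kernel"]


@njit(cache=True)
def encounter_kernel(stacked, attackers, seq_a, seq_b, lut, dominant):
    """Presentation outcomes of one pathogen generation.

    Returns ``(credits, infection_counts)``: per-host fitness credit for this
    pathogen generation and, per (species, pathogen individual), the number
    of hosts attacked and *not* presented.
    """
    n_species, n, n_antigens = stacked.shape
    credits = np.zeros(n, dtype=np.float64)
    counts = np.zeros((n_species, n), dtype=np.int64)
    for s in range(n_species):
        for h in range(n):
            att = attackers[s, h]
            pres_a = False
            pres_b = False
            for a in range(n_antigens):
                x = stacked[s, att, a]
                if lut[x ^ seq_a[h]]:
                    pres_a = True
                if lut[x ^ seq_b[h]]:
                    pres_b = True
                if pres_a and pres_b:
                    break
            if dominant:
                if pres_a or pres_b:
                    credits[h] += 1.0
            else:
                credits[h] += 0.5 * (np.float64(pres_a) + np.float64(pres_b))
            if not (pres_a or pres_b):
                counts[s, att] += 1
    return credits, counts
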
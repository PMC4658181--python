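"""Bit-string MHC-antigen recognition.

An MHC molecule and a pathogen antigen are both fixed-length binary strings
(default 16 bits, standing in for the polymorphic residues of the antigen
binding sites).  An MHC molecule *presents* an antigen when the two strings
agree at a contiguous run of at least ``match_threshold`` aligned positions
(default 7).  A pathogen expressing several antigens is presented as soon as
any one of its antigens is; presenting more than one antigen confers no extra
benefit.

Sequences are stored bit-packed as unsigned integers, most significant bit
first, so that whole populations can be compared with vectorised XOR plus a
precomputed run-detection lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "MatchRule",
    "seq_to_str",
    "str_to_seq",
    "random_sequences",
    "longest_match_run",
    "recognizes",
    "presents_pathogen",
    "random_presentation_probability",
    "motif_count",
    "recognition_lut",
    "presentation_matrix",
    "build_recognition_table",
]


@dataclass(frozen=True)
class MatchRule:
    """Geometry of the recognition rule.

    Parameters
    ----------
    string_length
        Number of bits per MHC molecule / antigen.
    match_threshold
        Minimal length of a contiguous run of agreeing aligned positions
        required for presentation.
    """

    string_length: int = 16
    match_threshold: int = 7

    def __post_init__(self) -> None:
        if self.string_length < 1:
            raise ValueError("string_length must be >= 1")
        if not 1 <= self.match_threshold:
            raise ValueError("match_threshold must be >= 1")

    @property
    def full_mask(self) -> int:
        return (1 << self.string_length) - 1

    @property
    def windows_per_antigen(self) -> int:
        """Number of distinct aligned windows of threshold length."""
        return max(self.string_length - self.match_threshold + 1, 0)


def seq_to_str(seq: int, rule: MatchRule) -> str:
    """Render a packed sequence as a 0/1 string, MSB first."""
    return format(int(seq), f"0{rule.string_length}b")


def str_to_seq(s: str, rule: MatchRule) -> int:
    if len(s) != rule.string_length or set(s) - {"0", "1"}:
        raise ValueError(f"expected a {rule.string_length}-character 0/1 string")
    return int(s, 2)


def random_sequences(rng: np.random.Generator, size, rule: MatchRule) -> np.ndarray:
    """Uniform random packed sequences of the rule's length."""
    return rng.integers(0, rule.full_mask + 1, size=size, dtype=np.uint32)


def _longest_one_run(x: int) -> int:
    run = 0
    while x:
        x &= x >> 1
        run += 1
    return run


def longest_match_run(a: int, b: int, rule: MatchRule) -> int:
    """Length of the longest contiguous run of aligned agreeing bits.

    Symmetric in its arguments; equals ``string_length`` iff ``a == b``.
    """
    for name, s in (("a", a), ("b", b)):
        if not 0 <= int(s) <= rule.full_mask:
            raise ValueError(f"sequence {name} does not fit in {rule.string_length} bits")
    match = (~(int(a) ^ int(b))) & rule.full_mask
    return _longest_one_run(match)


def recognizes(mhc: int, antigen: int, rule: MatchRule) -> bool:
    """True iff the MHC molecule presents this single antigen."""
    return longest_match_run(mhc, antigen, rule) >= rule.match_threshold


def presents_pathogen(mhc: int, antigens, rule: MatchRule) -> bool:
    """True iff at least one antigen of the pathogen is recognized.

    The number of recognized antigens beyond the first carries no weight.
    """
    antigens = np.atleast_1d(np.asarray(antigens))
    if antigens.size == 0:
        raise ValueError("pathogen must express at least one antigen")
    return any(recognizes(mhc, int(ag), rule) for ag in antigens.ravel())


@lru_cache(maxsize=8)
def _recognition_lut_cached(string_length: int, match_threshold: int) -> np.ndarray:
    """Boolean table over all XOR patterns: does ~xor contain a k-run of ones?"""
    if string_length > 24:
        raise ValueError("lookup table limited to string_length <= 24")
    full = (1 << string_length) - 1
    xor = np.arange(full + 1, dtype=np.uint32)
    match = np.bitwise_xor(xor, np.uint32(full))  # agreement indicator
    r = match.copy()
    for _ in range(match_threshold - 1):
        r &= r >> np.uint32(1)
    lut = r != 0
    lut.setflags(write=False)
    return lut


def recognition_lut(rule: MatchRule) -> np.ndarray:
    """Read-only boolean array indexed by ``a ^ b``: presentation of one antigen."""
    return _recognition_lut_cached(rule.string_length, rule.match_threshold)


def presentation_matrix(mhc_seqs, antigens, rule: MatchRule) -> np.ndarray:
    """Vectorised presentation of pathogens by MHC sequences.

    Parameters
    ----------
    mhc_seqs
        Array of packed MHC sequences, shape ``(A,)``.
    antigens
        Packed antigens, shape ``(..., n_antigens)`` — trailing axis is the
        antigen repertoire of one pathogen individual.

    Returns
    -------
    Boolean array of shape ``(A, ...)``: entry ``[i, ...]`` is True iff MHC
    sequence ``i`` presents the corresponding pathogen.
    """
    lut = recognition_lut(rule)
    mhc_seqs = np.asarray(mhc_seqs, dtype=np.uint32)
    antigens = np.asarray(antigens, dtype=np.uint32)
    expand = (...,) + (np.newaxis,) * antigens.ndim
    xor = mhc_seqs[expand] ^ antigens[np.newaxis, ...]
    return lut[xor].any(axis=-1)


def _count_without_run(length: int, k: int) -> int:
    """Number of binary strings of given length with no run of >= k ones."""
    f = [0] * (max(length, k) + 1)
    for n in range(min(k, length + 1)):
        f[n] = 1 << n
    for n in range(k, length + 1):
        f[n] = sum(f[n - j] for j in range(1, k + 1))
    return f[length]


def random_presentation_probability(
    rule: MatchRule, method: str = "recurrence"
) -> Fraction:
    """Exact probability that a random MHC presents one random antigen.

    Aligned positions of two independent uniform strings agree independently
    with probability 1/2, so the probability equals the fraction of binary
    agreement-indicator strings containing a run of at least
    ``match_threshold`` ones.

    ``method`` is either ``"recurrence"`` (run-avoidance recurrence
    ``f(n) = sum_{j=1..k} f(n-j)``) or ``"enumeration"`` (explicit scan of all
    ``2**string_length`` indicator patterns); the two agree exactly.
    """
    length, k = rule.string_length, rule.match_threshold
    total = 1 << length
    if k > length:
        return Fraction(0)
    if method == "recurrence":
        hits = total - _count_without_run(length, k)
    elif method == "enumeration":
        # XOR of two independent uniform strings is itself uniform, so count
        # the favourable entries of the full lookup table.
        hits = int(np.count_nonzero(_recognition_lut_cached(length, k)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return Fraction(hits, total)


def motif_count(rule: MatchRule, antigens_per_pathogen: int) -> int:
    """Total number of threshold-length aligned windows a pathogen offers."""
    if antigens_per_pathogen < 1:
        raise ValueError("antigens_per_pathogen must be >= 1")
    return rule.windows_per_antigen * antigens_per_pathogen


def build_recognition_table(mhc_seqs, pathogen_pops, rule: MatchRule) -> dict:
    """Presentation outcome for every (MHC sequence, species, individual).

    Duplicated MHC sequences collapse to a single row.  The table is exactly
    equivalent to calling :func:`presents_pathogen` for every key; it exists
    so the engine and the summary statistics can share one vectorised pass.
    """
    uniq = sorted({int(s) for s in np.asarray(mhc_seqs).ravel()})
    table: dict = {}
    if not uniq:
        return table
    seqs = np.asarray(uniq, dtype=np.uint32)
    for pop in pathogen_pops:
        pres = presentation_matrix(seqs, pop.antigens, rule)  # (A, N)
        for i, seq in enumerate(uniq):
            for j in range(pres.shape[1]):
                table[(seq, pop.species_id, j)] = bool(pres[i, j])
    return table
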
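"""Per-genome survey tables: top oligomers, HIP1 summary, palindrome-class
scans and HIP-subtracted O/E ratios.

Reverse-complement pairs of k-mers are collapsed to a single entry (the
lexicographically smaller member represents the pair) whose count is the mean
of the two forward counts; palindromes stand alone. Rankings break ties
lexicographically on the representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import numpy as np

from . import _kmers
from .expectation import expected_count, expected_count_order0, oe_ratio
from .sequence import (
    COMPLEMENT,
    GenomeSeq,
    OligoPattern,
    as_pattern,
    count_occurrences,
    strand_collapsed_count,
)

__all__ = [
    "HIP1",
    "OligoStat",
    "top_oligomers",
    "hip_summary",
    "palindromic_hexamers",
    "palindromic_pentamers_ws",
    "degenerate_palindromic_hexamers",
    "CLASS_DEFS",
    "best_in_class",
    "within_hip1",
    "oe_excluding_hip",
]

#: The canonical Highly Iterated Palindrome.
HIP1 = "GCGATCGC"


@dataclass(frozen=True)
class OligoStat:
    """Summary statistics for one (collapsed) oligomer."""

    pattern: str
    count_raw: int
    count_collapsed: float
    count_per_m: float
    expected: float
    model: str
    oe: float
    is_palindromic: bool
    contained_in: Optional[str] = None


def overlaps_reference(pattern: str, reference: str, min_overlap: int = 4) -> bool:
    """True if the oligomer (or its RC) overlaps/contains the reference.

    Overlap means some alignment of the two strings agrees over at least
    ``min_overlap`` positions with no mismatch in the shared window — the
    sense in which 8-mers like CGATCGCC "overlap" HIP1.
    """

    def _aligned(a: str, b: str) -> bool:
        for shift in range(-len(a) + min_overlap, len(b) - min_overlap + 1):
            n = min(len(a), len(b) - shift) - max(0, -shift)
            if n < min_overlap:
                continue
            lo = max(0, -shift)
            if all(a[lo + i] == b[lo + shift + i] for i in range(n)):
                return True
        return False

    rc = as_pattern(pattern).reverse_complement().pattern
    return _aligned(pattern, reference) or _aligned(rc, reference)


def _expected_all(genome: GenomeSeq, k: int, model: str) -> np.ndarray:
    if model == "order0":
        return _kmers.expected_order0_all(genome.length, genome.gc_fraction, k)
    if model == "markov1":
        return _kmers.expected_markov_all(genome, k, 1)
    if model == "markov2":
        return _kmers.expected_markov_all(genome, k, 2)
    raise ValueError(f"unknown model {model!r}")


def top_oligomers(
    genome: GenomeSeq,
    k: int = 8,
    n: int = 12,
    rank_by: str = "oe",
    model: str = "order0",
    reference: Optional[str] = HIP1,
) -> list[OligoStat]:
    """The n most overrepresented k-mers of a genome.

    All ``4**k`` k-mers are counted; RC pairs are collapsed; entries are
    sorted descending by ``rank_by`` ("oe" or "count_per_m") with
    lexicographic tie-breaks, and annotated with ``reference`` when they
    overlap or contain it.
    """
    if not 4 <= k <= 12:
        raise ValueError("k must be in 4..12")
    if rank_by not in ("oe", "count_per_m"):
        raise ValueError("rank_by must be 'oe' or 'count_per_m'")
    spectrum = _kmers.kmer_spectrum(genome, k)
    rc_perm = _kmers.rc_permutation(k)
    collapsed = (spectrum + spectrum[rc_perm]) / 2.0
    expected = _expected_all(genome, k, model)
    # mean of the pair's expectations (identical under order0)
    expected_c = (expected + expected[rc_perm]) / 2.0
    idx = np.arange(4**k)
    canon = np.minimum(idx, rc_perm)
    reps = np.flatnonzero(idx == canon)

    per_m = collapsed * 1e6 / genome.length
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected_c > 0, collapsed / expected_c, np.nan)
    rank_val = oe if rank_by == "oe" else per_m

    vals = rank_val[reps]
    order = sorted(
        range(len(reps)),
        key=lambda i: (-(vals[i] if np.isfinite(vals[i]) else -np.inf), int(reps[i])),
    )
    out: list[OligoStat] = []
    for i in order[: min(n, len(reps))]:
        j = int(reps[i])
        pat = _kmers.decode_index(j, k)
        contained = None
        if reference and overlaps_reference(pat, reference):
            contained = reference
        out.append(
            OligoStat(
                pattern=pat,
                count_raw=int(spectrum[j]),
                count_collapsed=float(collapsed[j]),
                count_per_m=float(per_m[j]),
                expected=float(expected_c[j]),
                model=model,
                oe=float(oe[j]),
                is_palindromic=bool(rc_perm[j] == j),
                contained_in=contained,
            )
        )
    return out


def hip_summary(genome: GenomeSeq) -> dict:
    """HIP1 frequency summary plus the top 8-mer when it is not HIP1.

    Returns hip1_count_per_m, hip1_oe under order0/markov1/markov2, and
    top8_pattern / top8_count_per_m / top8_oe (None when HIP1 itself ranks
    first, following the survey-table convention).
    """
    if genome.length < 10_000:
        raise ValueError("hip_summary requires a genome of at least 10 knt")
    obs = strand_collapsed_count(genome, HIP1)
    summary = {
        "hip1_count_per_m": obs * 1e6 / genome.length,
        "hip1_oe_order0": oe_ratio(obs, expected_count(genome, HIP1, "order0")),
        "hip1_oe_markov1": oe_ratio(obs, expected_count(genome, HIP1, "markov1")),
        "hip1_oe_markov2": oe_ratio(obs, expected_count(genome, HIP1, "markov2")),
        "top8_pattern": None,
        "top8_count_per_m": None,
        "top8_oe": None,
    }
    if obs == 0:
        for key in ("hip1_oe_order0", "hip1_oe_markov1", "hip1_oe_markov2"):
            summary[key] = 0.0
    top = top_oligomers(genome, k=8, n=1, rank_by="oe", model="order0")
    if top and top[0].pattern != HIP1:
        summary["top8_pattern"] = top[0].pattern
        summary["top8_count_per_m"] = top[0].count_per_m
        summary["top8_oe"] = top[0].oe
    return summary


def _self_rc(pattern: str) -> bool:
    return as_pattern(pattern).is_palindromic


def palindromic_hexamers() -> list[OligoPattern]:
    """All 64 nondegenerate palindromic 6-mers."""
    out = []
    for half in product("ACGT", repeat=3):
        left = "".join(half)
        right = "".join(COMPLEMENT[c] for c in left[::-1])
        out.append(OligoPattern(left + right))
    return out


def palindromic_pentamers_ws() -> list[OligoPattern]:
    """All 32 palindromic 5-mer patterns with a W or S central position."""
    out = []
    for half in product("ACGT", repeat=2):
        left = "".join(half)
        right = "".join(COMPLEMENT[c] for c in left[::-1])
        for center in "WS":
            out.append(OligoPattern(left + center + right))
    return out


_TWOFOLD = "RYSWKM"


def degenerate_palindromic_hexamers() -> list[OligoPattern]:
    """Self-reverse-complementary 6-mers with one two-fold-degenerate mirror pair.

    One of the three position pairs (1,6), (2,5), (3,4) carries a two-fold
    IUPAC code (R/Y/S/W/K/M, mirror forced to its complement); the other two
    pairs are concrete: 3 x 6 x 16 = 288 members, e.g. RCCGGY.
    """
    out = []
    for deg_pair in range(3):
        for code in _TWOFOLD:
            for fill in product("ACGT", repeat=2):
                left = [None, None, None]
                it = iter(fill)
                for pos in range(3):
                    left[pos] = code if pos == deg_pair else next(it)
                l = "".join(left)
                r = "".join(COMPLEMENT[c] for c in l[::-1])
                out.append(OligoPattern(l + r))
    return out


CLASS_DEFS = {
    "palindromic6": palindromic_hexamers,
    "palindromic5_center_WS": palindromic_pentamers_ws,
    "degenerate_palindromic6": degenerate_palindromic_hexamers,
}


def within_hip1(pattern: "OligoPattern | str") -> bool:
    """True iff every expansion occurs as a substring of HIP1 (or its RC)."""
    pat = as_pattern(pattern)
    return all(w in HIP1 for w in pat.expansions)


def best_in_class(
    genome: GenomeSeq,
    class_def: "str | Iterable[OligoPattern]",
    model: str = "order0",
) -> dict:
    """The class member with the highest O/E ratio in a genome.

    ``class_def`` is a class name from :data:`CLASS_DEFS` or an iterable of
    patterns (all the same length). Returns pattern, oe and whether the
    winner lies within HIP1.
    """
    members = CLASS_DEFS[class_def]() if isinstance(class_def, str) else list(class_def)
    if not members:
        raise ValueError("empty class")
    k = len(members[0])
    spectrum = _kmers.kmer_spectrum(genome, k)
    rc_perm = _kmers.rc_permutation(k)
    collapsed = (spectrum + spectrum[rc_perm]) / 2.0
    expected = _expected_all(genome, k, model)
    expected_c = (expected + expected[rc_perm]) / 2.0

    best: tuple[float, str] | None = None
    for pat in members:
        if len(pat) != k:
            raise ValueError("class members must share one length")
        ids = [_kmers.kmer_index(w) for w in pat.expansions]
        # members are self-RC patterns: their expansion set is RC-closed, so
        # summing collapsed counts over expansions equals the forward count
        obs = float(collapsed[ids].sum())
        exp = float(expected_c[ids].sum())
        oe = oe_ratio(obs, exp)
        if np.isnan(oe):
            continue
        key = (oe, pat.pattern)
        if best is None or (-key[0], key[1]) < (-best[0], best[1]):
            best = key
    if best is None:
        raise ValueError("no class member has a defined O/E ratio")
    oe_val, winner = best
    return {"pattern": winner, "oe": oe_val, "within_hip1": within_hip1(winner)}


def _substring_occurrences(word: str, sub: str) -> int:
    return sum(1 for i in range(len(word) - len(sub) + 1) if word[i : i + len(sub)] == sub)


def oe_excluding_hip(
    genome: GenomeSeq,
    inner: "OligoPattern | str",
    hip: "OligoPattern | str" = HIP1,
    model: str = "order0",
) -> float:
    """O/E ratio of an inner oligomer with the HIP contribution subtracted.

    Every occurrence of the (concrete) HIP oligomer carries a fixed number of
    inner-oligomer matches; that multiple of the HIP count is removed from the
    observed count (floored at zero) before forming O/E. The expectation is
    left unadjusted: the subtraction removes HIP's contribution to the
    observation only.
    """
    inner_pat = as_pattern(inner)
    hip_pat = as_pattern(hip)
    if hip_pat.degeneracy != 1:
        raise ValueError("hip oligomer must be concrete")
    hip_str = hip_pat.pattern
    rc_hip = hip_pat.reverse_complement().pattern
    rc_inner = inner_pat.reverse_complement()

    def mult(word: str, pat: OligoPattern) -> int:
        return sum(_substring_occurrences(word, w) for w in pat.expansions)

    if mult(hip_str, inner_pat) == 0 and mult(rc_hip, inner_pat) == 0:
        raise ValueError(f"{inner_pat} does not occur within {hip_str}")
    hip_fwd = count_occurrences(genome, hip_pat, "forward")
    fwd = count_occurrences(genome, inner_pat, "forward")
    rev = (
        fwd
        if inner_pat.is_palindromic
        else count_occurrences(genome, rc_inner, "forward")
    )
    if hip_pat.is_palindromic:
        # each physical HIP locus reads hip_str on the forward strand
        adj_fwd = max(fwd - hip_fwd * mult(hip_str, inner_pat), 0)
        adj_rev = max(rev - hip_fwd * mult(hip_str, rc_inner), 0)
    else:
        hip_rev = count_occurrences(genome, hip_pat.reverse_complement(), "forward")
        adj_fwd = max(
            fwd - hip_fwd * mult(hip_str, inner_pat) - hip_rev * mult(rc_hip, inner_pat), 0
        )
        adj_rev = max(
            rev - hip_fwd * mult(hip_str, rc_inner) - hip_rev * mult(rc_hip, rc_inner), 0
        )
    observed = (adj_fwd + adj_rev) / 2.0
    return oe_ratio(observed, expected_count(genome, inner_pat, model))
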
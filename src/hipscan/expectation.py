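"""Expected oligomer counts, O/E ratios, binomial deviation scores and shades.

The order-0 expectation follows the genome-composition formula
``E = L * (gc/2)^(G+C) * ((1-gc)/2)^(A+T)`` with G, C, A, T the base content
of the oligomer; degenerate patterns sum over their expansions. Markov
expectations use the standard sub-word count-ratio estimator with
strand-collapsed count tables.

Deviation from expectation is graded on a log10 binomial-probability scale:
``D = log10 P(E) - log10 P(O)`` with P the binomial pmf (n = genome length,
p = E/L) evaluated by continuous interpolation of the log-pmf, so that
non-integer expected counts are handled. D is >= 0, larger = more deviant;
the sign of enrichment is carried separately. Shades interpolate linearly
between D = 100 (least deviant) and D = 8000 (most deviant), and normalized
counts are filtered at D >= 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sequence import (
    GenomeSeq,
    IUPAC_CODES,
    OligoPattern,
    as_pattern,
    count_occurrences,
    count_per_million,
    strand_collapsed_count,
)

__all__ = [
    "ShadeScale",
    "expected_count_order0",
    "expected_count_markov",
    "expected_count",
    "oe_ratio",
    "deviation_score",
    "shade_category",
    "filtered_count",
]

MODELS = ("order0", "markov1", "markov2")


@dataclass(frozen=True)
class ShadeScale:
    """Thresholds of the log10 binomial-probability shade scale."""

    logpr_extreme: float = 8000.0
    logpr_least: float = 100.0
    filter_logpr: float = 1000.0

    def __post_init__(self) -> None:
        if not self.logpr_extreme > self.logpr_least > 0:
            raise ValueError("require logpr_extreme > logpr_least > 0")


DEFAULT_SCALE = ShadeScale()


def expected_count_order0(length: int, gc: float, pattern: "OligoPattern | str") -> float:
    """Order-0 expected count of a pattern in a genome of given length and GC.

    For a degenerate pattern the sum over expansions factorizes into a product
    of per-position code probabilities. Returned per single strand. ``gc`` of
    0 or 1 yields E = 0 for patterns requiring the absent base class.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    pat = as_pattern(pattern)
    p_base = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    e = float(length)
    for c in pat.pattern:
        e *= sum(p_base[b] for b in IUPAC_CODES[c])
    return e


def _subword_counts(genome: GenomeSeq, words: set[str]) -> dict[str, float]:
    return {w: strand_collapsed_count(genome, w) for w in words}


def expected_count_markov(
    genome: GenomeSeq, pattern: "OligoPattern | str", order: int
) -> float:
    """Markov expected count of a pattern under order 1 or 2.

    For a concrete k-mer w, ``E(w) = prod N(w[j:j+m+1]) / prod N(w[j+1:j+m+1-1])``
    over its (m+1)-windows and internal m-windows, with N strand-collapsed
    observed counts. Degenerate patterns sum over expansions. A zero
    denominator makes the expectation undefined (NaN).
    """
    m = order
    if m not in (1, 2):
        raise ValueError("order must be 1 or 2")
    pat = as_pattern(pattern)
    k = len(pat)
    if k <= m:
        raise ValueError("pattern length must exceed the Markov order")
    words: set[str] = set()
    for w in pat.expansions:
        for j in range(k - m):
            words.add(w[j : j + m + 1])
        for j in range(1, k - m):
            words.add(w[j : j + m])
    tab = _subword_counts(genome, words)
    total = 0.0
    for w in pat.expansions:
        e = 1.0
        ok = True
        for j in range(k - m):
            e *= tab[w[j : j + m + 1]]
        for j in range(1, k - m):
            den = tab[w[j : j + m]]
            if den == 0:
                ok = False
                break
            e /= den
        if not ok:
            return float("nan")
        total += e
    return total


def expected_count(genome: GenomeSeq, pattern: "OligoPattern | str", model: str = "order0") -> float:
    """Expected count under a named null model: order0, markov1 or markov2."""
    if model == "order0":
        return expected_count_order0(genome.length, genome.gc_fraction, pattern)
    if model == "markov1":
        return expected_count_markov(genome, pattern, 1)
    if model == "markov2":
        return expected_count_markov(genome, pattern, 2)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def oe_ratio(observed: float, expected: float) -> float:
    """Observed count divided by expected count; NaN when expected <= 0."""
    if expected is None or not expected > 0 or math.isnan(expected):
        return float("nan")
    return observed / expected


def _log10_binom_pmf(x, n: int, p: float):
    """Continuous-x log10 binomial pmf via log-gamma."""
    x = np.asarray(x, dtype=np.float64)
    ln10 = math.log(10.0)
    return (
        gammaln(n + 1.0)
        - gammaln(x + 1.0)
        - gammaln(n - x + 1.0)
        + x * math.log(p)
        + (n - x) * math.log1p(-p)
    ) / ln10


def deviation_score(c_obs, c_exp, length: int):
    """Magnitude of deviation: D = log10 P(c_exp) - log10 P(c_obs) >= 0.

    P is the binomial pmf with n = genome length and p = c_exp/length,
    interpolated continuously so real-valued counts are handled; the reference
    point is the pmf at the mean (which sits within one count of the mode).
    Accepts scalars or arrays.
    """
    scalar = np.isscalar(c_obs)
    c_obs = np.asarray(c_obs, dtype=np.float64)
    if np.any(c_obs < 0):
        raise ValueError("observed count must be non-negative")
    if length <= 0:
        raise ValueError("length must be positive")
    c_exp = float(c_exp)
    if not c_exp > 0:
        raise ValueError("expected count must be positive")
    p = c_exp / length
    d = _log10_binom_pmf(c_exp, length, p) - _log10_binom_pmf(c_obs, length, p)
    d = np.maximum(d, 0.0)  # mean vs mode differ by < 1 count
    return float(d) if scalar else d


def shade_category(
    c_obs: float, c_exp: float, length: int, scale: ShadeScale = DEFAULT_SCALE
) -> float:
    """Signed shade in [-1, +1]: red (+) for enrichment, green (-) for depletion.

    The magnitude interpolates linearly in D between ``scale.logpr_least``
    (shade 0) and ``scale.logpr_extreme`` (shade 1); D below the least
    threshold is unshaded.
    """
    d = deviation_score(c_obs, c_exp, length)
    span = scale.logpr_extreme - scale.logpr_least
    mag = min(max((d - scale.logpr_least) / span, 0.0), 1.0)
    sign = 1.0 if c_obs > c_exp else (-1.0 if c_obs < c_exp else 0.0)
    return sign * mag


def filtered_count(
    genome: GenomeSeq,
    pattern: "OligoPattern | str",
    scale: ShadeScale = DEFAULT_SCALE,
) -> float:
    """Normalized count, passed only for strong enrichment.

    Returns ``count_per_million`` when the enrichment deviation score reaches
    ``scale.filter_logpr`` (under the order-0 model) and the observed count
    exceeds expectation; otherwise 0. This reproduces the noise filter applied
    to normalized-count displays.
    """
    c_obs = strand_collapsed_count(genome, pattern)
    c_exp = expected_count_order0(genome.length, genome.gc_fraction, pattern)
    if not c_exp > 0:
        return 0.0
    if c_obs > c_exp and deviation_score(c_obs, c_exp, genome.length) >= scale.filter_logpr:
        return count_per_million(genome, pattern)
    return 0.0
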
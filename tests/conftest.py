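"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's counting machinery: they
scan position by position with direct IUPAC set membership, so they can serve
as ground truth for the regex- and spectrum-based implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hipscan.sequence import COMPLEMENT, GenomeSeq, IUPAC_CODES


def naive_forward_count(genome: GenomeSeq, pattern: str) -> int:
    """Position-by-position overlapping match count (forward strand)."""
    k = len(pattern)
    total = 0
    for seq, circ, _off in genome.contigs():
        if len(seq) < k:
            continue
        view = seq + seq[: k - 1] if circ and k > 1 else seq
        for i in range(len(view) - k + 1):
            if all(view[i + j] in IUPAC_CODES[c] for j, c in enumerate(pattern)):
                total += 1
    return total


def naive_rc(pattern: str) -> str:
    return "".join(COMPLEMENT[c] for c in pattern)[::-1]


def naive_count(genome: GenomeSeq, pattern: str, strand: str = "forward") -> int:
    n = naive_forward_count(genome, pattern)
    if strand == "both":
        n += naive_forward_count(genome, naive_rc(pattern))
    return n


def naive_collapsed(genome: GenomeSeq, pattern: str) -> float:
    rc = naive_rc(pattern)
    if rc == pattern:
        return float(naive_forward_count(genome, pattern))
    return (naive_forward_count(genome, pattern) + naive_forward_count(genome, rc)) / 2.0


def naive_markov_expectation(genome: GenomeSeq, word: str, order: int) -> float:
    """Sub-word count-ratio Markov expectation from naive collapsed counts."""
    k, m = len(word), order
    e = 1.0
    for j in range(k - m):
        e *= naive_collapsed(genome, word[j : j + m + 1])
    for j in range(1, k - m):
        den = naive_collapsed(genome, word[j : j + m])
        if den == 0:
            return float("nan")
        e /= den
    return e


def random_genome_str(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_genome():
    g = np.random.default_rng(11)
    return GenomeSeq.from_string(random_genome_str(g, 3000, 0.5), name="small")
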
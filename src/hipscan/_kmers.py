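"""Vectorized k-mer spectra and per-k-mer expected counts.

k-mers are indexed by base-4 codes (A=0, C=1, G=2, T=3, most significant digit
first); windows containing N are excluded; circular contigs include wrap
windows, matching :func:`hipscan.sequence.count_occurrences`.
"""

from __future__ import annotations

import numpy as np

from .sequence import GenomeSeq

BASES = "ACGT"

_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """uint8 codes, 4 for N."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode_index(idx: int, k: int) -> str:
    """k-mer string for a base-4 index."""
    out = []
    for j in range(k):
        out.append(BASES[(idx >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = (idx << 2) | BASES.index(c)
    return idx


def kmer_spectrum(genome: GenomeSeq, k: int) -> np.ndarray:
    """Forward-strand counts of all ``4**k`` concrete k-mers."""
    if not 1 <= k <= 12:
        raise ValueError("k must be in 1..12")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq, circ, _off in genome.contigs():
        if len(seq) < k:
            continue
        view = seq + seq[: k - 1] if circ and k > 1 else seq
        codes = encode(view)
        n = len(codes) - k + 1
        idx = np.zeros(n, dtype=np.int64)
        for j in range(k):
            idx = (idx << 2) | codes[j : j + n]
        bad = (codes >= 4).astype(np.int32)
        badcum = np.concatenate(([0], np.cumsum(bad)))
        valid = (badcum[k:] - badcum[:-k]) == 0
        counts += np.bincount(idx[valid], minlength=4**k)
    return counts


def rc_permutation(k: int) -> np.ndarray:
    """Index permutation mapping each k-mer index to its reverse complement's."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    for j in range(k):
        digit = (idx >> (2 * (k - 1 - j))) & 3
        out |= (3 - digit) << (2 * j)
    return out


def collapsed_spectrum(spectrum: np.ndarray, k: int) -> np.ndarray:
    """Strand-collapsed counts: (count(w) + count(rc(w))) / 2 for every index.

    Palindromic indices are fixed points of the RC permutation, so they keep
    their forward count, matching :func:`hipscan.sequence.strand_collapsed_count`.
    """
    return (spectrum + spectrum[rc_permutation(k)]) / 2.0


def gc_counts(k: int) -> np.ndarray:
    """Number of G+C bases in each k-mer, by index."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros(4**k, dtype=np.int64)
    for j in range(k):
        digit = (idx >> (2 * j)) & 3
        out += (digit == 1) | (digit == 2)
    return out


def expected_order0_all(length: int, gc: float, k: int) -> np.ndarray:
    """Order-0 expected count of every k-mer: L * (gc/2)^(G+C) * ((1-gc)/2)^(A+T)."""
    s = gc_counts(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = float(length) * (gc / 2.0) ** s * ((1.0 - gc) / 2.0) ** (k - s)
    return np.nan_to_num(e, nan=0.0)


def expected_markov_all(genome: GenomeSeq, k: int, order: int) -> np.ndarray:
    """Markov expected counts for every k-mer from sub-word count ratios.

    E(w) = prod_j N(w[j..j+m]) / prod_j N(w[j+1..j+m]) over the k-m windows of
    length m+1 and the k-m-1 internal windows of length m, with N the
    strand-collapsed observed counts. Indices with a zero denominator get NaN.
    """
    m = order
    if m not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if k <= m:
        raise ValueError("k must exceed the Markov order")
    num_tab = collapsed_spectrum(kmer_spectrum(genome, m + 1), m + 1)
    den_tab = collapsed_spectrum(kmer_spectrum(genome, m), m)
    idx = np.arange(4**k, dtype=np.int64)
    mask_num = (1 << (2 * (m + 1))) - 1
    mask_den = (1 << (2 * m)) - 1
    loge = np.zeros(4**k, dtype=np.float64)
    undefined = np.zeros(4**k, dtype=bool)
    with np.errstate(divide="ignore"):
        log_num = np.log(num_tab)
        log_den = np.log(den_tab)
    for j in range(k - m):
        sub = (idx >> (2 * (k - m - 1 - j))) & mask_num
        loge += log_num[sub]
    for j in range(1, k - m):
        sub = (idx >> (2 * (k - m - j))) & mask_den
        zero = den_tab[sub] == 0
        undefined |= zero
        loge -= np.where(zero, 0.0, log_den[sub])
    e = np.exp(loge)
    e[undefined] = np.nan
    return e
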
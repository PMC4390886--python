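"""Genome loading and oligomer counting.

Conventions shared by every downstream stage of the HIP survey:

* coordinates are 0-based, half-open;
* occurrences are counted with overlaps (``AAAA`` contains ``AA`` three times);
* matches never span contig boundaries; a contig flagged circular additionally
  counts matches in the wrap-around window of length ``k - 1``;
* ``N`` in the genome matches nothing, including the pattern code ``N``;
* degenerate patterns use IUPAC one-letter codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from itertools import product
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "COMPLEMENT",
    "OligoPattern",
    "GenomeSeq",
    "FastaError",
    "load_fasta",
    "reverse_complement",
    "count_occurrences",
    "find_occurrences",
    "strand_collapsed_count",
    "count_per_million",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases each matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: IUPAC complementation (A<->T, C<->G, R<->Y, K<->M; S, W, N self-complementary).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_GENOME_ALPHABET = frozenset("ACGTN")


class FastaError(ValueError):
    """Raised for unreadable or malformed FASTA input."""


def _complement_str(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in s)


@dataclass(frozen=True)
class OligoPattern:
    """An oligomer or degenerate IUPAC pattern (e.g. ``GCGATCGC``, ``RCCGGY``)."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty pattern")
        bad = set(pat) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern {self.pattern!r}: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def degeneracy(self) -> int:
        """Number of concrete oligomers the pattern matches."""
        n = 1
        for c in self.pattern:
            n *= len(IUPAC_CODES[c])
        return n

    @cached_property
    def expansions(self) -> tuple[str, ...]:
        """All concrete oligomers matched, in lexicographic order."""
        return tuple(
            "".join(p) for p in product(*(sorted(IUPAC_CODES[c]) for c in self.pattern))
        )

    @cached_property
    def is_palindromic(self) -> bool:
        """True when the pattern equals its IUPAC reverse complement."""
        return self.pattern == self.reverse_complement().pattern

    def reverse_complement(self) -> "OligoPattern":
        return OligoPattern(_complement_str(self.pattern)[::-1])

    @cached_property
    def _regex(self) -> re.Pattern[str]:
        # A character class per position; genome N never matches (no code expands to N).
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
            for c in self.pattern
        )
        return re.compile(f"(?=(?:{body}))")

    def matches_at(self, s: str, pos: int) -> bool:
        """Does the concrete string ``s`` match this pattern at offset ``pos``?"""
        if pos < 0 or pos + len(self.pattern) > len(s):
            return False
        return all(s[pos + j] in IUPAC_CODES[c] for j, c in enumerate(self.pattern))


def as_pattern(pattern: "OligoPattern | str") -> OligoPattern:
    return pattern if isinstance(pattern, OligoPattern) else OligoPattern(pattern)


def reverse_complement(pattern: "OligoPattern | str") -> OligoPattern:
    """IUPAC reverse complement of a pattern."""
    return as_pattern(pattern).reverse_complement()


@dataclass(frozen=True)
class GenomeSeq:
    """A loaded genome: concatenated contigs over ``{A,C,G,T,N}``.

    ``contig_bounds`` are half-open intervals partitioning ``[0, length)``;
    ``circular_flags`` holds one boolean per contig.
    """

    name: str
    residues: str
    contig_bounds: tuple[tuple[int, int], ...]
    circular_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.contig_bounds) != len(self.circular_flags):
            raise ValueError("one circular flag per contig required")
        pos = 0
        for start, end in self.contig_bounds:
            if start != pos or end <= start:
                raise ValueError("contig_bounds must partition [0, length) in order")
            pos = end
        if pos != len(self.residues):
            raise ValueError("contig_bounds do not cover the residues")
        bad = set(self.residues) - _GENOME_ALPHABET
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)}; expected A/C/G/T/N")

    @classmethod
    def from_string(
        cls, residues: str, name: str = "genome", circular: bool = False
    ) -> "GenomeSeq":
        residues = residues.upper()
        return cls(name, residues, ((0, len(residues)),), (circular,))

    @property
    def length(self) -> int:
        return len(self.residues)

    @cached_property
    def gc_fraction(self) -> float:
        """(#G + #C) / (#A + #C + #G + #T); N excluded from both sums."""
        gc = self.residues.count("G") + self.residues.count("C")
        acgt = self.length - self.residues.count("N")
        return gc / acgt if acgt else 0.0

    @property
    def n_contigs(self) -> int:
        return len(self.contig_bounds)

    def contig(self, i: int) -> str:
        start, end = self.contig_bounds[i]
        return self.residues[start:end]

    def contigs(self) -> Iterator[tuple[str, bool, int]]:
        """Yield (sequence, circular, genome-offset) per contig."""
        for (start, end), circ in zip(self.contig_bounds, self.circular_flags):
            yield self.residues[start:end], circ, start

    def reverse_complement(self) -> "GenomeSeq":
        """Reverse-complemented genome (contig order reversed accordingly)."""
        rc = _complement_str(self.residues)[::-1]
        bounds: list[tuple[int, int]] = []
        pos = 0
        for start, end in reversed(self.contig_bounds):
            bounds.append((pos, pos + (end - start)))
            pos += end - start
        return GenomeSeq(
            self.name + "_rc", rc, tuple(bounds), tuple(reversed(self.circular_flags))
        )


# Input characters tolerated in FASTA records: ambiguity codes collapse to N.
_FASTA_MAP = {c: (c if c in "ACGT" else "N") for c in IUPAC_CODES}


def load_fasta(path: "str | Path", circular: bool = False, name: str | None = None) -> GenomeSeq:
    """Load a single- or multi-record FASTA file into one :class:`GenomeSeq`.

    Records are concatenated in file order and their boundaries recorded.
    Lowercase is uppercased; IUPAC ambiguity codes other than A/C/G/T map to N;
    anything else raises :class:`FastaError` naming the record and offset.
    ``circular`` applies to every contig.
    """
    path = Path(path)
    pieces: list[str] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        cleaned = []
        for off, c in enumerate(seq):
            mapped = _FASTA_MAP.get(c)
            if mapped is None:
                raise FastaError(
                    f"illegal character {c!r} in record {record.id!r} at offset {off}"
                )
            cleaned.append(mapped)
        if not cleaned:
            raise FastaError(f"record {record.id!r} has no sequence")
        pieces.append("".join(cleaned))
        bounds.append((pos, pos + len(cleaned)))
        pos += len(cleaned)
    if not pieces:
        raise FastaError(f"no sequence records in {path}")
    return GenomeSeq(
        name or path.stem,
        "".join(pieces),
        tuple(bounds),
        tuple([circular] * len(bounds)),
    )


def write_fasta(genome: GenomeSeq, path: "str | Path", width: int = 70) -> None:
    """Write a genome back out as FASTA, one record per contig."""
    with open(path, "w") as fh:
        for i, (seq, _circ, _off) in enumerate(genome.contigs()):
            label = genome.name if genome.n_contigs == 1 else f"{genome.name}_{i}"
            fh.write(f">{label}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def _scan_views(genome: GenomeSeq, k: int) -> Iterator[str]:
    """Per-contig strings to scan for a length-k pattern (wrap appended if circular)."""
    for seq, circ, _off in genome.contigs():
        if len(seq) < k:
            continue
        yield seq + seq[: k - 1] if circ and k > 1 else seq


def count_occurrences(
    genome: GenomeSeq, pattern: "OligoPattern | str", strand: str = "forward"
) -> int:
    """Overlapping occurrence count of ``pattern`` in ``genome``.

    ``strand="forward"`` counts matches of the pattern as written;
    ``strand="both"`` adds forward matches of the reverse-complement pattern.
    Matches never cross contig boundaries; circular contigs include the
    wrap-around window. Raises if the pattern is longer than every contig.
    """
    pat = as_pattern(pattern)
    k = len(pat)
    if strand not in ("forward", "both"):
        raise ValueError(f"strand must be 'forward' or 'both', got {strand!r}")
    if all(end - start < k for start, end in genome.contig_bounds):
        raise ValueError(f"pattern of length {k} longer than every contig")
    total = sum(len(pat._regex.findall(view)) for view in _scan_views(genome, k))
    if strand == "both":
        rc = pat.reverse_complement()
        total += sum(len(rc._regex.findall(view)) for view in _scan_views(genome, k))
    return total


def find_occurrences(genome: GenomeSeq, pattern: "OligoPattern | str") -> list[int]:
    """Forward-strand start positions (genome coordinates) of pattern matches.

    Wrap-around matches on circular contigs report their start position
    within the contig (i.e. near its right end).
    """
    pat = as_pattern(pattern)
    k = len(pat)
    out: list[int] = []
    for seq, circ, off in genome.contigs():
        if len(seq) < k:
            continue
        view = seq + seq[: k - 1] if circ and k > 1 else seq
        for m in pat._regex.finditer(view):
            if m.start() < len(seq):
                out.append(off + m.start())
    return out


def strand_collapsed_count(genome: GenomeSeq, pattern: "OligoPattern | str") -> float:
    """Strand-collapsed occurrence count.

    A palindromic pattern represents itself: its forward count is returned.
    A non-palindromic pattern represents itself and its reverse complement:
    the arithmetic mean of the two forward counts is returned.
    """
    pat = as_pattern(pattern)
    fwd = count_occurrences(genome, pat, "forward")
    if pat.is_palindromic:
        return float(fwd)
    rev = count_occurrences(genome, pat.reverse_complement(), "forward")
    return (fwd + rev) / 2.0


def count_per_million(genome: GenomeSeq, pattern: "OligoPattern | str") -> float:
    """Strand-collapsed count normalized per million nucleotides of genome."""
    if genome.length == 0:
        raise ValueError("zero-length genome")
    return strand_collapsed_count(genome, pattern) * 1e6 / genome.length
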
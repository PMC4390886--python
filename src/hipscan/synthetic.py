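"""Seeded synthetic genomes with planted signal, for end-to-end testing.

Generators produce i.i.d. background genomes of specified length and GC
fraction and plant, at recorded positions: palindromic oligomers at chosen
densities (the 300–2700 per Mnt range typical of iterated palindromes),
flanking-extension mixtures (a chosen fraction of cores enclosed by a
complementary base pair), and one-off deviant spectra around a consensus.
Each generator returns ground-truth bookkeeping so downstream statistics can
be checked against exactly known inputs. Background occurrences of planted
patterns are not masked; they are reported so total counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from ._kmers import BASES
from .sequence import COMPLEMENT, GenomeSeq, OligoPattern, as_pattern, count_occurrences

__all__ = [
    "generate_genome",
    "plant_pattern",
    "plant_extension_mixture",
    "plant_deviants",
    "SyntheticSpec",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(
    length: int, gc: float, seed: int, name: str = "synthetic", circular: bool = False
) -> GenomeSeq:
    """i.i.d. random genome with P(G) = P(C) = gc/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    residues = _BASE_BYTES[codes].tobytes().decode("ascii")
    return GenomeSeq.from_string(residues, name=name, circular=circular)


def _slot_positions(
    length: int, count: int, item_len: int, min_spacing: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping start positions with pairwise gaps >= min_spacing.

    One item per equal-width slot, jittered within the slack that guarantees
    the spacing; raises if the slots cannot hold the items.
    """
    if count == 0:
        return []
    slot = length // count
    slack = slot - item_len - min_spacing
    if slack < 0:
        raise ValueError(
            f"cannot place {count} items of length {item_len} with spacing "
            f"{min_spacing} in {length} nt"
        )
    jitter = rng.integers(0, slack + 1, size=count)
    return [i * slot + int(j) for i, j in zip(range(count), jitter)]


def _write_at(residues: list[str], pos: int, word: str) -> None:
    residues[pos : pos + len(word)] = list(word)


def plant_pattern(
    genome: GenomeSeq,
    pattern: "OligoPattern | str",
    count: int,
    min_spacing: int = 2,
    seed: int = 0,
) -> tuple[GenomeSeq, dict]:
    """Overwrite ``count`` non-overlapping copies of a pattern into a genome.

    Degenerate patterns plant a uniformly chosen expansion per copy. Returns
    the modified genome and a truth record with the planted positions, the
    planted count, and the total forward occurrence count of the pattern in
    the final genome (planted plus background).
    """
    pat = as_pattern(pattern)
    rng = np.random.default_rng(seed)
    residues = list(genome.residues)
    positions = _slot_positions(genome.length, count, len(pat), min_spacing, rng)
    expansions = pat.expansions
    for pos in positions:
        word = expansions[int(rng.integers(0, len(expansions)))]
        _write_at(residues, pos, word)
    planted = GenomeSeq(
        genome.name, "".join(residues), genome.contig_bounds, genome.circular_flags
    )
    total = count_occurrences(planted, pat, "forward")
    truth = {
        "pattern": pat.pattern,
        "positions": positions,
        "planted": count,
        "total_forward": total,
        "background": total - count,
    }
    return planted, truth


def plant_extension_mixture(
    genome: GenomeSeq,
    core: "OligoPattern | str",
    ext_base: str,
    fraction: float,
    count: int,
    min_spacing: int = 2,
    seed: int = 0,
) -> tuple[GenomeSeq, dict]:
    """Plant cores of which a chosen fraction carry a complementary extension.

    ``round(fraction * count)`` cores are written as
    ``ext_base + core + complement(ext_base)``; the remainder get random
    non-complementary flanking pairs, so the planted extension fraction is
    exact up to rounding.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    pat = as_pattern(core)
    if pat.degeneracy != 1:
        raise ValueError("core must be concrete")
    ext_base = ext_base.upper()
    if ext_base not in "ACGT":
        raise ValueError("ext_base must be one of A/C/G/T")
    rng = np.random.default_rng(seed)
    residues = list(genome.residues)
    item_len = len(pat) + 2
    positions = _slot_positions(genome.length, count, item_len, min_spacing, rng)
    n_ext = round(fraction * count)
    extended_word = ext_base + pat.pattern + COMPLEMENT[ext_base]
    order = rng.permutation(count)
    for rank, pos in zip(order, positions):
        if rank < n_ext:
            word = extended_word
        else:
            while True:
                left = "ACGT"[int(rng.integers(0, 4))]
                right = "ACGT"[int(rng.integers(0, 4))]
                if right != COMPLEMENT[left]:
                    break
            word = left + pat.pattern + right
        _write_at(residues, pos, word)
    planted = GenomeSeq(
        genome.name, "".join(residues), genome.contig_bounds, genome.circular_flags
    )
    truth = {
        "core": pat.pattern,
        "ext_base": ext_base,
        "fraction": fraction,
        "planted": count,
        "extended": n_ext,
        "positions": positions,
    }
    return planted, truth


def plant_deviants(
    genome: GenomeSeq,
    consensus: "OligoPattern | str",
    spectrum: Sequence[float],
    total: int,
    min_spacing: int = 2,
    seed: int = 0,
) -> tuple[GenomeSeq, dict]:
    """Plant exact consensus copies plus per-position one-off deviants.

    ``total`` exact copies are planted; for each position i with target
    fraction f_i, ``round(f_i * total / (1 - f_i))`` copies deviating only at
    i are added, so that the one-off fraction among position-i patterns is
    f_i (up to background). Deviant bases are drawn uniformly from the three
    alternatives.
    """
    pat = as_pattern(consensus)
    if pat.degeneracy != 1:
        raise ValueError("consensus must be concrete")
    m = len(pat)
    if len(spectrum) != m:
        raise ValueError("spectrum length must equal consensus length")
    if any(not 0.0 <= f < 1.0 for f in spectrum):
        raise ValueError("spectrum fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    deviants_per_pos = [round(f * total / (1.0 - f)) for f in spectrum]
    words: list[str] = [pat.pattern] * total
    for i, d in enumerate(deviants_per_pos):
        alts = [b for b in "ACGT" if b != pat.pattern[i]]
        for _ in range(d):
            b = alts[int(rng.integers(0, 3))]
            words.append(pat.pattern[:i] + b + pat.pattern[i + 1 :])
    order = rng.permutation(len(words))
    residues = list(genome.residues)
    positions = _slot_positions(genome.length, len(words), m, min_spacing, rng)
    for pos, j in zip(positions, order):
        _write_at(residues, pos, words[int(j)])
    planted = GenomeSeq(
        genome.name, "".join(residues), genome.contig_bounds, genome.circular_flags
    )
    truth = {
        "consensus": pat.pattern,
        "spectrum": list(spectrum),
        "exact": total,
        "deviants_per_pos": deviants_per_pos,
        "positions": positions,
    }
    return planted, truth


@dataclass
class SyntheticSpec:
    """Declarative recipe for a synthetic genome (YAML-loadable).

    Keys: length, gc, seed, optional lists ``plants`` (pattern, count or
    per_mnt, min_spacing), optional ``extension_mix`` (core, ext_base,
    fraction, count) and ``deviant_spec`` (consensus, spectrum, total).
    """

    length: int
    gc: float
    seed: int
    plants: list[dict] = field(default_factory=list)
    extension_mix: Optional[dict] = None
    deviant_spec: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            length=int(raw["length"]),
            gc=float(raw["gc"]),
            seed=int(raw.get("seed", 0)),
            plants=list(raw.get("plants", [])),
            extension_mix=raw.get("extension_mix"),
            deviant_spec=raw.get("deviant_spec"),
        )

    def build(self) -> tuple[GenomeSeq, list[dict]]:
        """Generate the genome, apply every plant in order, return truths."""
        genome = generate_genome(self.length, self.gc, self.seed)
        truths: list[dict] = []
        sub = 1
        for plant in self.plants:
            count = plant.get("count")
            if count is None:
                count = int(round(plant["per_mnt"] * self.length / 1e6))
            genome, truth = plant_pattern(
                genome,
                plant["pattern"],
                count,
                min_spacing=int(plant.get("min_spacing", 2)),
                seed=self.seed + sub,
            )
            truth["kind"] = "pattern"
            truths.append(truth)
            sub += 1
        if self.extension_mix:
            em = self.extension_mix
            genome, truth = plant_extension_mixture(
                genome,
                em["core"],
                em["ext_base"],
                float(em["fraction"]),
                int(em["count"]),
                min_spacing=int(em.get("min_spacing", 2)),
                seed=self.seed + sub,
            )
            truth["kind"] = "extension_mix"
            truths.append(truth)
            sub += 1
        if self.deviant_spec:
            ds = self.deviant_spec
            genome, truth = plant_deviants(
                genome,
                ds["consensus"],
                [float(f) for f in ds["spectrum"]],
                int(ds["total"]),
                min_spacing=int(ds.get("min_spacing", 2)),
                seed=self.seed + sub,
            )
            truth["kind"] = "deviants"
            truths.append(truth)
        return genome, truths
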
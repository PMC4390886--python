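"""Per-position one-off deviation profiles around a consensus oligomer.

The fraction of sequences deviating from a consensus at position i is

    f_i = (C(N_i) - C(consensus)) / C(N_i)

where N_i is the consensus with position i replaced by N (any base) and C is
the strand-collapsed occurrence count. A sequence deviating at two or more
positions matches no N_i pattern and is not counted — the statistic is a pure
one-off fraction. An optional flanking-context rule restricts the counts to
occurrences whose immediate neighbors satisfy it (e.g. CGATCG occurrences not
preceded by G and not followed by C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .sequence import COMPLEMENT, GenomeSeq, OligoPattern, as_pattern

__all__ = ["ContextRule", "DeviationProfile", "deviation_profile", "context_deviation"]


@dataclass(frozen=True)
class ContextRule:
    """Constraints on the bases immediately flanking an occurrence.

    ``None`` means unconstrained; a required set demands the neighbor be in
    it; a forbidden set excludes those bases. Occurrences at a linear contig
    edge fail any requirement on the missing side but trivially satisfy
    forbidden-only rules.
    """

    left_required: Optional[frozenset] = None
    left_forbidden: frozenset = frozenset()
    right_required: Optional[frozenset] = None
    right_forbidden: frozenset = frozenset()

    def __post_init__(self) -> None:
        for req, forb, side in (
            (self.left_required, self.left_forbidden, "left"),
            (self.right_required, self.right_forbidden, "right"),
        ):
            if req is not None:
                if not req:
                    raise ValueError(f"{side} requirement is empty (contradictory rule)")
                if req <= forb:
                    raise ValueError(f"{side} rule contradictory: required ⊆ forbidden")

    def mirrored(self) -> "ContextRule":
        """The rule seen by the reverse-complement pattern on the forward strand."""

        def comp(s):
            return None if s is None else frozenset(COMPLEMENT[b] for b in s)

        return ContextRule(
            left_required=comp(self.right_required),
            left_forbidden=frozenset(COMPLEMENT[b] for b in self.right_forbidden),
            right_required=comp(self.left_required),
            right_forbidden=frozenset(COMPLEMENT[b] for b in self.left_forbidden),
        )

    def _ok(self, base: Optional[str], required, forbidden) -> bool:
        if base is None:
            return required is None
        if required is not None and base not in required:
            return False
        return base not in forbidden

    def left_ok(self, base: Optional[str]) -> bool:
        return self._ok(base, self.left_required, self.left_forbidden)

    def right_ok(self, base: Optional[str]) -> bool:
        return self._ok(base, self.right_required, self.right_forbidden)

    @classmethod
    def no_gc_flanks(cls) -> "ContextRule":
        """Occurrences NOT preceded by G and NOT followed by C (outside-HIP context)."""
        return cls(left_forbidden=frozenset("G"), right_forbidden=frozenset("C"))


@dataclass(frozen=True)
class DeviationProfile:
    """Per-position one-off deviant fractions from a consensus oligomer."""

    consensus: str
    fractions: tuple[float, ...]  # NaN where undefined / not computed
    counts: tuple[tuple[float, float], ...]  # (deviant, total) per position
    context: Optional[ContextRule] = None

    def __len__(self) -> int:
        return len(self.consensus)


def _forward_count_with_context(
    genome: GenomeSeq, pattern: OligoPattern, rule: Optional[ContextRule]
) -> int:
    if rule is None:
        raise ValueError("use count_occurrences for unrestricted counts")
    k = len(pattern)
    total = 0
    for seq, circ, _off in genome.contigs():
        n = len(seq)
        if n < k:
            continue
        view = seq + seq[: k - 1] if circ and k > 1 else seq
        for m in pattern._regex.finditer(view):
            pos = m.start()
            if pos >= n:
                continue
            if circ:
                left = seq[(pos - 1) % n]
                right = seq[(pos + k) % n]
            else:
                left = seq[pos - 1] if pos > 0 else None
                right = seq[pos + k] if pos + k < n else None
            if rule.left_ok(left) and rule.right_ok(right):
                total += 1
    return total


def _collapsed_count_ctx(
    genome: GenomeSeq, pattern: "OligoPattern | str", rule: Optional[ContextRule]
) -> float:
    from .sequence import strand_collapsed_count

    pat = as_pattern(pattern)
    if rule is None:
        return strand_collapsed_count(genome, pat)
    fwd = _forward_count_with_context(genome, pat, rule)
    rev = _forward_count_with_context(
        genome, pat.reverse_complement(), rule.mirrored()
    )
    return (fwd + rev) / 2.0


def _profile(
    genome: GenomeSeq,
    consensus: str,
    positions: Sequence[int],
    rule: Optional[ContextRule],
) -> DeviationProfile:
    m = len(consensus)
    cons_count = _collapsed_count_ctx(genome, consensus, rule)
    fractions = [float("nan")] * m
    counts = [(float("nan"), float("nan"))] * m
    for i in positions:
        pat = consensus[:i] + "N" + consensus[i + 1 :]
        total = _collapsed_count_ctx(genome, pat, rule)
        deviant = max(total - cons_count, 0.0)
        counts[i] = (deviant, total)
        fractions[i] = deviant / total if total > 0 else float("nan")
    return DeviationProfile(consensus, tuple(fractions), tuple(counts), rule)


def deviation_profile(genome: GenomeSeq, consensus: "OligoPattern | str") -> DeviationProfile:
    """One-off deviation fractions at every position of a concrete consensus."""
    pat = as_pattern(consensus)
    if pat.degeneracy != 1:
        raise ValueError("consensus must be a concrete oligomer (no degenerate codes)")
    return _profile(genome, pat.pattern, range(len(pat)), None)


def context_deviation(
    genome: GenomeSeq,
    core: "OligoPattern | str",
    context: ContextRule,
    positions: Optional[Sequence[int]] = None,
) -> DeviationProfile:
    """Deviation fractions restricted to occurrences satisfying a flank rule.

    ``positions`` defaults to the central pair of the core (the methylation-
    relevant positions); pass an explicit sequence for others. Fractions at
    unrequested positions are NaN.
    """
    pat = as_pattern(core)
    if pat.degeneracy != 1:
        raise ValueError("core must be a concrete oligomer")
    m = len(pat)
    if positions is None:
        positions = (m // 2 - 1, m // 2)
    return _profile(genome, pat.pattern, list(positions), context)
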
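"""Iterative detection of conserved palindromic extensions flanking a core
oligomer.

Starting from a core (HIP1 or another repeated oligomer), each round asks
what fraction of its occurrences are enclosed by a complementary base pair
``x .. core .. comp(x)``. Only complementary flank pairs are tested, since
they preserve the palindromic character of the core. The winning pair is
tiered:

* strong — at least 50% of the enclosed sequences are extended;
* weak — at least 25% are extended and the extension's O/E ratio exceeds 4;
* none — neither rule holds (or the best two bases tie), stopping the search.

Outer rounds use the previously extended sequence as the denominator, which
produces the two-number "(63%, 31%)" style of nested-extension reports. The
encoded string writes strong extensions in uppercase and weak ones in
lowercase around the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .expectation import expected_count_order0
from .sequence import (
    COMPLEMENT,
    GenomeSeq,
    OligoPattern,
    as_pattern,
    strand_collapsed_count,
)

__all__ = ["ExtensionRound", "ExtensionReport", "find_extensions", "MIN_CORE_OCCURRENCES"]

MIN_CORE_OCCURRENCES = 20


@dataclass(frozen=True)
class ExtensionRound:
    left_base: str
    right_base: str
    ratio: float
    oe_extended: float
    tier: str  # "strong" | "weak" | "none"


@dataclass(frozen=True)
class ExtensionReport:
    """Result of the iterative extension search for one concrete core."""

    core: str
    rounds: tuple[ExtensionRound, ...]
    encoded: str
    insufficient: bool = False
    per_expansion: Optional[dict] = None  # set on degenerate cores that disagree

    @property
    def ratios(self) -> tuple[float, ...]:
        """Per-round ratios, inner to outer."""
        return tuple(r.ratio for r in self.rounds if r.tier != "none")


def _classify(ratio: float, oe_extended: float) -> str:
    if ratio >= 0.5:
        return "strong"
    if ratio >= 0.25 and oe_extended > 4.0:
        return "weak"
    return "none"


def _extend_concrete(
    genome: GenomeSeq, core: str, max_rounds: int
) -> tuple[tuple[ExtensionRound, ...], str, bool]:
    count = strand_collapsed_count(genome, core)
    if count < MIN_CORE_OCCURRENCES:
        return (), core, True
    gc = genome.gc_fraction
    length = genome.length
    current = core
    c_current = count
    rounds: list[ExtensionRound] = []
    encoded = core
    for _ in range(max_rounds):
        best: tuple[float, str, float] | None = None
        tied = False
        for x in "ACGT":
            ext = x + current + COMPLEMENT[x]
            c_ext = strand_collapsed_count(genome, ext)
            r = c_ext / c_current if c_current else 0.0
            if best is None or r > best[0]:
                best = (r, x, c_ext)
                tied = False
            elif r == best[0]:
                tied = True
        assert best is not None
        ratio, x, c_ext = best
        ext = x + current + COMPLEMENT[x]
        e = expected_count_order0(length, gc, ext)
        oe_ext = c_ext / e if e > 0 else float("inf")
        tier = "none" if tied else _classify(ratio, oe_ext)
        if tier == "none":
            break
        rounds.append(
            ExtensionRound(
                left_base=x,
                right_base=COMPLEMENT[x],
                ratio=ratio,
                oe_extended=oe_ext,
                tier=tier,
            )
        )
        left = x.upper() if tier == "strong" else x.lower()
        right = COMPLEMENT[x].upper() if tier == "strong" else COMPLEMENT[x].lower()
        encoded = left + encoded + right
        current = ext
        c_current = c_ext
    return tuple(rounds), encoded, False


def find_extensions(
    genome: GenomeSeq, core: "OligoPattern | str", max_rounds: int = 4
) -> ExtensionReport:
    """Search for conserved complementary extensions around ``core``.

    A degenerate core is analysed expansion by expansion; the reports are
    merged into one only when every sufficiently-occurring expansion agrees
    on the extension bases and tiers per round, otherwise ``per_expansion``
    carries the individual reports (the merged fields then describe the first
    expansion with occurrences).
    """
    pat = as_pattern(core)
    if pat.degeneracy == 1:
        rounds, encoded, insufficient = _extend_concrete(genome, pat.pattern, max_rounds)
        return ExtensionReport(pat.pattern, rounds, encoded, insufficient)

    reports: dict[str, ExtensionReport] = {}
    for w in pat.expansions:
        rounds, encoded, insufficient = _extend_concrete(genome, w, max_rounds)
        reports[w] = ExtensionReport(w, rounds, encoded, insufficient)
    informative = [r for r in reports.values() if not r.insufficient]
    if not informative:
        return ExtensionReport(pat.pattern, (), pat.pattern, True, reports)
    keys = {
        tuple((rd.left_base, rd.right_base, rd.tier) for rd in r.rounds)
        for r in informative
    }
    if len(keys) == 1:
        first = informative[0]
        return ExtensionReport(pat.pattern, first.rounds, first.encoded, False, None)
    return ExtensionReport(
        pat.pattern, informative[0].rounds, informative[0].encoded, False, reports
    )
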
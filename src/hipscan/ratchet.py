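"""Stochastic simulator of the G-meC-directed mismatch-repair ratchet.

The model: a methyltransferase (default recognition CGATCG, methylating its
first cytosine) marks sites whose methylated C is immediately preceded by G
on its own strand — a G^meC dinucleotide, the signal read by a hypothetical
MutH-analog nicking enzyme. After each replication, mismatches on the nascent
strand are resolved in precedence order:

(a) a parental methylated site within the repair radius R directs repair
    toward the parent — the mutation is lost (and methylated sites are
    thereby protected from mutation themselves);
(b) otherwise, if the nascent strand with the mutation carries a qualifying
    (pattern + G^meC context) site overlapping or adjacent to the mutated
    position, the MTase wins the race with probability ``p_meth``: the new
    site is methylated, repair is directed toward the daughter, and the
    mutation is fixed;
(c) otherwise the mismatch is resolved at random (fixed with probability 1/2).

Mutations creating new qualifying sites are therefore preferentially fixed —
a unidirectional ratchet — until most of the genome lies within R of a
methylated site, at which point rule (a) freezes further gains. Saturation is
predicted at a mean inter-site spacing on the order of the repair radius.

Methylation is binary and persistent; only the registry of explicitly
methylated sites (planted at initialisation or created by rule (b)) directs
repair — background pattern occurrences are unmethylated until a mutation
adjacent to them triggers rule (b).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kmers import BASES, encode
from .deviation import DeviationProfile, deviation_profile
from .sequence import GenomeSeq, OligoPattern, as_pattern

__all__ = [
    "RatchetParams",
    "RatchetState",
    "StepStats",
    "RatchetTrajectory",
    "init_state",
    "classify_mismatch",
    "step",
    "run",
    "run_to_plateau",
    "trajectory_deviation_spectrum",
]

_G = 2  # base codes: A=0 C=1 G=2 T=3
_C = 1


@dataclass(frozen=True)
class RatchetParams:
    """Configuration of the ratchet simulator.

    mu is the per-site per-generation mutation rate; p_meth the probability
    that the MTase methylates a qualifying nascent-strand site before the
    mismatch is resolved; repair_radius the distance (nt) over which a
    methylated site directs repair; init_site_per_nt the density of
    pre-methylated sites planted in the starting genome.
    """

    length: int = 200_000
    gc: float = 0.5
    circular: bool = True
    mu: float = 1e-4
    p_meth: float = 1.0
    repair_radius: int = 1000
    mtase_pattern: str = "CGATCG"
    meth_offset: int = 0
    generations: int = 20_000
    seed: int = 0
    init_site_per_nt: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1e-2:
            raise ValueError("mu must be in [0, 1e-2]")
        if self.repair_radius < 1:
            raise ValueError("repair_radius must be >= 1")
        if not 0.0 <= self.p_meth <= 1.0:
            raise ValueError("p_meth must be in [0, 1]")
        pat = self.mtase_pattern.upper()
        if not 0 <= self.meth_offset < len(pat):
            raise ValueError("meth_offset outside the pattern")
        if pat[self.meth_offset] != "C":
            raise ValueError("mtase_pattern must have C at meth_offset")
        object.__setattr__(self, "mtase_pattern", pat)


@dataclass
class RatchetState:
    """Parent-strand sequence plus the registry of methylated site starts."""

    seq: np.ndarray  # uint8 base codes
    methylated: list[int]  # sorted forward start coordinates of site windows
    generation: int
    params: RatchetParams

    def to_genome(self, name: str = "ratchet") -> GenomeSeq:
        residues = "".join(BASES[c] for c in self.seq)
        return GenomeSeq.from_string(residues, name=name, circular=self.params.circular)

    def site_count(self) -> int:
        return len(self.methylated)


@dataclass(frozen=True)
class StepStats:
    """Per-generation bookkeeping; fixed + lost equals mismatches drawn."""

    mismatches: int
    lost_parental: int
    fixed_methylation: int
    fixed_random: int
    lost_random: int
    site_count: int
    mean_spacing: float
    median_spacing: float


@dataclass
class RatchetTrajectory:
    params: RatchetParams
    stats: list[StepStats]
    final_state: RatchetState

    def site_counts(self) -> np.ndarray:
        return np.array([s.site_count for s in self.stats])

    def mean_spacings(self) -> np.ndarray:
        return np.array([s.mean_spacing for s in self.stats])

    def equilibrium_spacing(self, tail_frac: float = 0.25) -> float:
        """Mean inter-site spacing over the trailing fraction of generations."""
        tail = self.mean_spacings()[-max(1, int(len(self.stats) * tail_frac)) :]
        return float(np.nanmean(tail))

    def totals(self) -> dict:
        return {
            "mismatches": sum(s.mismatches for s in self.stats),
            "lost_parental": sum(s.lost_parental for s in self.stats),
            "fixed_methylation": sum(s.fixed_methylation for s in self.stats),
            "fixed_random": sum(s.fixed_random for s in self.stats),
            "lost_random": sum(s.lost_random for s in self.stats),
        }


def _pattern_codes(params: RatchetParams) -> tuple[np.ndarray, np.ndarray]:
    pat = as_pattern(params.mtase_pattern)
    fwd = encode(pat.pattern)
    rev = encode(pat.reverse_complement().pattern)
    return fwd, rev


def _qualifies(seq_get, s: int, pat_f, pat_r, k: int, offset: int) -> Optional[str]:
    """Is there a qualifying (pattern + G^meC context) occurrence starting at s?

    Returns "fwd", "rev" or None. ``seq_get(i)`` must return the base code at
    (possibly wrapped) index i. Forward context: G immediately before the
    methylated C at s+offset; reverse context: the rc-pattern occurrence read
    on its own strand has G before its methylated C, i.e. base C at s+k-offset.
    """
    if all(seq_get(s + j) == pat_f[j] for j in range(k)):
        if seq_get(s + offset - 1) == _G:
            return "fwd"
    if all(seq_get(s + j) == pat_r[j] for j in range(k)):
        if seq_get(s + k - offset) == _C:
            return "rev"
    return None


def init_state(params: RatchetParams) -> RatchetState:
    """Random genome with pre-methylated qualifying sites planted.

    Sites are written as G + pattern (the G providing the G^meC context) at
    approximately even spacing, and all planted sites start methylated.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[0])
    L = params.length
    gc = params.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=L, p=p).astype(np.uint8)
    k = len(params.mtase_pattern)
    n_sites = int(round(params.init_site_per_nt * L))
    site_len = k + 1  # context G + pattern
    methylated: list[int] = []
    if n_sites > 0:
        slot = L // n_sites
        if slot < site_len + 1:
            raise ValueError("requested initial site density unachievable without overlap")
        pat_codes = encode(params.mtase_pattern)
        jitter_max = max(slot - site_len, 1)
        for i in range(n_sites):
            pos = i * slot + int(rng.integers(0, jitter_max))
            seq[pos] = _G
            seq[pos + 1 : pos + 1 + k] = pat_codes
            methylated.append(pos + 1)
    return RatchetState(seq=seq, methylated=methylated, generation=0, params=params)


def _near_methylated(ms: list[int], p: int, R: int, L: int, circular: bool) -> bool:
    if not ms:
        return False
    i = bisect.bisect_left(ms, p)
    for j in (i - 1, i % len(ms)):
        d = abs(p - ms[j])
        if circular:
            d = min(d, L - d)
        if d <= R:
            return True
    return False


def classify_mismatch(
    seq: np.ndarray,
    methylated: list[int],
    params: RatchetParams,
    p: int,
    alt: int,
    pat_f: Optional[list] = None,
    pat_r: Optional[list] = None,
) -> tuple[str, Optional[int]]:
    """Deterministic part of mismatch resolution.

    Returns ("parental", None) when a methylated site within the repair
    radius directs repair toward the parent; ("methylation", start) when the
    nascent strand with the mutation carries a qualifying site overlapping or
    adjacent to position p (the p_meth race is decided by the caller);
    ("random", None) otherwise.
    """
    L = params.length
    k = len(params.mtase_pattern)
    offset = params.meth_offset
    circular = params.circular
    if pat_f is None or pat_r is None:
        f, r = _pattern_codes(params)
        pat_f, pat_r = f.tolist(), r.tolist()
    if _near_methylated(methylated, p, params.repair_radius, L, circular):
        return "parental", None

    def get(i: int) -> int:
        i = i % L if circular else i
        if i == p:
            return alt
        if 0 <= i < L:
            return int(seq[i])
        return -1

    for s in range(p - k - 1, p + 3):
        if not circular and (s - 1 < 0 or s + k >= L):
            continue
        which = _qualifies(get, s, pat_f, pat_r, k, offset)
        if which is None:
            continue
        span_lo = s - 1 if which == "fwd" else s
        span_hi = s + k - 1 if which == "fwd" else s + k
        if span_lo - 1 <= p <= span_hi + 1:
            return "methylation", (s % L if circular else s)
    return "random", None


def step(
    state: RatchetState, params: RatchetParams, rng: np.random.Generator
) -> tuple[RatchetState, StepStats]:
    """One replication: draw mismatches, resolve each by rules (a)/(b)/(c).

    Mutates and returns ``state``; resolution of each mismatch sees the
    parental sequence plus that mismatch only (mismatches are independent
    events on the nascent strand), fixed mutations are applied afterwards
    and the methylated-site registry updated.
    """
    L = params.length
    k = len(params.mtase_pattern)
    offset = params.meth_offset
    pat_f, pat_r = _pattern_codes(params)
    pat_f = pat_f.tolist()
    pat_r = pat_r.tolist()
    seq = state.seq
    ms = state.methylated
    circular = params.circular

    n_draw = rng.binomial(L, params.mu)
    positions = np.unique(rng.integers(0, L, n_draw)) if n_draw else np.empty(0, int)
    alts = (
        (seq[positions].astype(np.int64) + 1 + rng.integers(0, 3, len(positions))) % 4
        if len(positions)
        else np.empty(0, int)
    )

    lost_parental = fixed_meth = fixed_random = lost_random = 0
    to_fix: list[tuple[int, int]] = []
    new_sites: list[int] = []

    for p, alt in zip(positions.tolist(), alts.tolist()):
        rule, hit_start = classify_mismatch(seq, ms, params, p, alt, pat_f, pat_r)
        if rule == "parental":
            lost_parental += 1
            continue
        if rule == "methylation" and rng.random() < params.p_meth:
            fixed_meth += 1
            to_fix.append((p, alt))
            new_sites.append(hit_start)
            continue
        # (c) random resolution
        if rng.random() < 0.5:
            fixed_random += 1
            to_fix.append((p, alt))
        else:
            lost_random += 1

    for p, alt in to_fix:
        seq[p] = alt

    if to_fix or new_sites:
        # re-verify registry entries near fixed mutations (relevant only when
        # R is smaller than the site span) and admit the new sites
        def get_final(i: int) -> int:
            i = i % L if circular else i
            return int(seq[i]) if 0 <= i < L else -1

        if to_fix and params.repair_radius <= k + 2:
            changed = {p for p, _ in to_fix}
            kept = []
            for s in ms:
                if any((s - k - 1) <= p <= (s + k + 1) for p in changed):
                    if _qualifies(get_final, s, pat_f, pat_r, k, offset) is None:
                        continue
                kept.append(s)
            ms[:] = kept
        for s in new_sites:
            if _qualifies(get_final, s, pat_f, pat_r, k, offset) is None:
                continue
            i = bisect.bisect_left(ms, s)
            if i == len(ms) or ms[i] != s:
                ms.insert(i, s)

    state.generation += 1
    n = len(ms)
    if n == 0:
        mean_sp = median_sp = float("nan")
    elif n == 1:
        mean_sp = median_sp = float(L) if circular else float("nan")
    else:
        arr = np.array(ms)
        gaps = np.diff(arr)
        if circular:
            gaps = np.append(gaps, L - arr[-1] + arr[0])
            mean_sp = L / n
        else:
            mean_sp = float(gaps.mean())
        median_sp = float(np.median(gaps))

    stats = StepStats(
        mismatches=len(positions),
        lost_parental=lost_parental,
        fixed_methylation=fixed_meth,
        fixed_random=fixed_random,
        lost_random=lost_random,
        site_count=n,
        mean_spacing=mean_sp,
        median_spacing=median_sp,
    )
    return state, stats


def run(params: RatchetParams) -> RatchetTrajectory:
    """Simulate ``params.generations`` replications; reproducible from the seed."""
    state = init_state(params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[1])
    stats: list[StepStats] = []
    for _ in range(params.generations):
        state, s = step(state, params, rng)
        stats.append(s)
    return RatchetTrajectory(params=params, stats=stats, final_state=state)


def run_to_plateau(
    params: RatchetParams,
    block: int = 20_000,
    rel_tol: float = 0.02,
    max_generations: int = 160_000,
) -> RatchetTrajectory:
    """Run at least ``params.generations`` and extend until the site count plateaus.

    After the initial run, generations are added in blocks until the relative
    site-count growth over the last block drops below ``rel_tol`` (or the cap
    is reached). Equilibrium quantities should then be read from the trailing
    generations, e.g. :meth:`RatchetTrajectory.equilibrium_spacing`.
    """
    state = init_state(params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[1])
    stats: list[StepStats] = []

    def advance(n: int) -> None:
        nonlocal state
        for _ in range(n):
            state, s = step(state, params, rng)
            stats.append(s)

    advance(max(params.generations, block))
    while len(stats) < max_generations:
        before = stats[-block].site_count if len(stats) >= block else 0
        now = stats[-1].site_count
        if before > 0 and now <= before * (1 + rel_tol):
            break
        advance(min(block, max_generations - len(stats)))
    return RatchetTrajectory(params=params, stats=stats, final_state=state)


def trajectory_deviation_spectrum(
    state: RatchetState, consensus: str = "GCGATCGC"
) -> DeviationProfile:
    """One-off deviation profile of the evolved genome around a consensus."""
    return deviation_profile(state.to_genome(), consensus)
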
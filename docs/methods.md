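# Methods

## Counting conventions

Occurrences are counted with overlaps, per contig, never across contig
boundaries; a contig flagged circular additionally scans the wrap-around
window of length k−1, so a circular count equals the count on the
doubled-prefix linearization. Coordinates are 0-based half-open. `N` in a
genome matches nothing, including the pattern code `N` — this is
deliberately conservative so degenerate patterns are never inflated by
ambiguous sequence. Degenerate patterns use IUPAC one-letter codes and are
counted as the union of their expansions (the expansions of an IUPAC pattern
are disjoint strings, so the union is a sum).

Strand collapsing reports one number per double-stranded motif: a palindrome
(equal to its reverse complement) counts once; a non-palindrome is reported
as the arithmetic mean of its forward count and its reverse complement's
forward count. All survey tables, extension ratios and deviation profiles
use collapsed counts. One consequence worth knowing: the one-off deviation
profile of a palindromic consensus is symmetrized, because the
reverse complement of "consensus with N at position i" is "consensus with N
at position k+1−i"; a deviant planted only at position 1 therefore surfaces
at half weight at positions 1 and 8 alike. Symmetric spectra — the shape
that matters for HIP analysis — are recovered exactly in expectation.

## Null models

The composition (order-0) expectation is L·(g/2)^S·((1−g)/2)^W with S and W
the strong/weak base counts of the oligomer; for degenerate patterns the sum
over expansions factorizes into per-position code probabilities. The sum of
order-0 expectations over all 4^k k-mers is L for any g.

Markov expectations of order m ∈ {1, 2} use the sub-word count-ratio
estimator E(w) = ∏_{j} N(w_j…w_{j+m}) / ∏_{j} N(w_{j+1}…w_{j+m}), with N the
strand-collapsed observed counts. Collapsed (rather than summed both-strand)
tables are used so that O/E stays calibrated at 1 on i.i.d. genomes when the
observed count is itself strand-collapsed; with summed tables every
expectation would double while observations would not. A zero denominator
makes the expectation undefined (NaN) and the O/E is reported missing rather
than guessed.

## Deviation score and shades

Departure from expectation is graded as D = log₁₀P(c_exp) − log₁₀P(c_obs),
with P the binomial pmf (n = genome length, p = c_exp/n) evaluated through
the log-gamma function as a continuous function of the count, because
expected counts are rarely integers. The reference point is the pmf at the
mean, which sits within one count of the mode; D is clamped at 0 to absorb
the sub-count discrepancy. D is a magnitude — enrichment vs depletion is
carried as a separate sign. Shades interpolate linearly between D = 100
(just visible) and D = 8000 (saturated); normalized counts pass the display
filter only when the enrichment D reaches 1000 under the order-0 model. For
orientation: at L = 10⁶ and an 8-mer expectation of ~15, the filter is
crossed near 780 observed copies per Mnt, so typical HIP densities
(300–2700/Mnt) straddle it and only genuinely iterated sequences pass.

## Survey tables and classes

Top-k-mer tables count all 4^k words via a 2-bit-encoded spectrum, collapse
reverse-complement pairs onto the lexicographically smaller representative,
rank by O/E or count/Mnt with lexicographic tie-breaks, and annotate entries
that overlap a reference oligomer (an aligned mismatch-free window of ≥ 4 nt
against HIP1 or its reverse complement). Under Markov models the pair's two
expectations are averaged, mirroring the averaged observation; under order-0
they are identical.

Three palindrome classes are enumerated exactly: the 64 nondegenerate
palindromic 6-mers; the 32 palindromic 5-mer patterns with a W or S centre
(an odd-length DNA palindrome is only definable with a self-complementary
central code); and 288 degenerate palindromic 6-mers carrying exactly one
mirror pair of two-fold degenerate positions (R/Y, S, W, K/M), the family
containing rCCGGy. A single degenerate character is impossible in a
self-reverse-complementary even-length pattern — degeneracy forces the
mirror position — so "one degenerate pair" is the minimal degenerate class;
wider IUPAC enumeration is avoided because N-heavy patterns would win any
best-in-class scan trivially. "Within HIP1" means every expansion of the
class member is a substring of GCGATCGC.

HIP-subtracted O/E removes, from the observed count of an inner oligomer,
the fixed number of copies contributed by each occurrence of the enclosing
HIP (computed per strand and then collapsed); the expectation is left
unadjusted, since the operation is defined as removing the HIP's
contribution to the *observation*. The subtracted O/E can therefore reach 0
but never exceeds the plain O/E.

## Extension search

Only complementary flank pairs x·S·comp(x) are tested — every convincing
extension of a palindromic core preserves its palindromic character, and
asymmetric motif discovery is out of scope. Rounds proceed outward; the
ratio denominator of an outer round is the count of the inner *extended*
sequence, which is what produces nested two-number reports. A tie between
two best bases stops the search (reported as no extension) rather than
picking arbitrarily. Tier rules: strong at ratio ≥ 0.5; weak at ratio ≥ 0.25
with extended-sequence O/E > 4 under the order-0 model. Cores with fewer
than 20 occurrences are reported as having insufficient data. Degenerate
cores are analysed per expansion and merged only when every informative
expansion agrees on bases and tiers per round. The default of 4 rounds
covers the deepest extensions observed in practice (two rounds beyond an
8-mer core on each side).

## Ratchet simulator

State is the parental strand (a base-code array, circular by default to
avoid edge effects in spacing statistics) plus a registry of methylated site
start positions. A qualifying site is an occurrence of the MTase pattern
(default CGATCG, methylated at its first C) whose methylated C is
immediately preceded by G *on its own strand* — i.e. the pattern preceded by
G, or, reading the complementary strand, followed by C.

Each generation: mismatch positions are drawn binomially at rate mu per
site; the erroneous base is uniform over the three alternatives; each
mismatch is resolved against the pre-replication state in precedence order —

1. a methylated site within the repair radius R directs repair toward the
   parent (mutation lost; this same rule restores any mutation inside a
   methylated site, so methylated sites are immortal while R ≥ their span);
2. otherwise, if the nascent strand with the mutation carries a qualifying
   site overlapping or adjacent (within 1 nt) to the mutated position, the
   MTase wins the race with probability p_meth: the site is methylated and
   the mutation fixed;
3. otherwise random resolution, fixed with probability 1/2.

Fixed mutations are applied and the registry updated incrementally (full
rescans are unnecessary because only mutated windows can change; the
registry invariant is re-verified in tests by independent whole-sequence
scans). The registry holds *explicitly methylated* sites only — planted at
initialisation or created by rule 2. Background qualifying occurrences in
the starting genome are unmethylated; they can be captured later when a
mutation lands next to them and rule 2 fires. Giving parental repair
priority over nascent-strand methylation is the modelling choice that
produces a saturation set point: site gain stops where rule 1 shadows the
genome.

Parameters and defaults: length 200 knt (large enough for ~100–200
equilibrium sites, small enough for second-scale runs), GC 0.5, mu = 1e-4
per site per generation (a simulation convenience, not a biological
estimate; it sets the time scale only), p_meth = 1 (the strongest-ratchet
reference condition), R = 1000 nt (the distance over which mismatch-repair
efficiency falls off in enteric bacteria), initial qualifying sites planted
at 1 per 10 knt (written as G+CGATCG, all methylated). Runs are
deterministic given the seed; the init and step streams are split from one
SeedSequence.

Equilibrium is read after the site count plateaus: runs extend in 20k-
generation blocks beyond the initial 20k until relative site growth per
block falls below 2% (capped at 160k generations). At the defaults the
plateau arrives near 80k generations with a mean inter-site spacing of
roughly 1.45 knt at R = 1000 and roughly 0.75 knt at R = 500 — spacing
scales with the repair radius, and the R = 1000 value lies within a factor
of 2 of the 1/1000-nt density the repair-range argument predicts.
Geometrically the spacing settles between R and 2R: a new site requires a
position farther than R from every methylated site, so gaps stop splitting
once they shrink below ~2R.

The evolved genomes deviate from the full palindrome GCGATCGC
overwhelmingly at positions 1 and 8 (the positions distinguishing the
MTase core from HIP1): accumulated G^meC-anchored 7-mers inflate the one-off
totals at the ends while interior one-offs remain at background.

## Synthetic data

The generators emulate the statistical structure the analyses consume:
i.i.d. background at a chosen GC; planted palindromes at chosen densities
(typical HIP surveys see 300–2700/Mnt); extension mixtures with an exact
extended fraction (non-extended copies get explicitly non-complementary
flanks); and one-off deviant spectra where position i receives
round(f_i·N/(1−f_i)) deviants alongside N exact copies. Placement uses one
item per equal-width slot with jitter bounded so a minimum spacing is
guaranteed; background occurrences are counted, not masked, and reported in
the truth record so downstream tolerances can be set analytically. The
generators do not emulate coding-sequence structure — the triplet-repeat
8-mers that dominate real genomes at low O/E have no counterpart here — nor
GC skew, repeats or mobile elements; passing tests demonstrate correct
recovery of planted signal over an i.i.d. background, not robustness to
every genomic confounder.

## Problem sizes used in the test suite

Brute-force oracle equivalence runs 200 random genome/pattern cases at up to
10 knt; null calibration uses one 5 Mnt i.i.d. genome; planted-signal
recovery 1 Mnt; deviation recovery 300 knt with 2000 planted sites (large
enough that one-off background shifts fractions by well under 0.01);
ratchet equilibria three seeds per radius at the 200 knt reference
conditions. These sizes were chosen so sampling error sits comfortably
inside the stated tolerances while the whole suite stays in the
few-minute range.

## Known limitations

* Expectations ignore the k−1 edge correction on linear contigs (the
  genome-length factor follows the standard composition formula); at survey
  scales the relative error is below 1e-5.
* The binomial deviation score is a display/filter statistic, not an
  inferential p-value; no multiple-testing control is applied or intended.
* The ratchet tracks a single parental strand with binary, persistent
  methylation; hemimethylation dynamics between generations, REase-driven
  site loss, selection and polyploidy are out of scope.
* Whether rule 2 should accept qualifying sites merely adjacent to (rather
  than overlapping) the mutation is not empirically constrained; the
  adjacent-within-1-nt window is a documented choice and the exhaustive
  rule-table test pins its exact semantics.
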
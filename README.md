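# hipscan

Tools for studying **highly iterated palindromes (HIPs)** in bacterial
genomes — above all HIP1, the octamer **GCGATCGC** that occurs hundreds to
thousands of times per million nucleotides in most cyanobacteria — and for
simulating the **G^meC-directed mismatch-repair ratchet**, a mechanistic model
for how such sites could be created and maintained by a DNA
methyltransferase acting at the replication fork.

The package is aimed at comparative genomicists asking: which oligomers in a
genome are overrepresented far beyond composition-based expectation, do they
form palindrome families, are they extended beyond their canonical core, how
do near-miss ("one-off") sequences distribute across positions — and can a
methylation-directed repair bias quantitatively explain the observed site
densities?

## What it computes

**Overrepresentation.** For an oligomer *w* the observed count (strand
collapsed: palindromes count once, a non-palindrome is averaged with its
reverse complement) is compared with a null expectation. The composition
(order-0) null is

    E(w) = L · (g/2)^(S) · ((1−g)/2)^(W)

with *L* the genome length, *g* its GC fraction, *S* and *W* the number of
strong (G/C) and weak (A/T) bases in *w*. First- and second-order Markov
nulls use the standard sub-word count-ratio estimator
E(w) = ∏ N(w_j…w_{j+m}) / ∏ N(w_{j+1}…w_{j+m}). The O/E ratio is graded on a
binomial log-probability scale D = log₁₀P(E) − log₁₀P(O); normalized counts
pass a noise filter only when D ≥ 1000.

**Surveys.** Top-*n* overrepresented k-mers (reverse-complement pairs
collapsed), a HIP1 summary per genome, and best-in-class scans over
palindromic 6-mers, W/S-centred palindromic 5-mers and degenerate palindromic
6-mers (the class containing rCCGGy).

**Extensions.** Iterative detection of conserved complementary flanks
x·core·comp(x): an extension is *strong* when ≥50% of cores carry it, *weak*
when ≥25% do and the extended sequence's O/E exceeds 4 (reported uppercase /
lowercase respectively, e.g. `GGCGATCGCC` vs `gGCGATCGCc`).

**Deviation profiles.** Per-position one-off fractions
f_i = (C(N_i) − C(consensus)) / C(N_i), where N_i is the consensus with an N
at position i — optionally restricted to occurrences whose flanks satisfy a
context rule (e.g. CGATCG not preceded by G nor followed by C).

**The ratchet.** A stochastic simulator of replication with errors, where a
MTase (default CGATCG, methylating its first C) marks sites carrying a G^meC
dinucleotide, and mismatch repair (a) repairs toward the parent within a
radius R of a methylated site, (b) otherwise fixes mutations that create new
qualifying sites (the MTase wins the race with probability p_meth), and
(c) otherwise resolves at random. Site density ratchets upward until most of
the genome is within R of a site, predicting an equilibrium spacing on the
order of R ≈ 1000 nt.

## Worked example

Build a synthetic 1 Mnt genome (GC 0.45) with 1000 planted HIP1 copies and
survey it:

```bash
python - <<'PY'
from hipscan.sequence import write_fasta
from hipscan.synthetic import generate_genome, plant_pattern
g = generate_genome(1_000_000, 0.45, seed=7)
g, truth = plant_pattern(g, "GCGATCGC", 1000, min_spacing=10, seed=8)
print("planted", truth["planted"], "background", truth["background"])
write_fasta(g, "demo.fa")
PY
hipscan survey demo.fa --top 6
```

```
planted 1000 background 13
pattern	count_raw	count_collapsed	count_per_M	expected	oe	within_hip1	shade
GCGATCGC	1013	1013.0000	1013.0000	10.0470	100.8264	True	0.1893
CGATCGCA	299	294.0000	294.0000	12.1587	24.1802	False	0.0234
AGCGATCG	279	290.0000	290.0000	12.1587	23.8513	False	0.0227
CGATCGCG	227	233.5000	233.5000	10.0470	23.2408	False	0.0155
CGATCGCC	208	225.0000	225.0000	10.0470	22.3948	False	0.0141
CAGCGATC	71	80.5000	80.5000	12.1587	6.6208	False	0.0000
```

The planted palindrome ranks first at 1013 copies/Mnt (1000 planted plus 13
background) with O/E ≈ 101 against the composition expectation of ~10; the
next entries are 8-mers overlapping the planted site, exactly the signature
seen around genuine HIP1 loci. `hipscan deviation demo.fa` then shows a flat
one-off profile (~0.02–0.04 per position, pure background), whereas genomes
shaped by the ratchet deviate predominantly at positions 1 and 8.

Running the simulator at reference conditions,

```bash
hipscan ratchet --length 200000 --radius 1000 --seed 1 --out traj.csv
```

prints `# equilibrium mean spacing (last quarter): 1456.3 nt` after the site
count plateaus (138 sites on 200 knt) — the ratchet drives methylated-site
spacing to the order of the repair radius.

Other subcommands: `hipscan extend` (flanking extensions), `hipscan synth`
(YAML-driven synthetic genomes with ground-truth TSV).

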
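# Methods

## Cloning model

Inserts are PCR fragments carrying a 5' enzyme-site tail and a NotI tail at
the 3' end. The default 5' enzyme is NcoI; a gene whose coding sequence
contains an internal NcoI site is cloned with NheI instead, and a gene with
an internal NotI site, or with both NcoI and NheI sites, is rejected as
uncloneable with the built-in pairs. All three built-ins (NcoI `C^CATGG`,
NotI `GC^GGCCGC`, NheI `G^CTAGC`) are palindromic 5'-overhang cutters; the
model reconstructs the ligated plasmid by joining the vector top strand cut
at `site + cut_top` to the insert top strand cut at the same offset, which
regenerates the full recognition site at each joint. Coordinates are
0-based, half-open, forward-strand; circular molecules are indexed modulo
length, and a vector whose site spans the origin is rotated before
digestion. Joint positions are stored as the index of the first base 3' of
the ligation point, so the insert-derived segment is exactly
`seq[left:right]`.

**Junction probes.** Each recombinant yields four probes: left/right joint
× forward/reverse strand, with the reverse probe the exact reverse
complement of the forward one. Flank lengths are constrained to 15–25 bases
per side; the default is 20+20. The range bounds come from the screening
protocol; within it, 20 is the midpoint and gives 40-mers, long enough that
a random match in unrelated sequence is vanishingly unlikely
(4^-40) and short enough to fit many offsets of a 150 b read. If the insert
is shorter than the requested insert flank, the flank shrinks to the
available length but never below 15; below that the probe loses
specificity ("probe collision risk"). Probe uniqueness is enforced across
the whole design at build time: a probe occurring in a second gene's set or
anywhere in the empty circular vector (either strand) is a hard error,
because such a probe would silently mis-assign counts. Inputs are
uppercased; IUPAC ambiguity codes are rejected rather than expanded, since
probes must remain literal strings for counting.

## Read counting

A read supports a gene when one of the gene's four probes occurs in it as a
substring; with `max_mismatches > 0` the match is by Hamming distance at
some offset (no indels). Exact matching is the default: junction extraction
is a presence/absence test of expected sequences, and the mismatch knob
exists for studying sequencing-error sensitivity. Counting rules, chosen
once and applied everywhere:

* one read increments at most one probe per gene — the first match in the
  fixed order left-fwd, left-rev, right-fwd, right-rev;
* a probe occurring twice in one read counts once (the read proves fragment
  identity, not within-read abundance);
* a chimeric read matching two or more genes increments each gene once and
  is tallied in `multi_gene_reads` for QC;
* mates of a pair are counted independently (pair deduplication is
  available via `dedupe_pairs` but off by default, since the statistic is
  defined over reads);
* reads shorter than the longest probe are skipped and tallied;
* base qualities are ignored — no quality filter is part of the method;
* reads are never reverse-complemented; the four-probe design covers both
  strands.

The exact-match path concatenates reads chunk-wise (newline-separated, so a
pure-ACGT probe cannot straddle two reads) and scans each probe with
C-level string search, making million-read FASTQ inputs practical in pure
Python. Counts are order-free sums, so read order never matters.

**Strand-bias diagnostic.** For each gene and joint the ratio
max(fwd, rev)/min(fwd, rev) is reported (∞ if one strand has zero reads,
not-applicable at 0/0); any joint ratio above 10 flags the gene. Short
inserts bias library preparation toward fragments starting on the vector
side, which shows up as complementary-strand imbalances up to a
thousand-fold in ligation samples; flagged genes deserve caution because
their effective joint-read yield is halved.

## Screen statistics

Percentages are per sample: `pct(g) = 100 · joints(g) / total_joints`, so
they sum to 100 and every downstream quantity is invariant to scaling all
counts by a constant. The depletion ratio is `pct_plasmid / pct_ligation`.
Calls use an inclusive threshold of 0.5 ("around or below"), configurable.
Dropout semantics: zero ligation percentage means the gene never entered
the pool, so no ratio exists (reported `NA`, never 0/0 arithmetic); zero
plasmid percentage with a positive ligation percentage is maximal depletion
(ratio 0.0), not a dropout.

Replicates: each plasmid sample is paired with the ligation mixture it came
from; ratios are computed per pair and then aggregated as mean ± sample SD
(n−1; the convention is a package choice — reported SDs at n = 2 are tiny
either way). This matches reporting a per-gene SD over replicate
transformations. A `pool_counts` mode that sums counts per arm before one
ratio is provided for comparison. A gene is a dropout only if absent from
every ligation replicate; replicates where it is present still contribute
ratios. Report rendering uses 2 decimals for percentages and ratios,
switching to 3 decimals for ratios below 0.01 so that extreme depletion is
not rounded to 0.00.

Plating fractions divide each gene's mean CFU by the mean CFU of the
non-toxic control gene (default *g178*) of the same batch; the SD is the
sample SD of per-replicate fractions (each replicate divided by the control
mean). The control's own fraction is 1 by construction; a batch without the
control, or with zero control counts, is an error.

## Simulator

The generator emulates the three stochastic layers of the screen with
deliberately simple models:

* **Ligation efficiency** — per-gene abundance `exp(N(0, σ))`, log-normal
  because efficiencies are positive and multiplicative. The default
  σ = 0.8 reproduces a spread of observed magnitude (roughly 50-fold
  between extremes in a ~10–25-gene pool); σ = 0 is the idealized equimolar
  pool (share 100/n %). No distributional form is claimed by the protocol —
  only the spread is matched.
* **Transformation** — `n_transformants` (default 10^5) cells each draw
  `1 + Poisson(λ)` plasmids from the pool with replacement; a cell survives
  if every plasmid passes its gene's Bernoulli(survival) check or is
  rescued by a co-transformed plasmid listed as its antitoxin (rescue is
  absolute — the simplest model of the verbal hypothesis). Survivors
  contribute all their plasmids. λ defaults to 0; no measured
  co-transformation frequency exists, so λ is an exploration knob, not an
  estimate. Note that rescue alone cannot push a toxin's ratio above 1:
  the ratio is relative, so it exceeds 1 only when the rest of the pool
  shrinks more — e.g. when other, unrescued toxins crash the total, as in
  a control pool where half the genes are toxic.
* **Sequencing** — fragment length `N(625, 311)` truncated at the read
  length (150 b paired-end), start uniform on the circular plasmid, random
  strand, substitution errors at 0.001/base (no indels; at exact matching,
  errors inside a probe window cause undercounting, which is the realistic
  failure mode). With probability `plasmid_side_bias` a joint-overlapping
  fragment is re-anchored so its 5' end sits on the vector side close
  enough that mate 1 reads across the joint — a deliberately strong knob
  that reproduces the direction of the library-prep strand bias, not its
  mechanism.

Synthetic designs use a 3 kb random site-free backbone plus an
NcoI/NheI/NotI multiple cloning site, and random coding sequences of
250–900 b (typical small phage genes) with enzyme tails; a realistic
minority of genes exercises the NheI fallback. All randomness flows from a
single integer seed through spawned `numpy` generators, so pools, FASTQ
bytes (gzip written with zeroed metadata) and reports are bit-identical
across runs.

**What passing simulations do and do not show.** The generator reproduces
unequal ligation shares, hard bottleneck selection, paired-end read
geometry and substitution errors. It does not model outgrowth dynamics,
plasmid copy number, PCR duplicates, GC bias, indels or quality-score
structure; recovery of planted toxins here demonstrates that the statistic
and the pipeline are correct and well-calibrated under the stated model,
not that real libraries are free of those additional effects.

## Problem sizes and numerical choices

Simulation-based checks use 24-gene pools at 10^5 read pairs per arm and
10^5 transformants over 10 seeds — large enough that a neutral pool yields
no candidates (per-gene joint counts of ~10^2–10^3 put 3+ standard errors
between ratio 1 and the 0.5 threshold) while a survival of 0.01 drops a
gene's ratio two orders of magnitude. The rescued-toxin scenario uses 6
genes (5 toxic, one rescued, λ = 3) where the expected rescued ratio is
about 2. Ties and degenerate inputs: empty count tables are an error at the
percentage step ("empty sample"); a single replicate reports SD 0 with a
warning; an all-dropout screen has no summary.

## Known limitations

* Only palindromic 5'-overhang enzymes are modeled; blunt and 3'-overhang
  chemistries are out of scope, as are Gibson/TA cloning and methylation
  sensitivity.
* Exact matching undercounts in proportion to the per-base error rate times
  probe length; use `max_mismatches=1` to quantify.
* Probe uniqueness is checked against the design and vector, not against
  the host genome; contaminating genomic reads that happen to contain a
  probe would be miscounted (40-mer collisions are vanishingly unlikely).
* The screen is a fixed-threshold classifier by design; no p-values or FDR
  control are attached to the calls.
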
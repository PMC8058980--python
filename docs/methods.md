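# Methods

## Codon usage tables

A usage table is a per-codon count vector over the 61 sense codons of the
standard genetic code (Biopython's table 1), built by tallying in-frame
CDS records.  Codons containing N are skipped rather than rejected, so
draft gene sets are usable; off-frame records are hard errors naming the
record.  Stop codons are counted separately: they carry no synonymous-family
weight, and the most frequent stop in the table is the default appended
stop codon for designs.

Derived statistics per synonymous family:

* family frequency f_c = count_c / family total (sums to 1);
* relative adaptiveness w_c = f_c / max f (family maximum is exactly 1);
* RSCU_c = count_c / mean family count (family sum equals the degeneracy;
  undefined and omitted for families with no counts).

Zero-count codons receive a floor weight (`pseudo_floor`, default 0.01) so
the geometric mean underlying CAI stays finite.  The floor is a
conventional regularization for geometric-mean statistics; it only affects
sequences that actually use an unobserved codon.  Weights are invariant
under rescaling all counts, so tables built from different-sized gene sets
are comparable.

RNA input (U) is normalized to T everywhere; output DNA always uses T.
Two table formats are read: the package's own TSV (`codon`, `amino_acid`,
`count`, header required, missing codons = 0) and the widespread
whitespace-delimited "frequency( count )" text layout.

## Sequence metrics

* **CAI** — geometric mean of w over sense codons, computed in log space.
  Single-codon families (Met, Trp) participate with weight 1; this raises
  the absolute value relative to a convention that drops them but cannot
  change the ranking of designs, and is fixed here so scores are comparable
  across runs.  A terminal stop is permitted and excluded; internal stops
  are errors naming the codon position.
* **GC / GC3** — fraction of G+C over all positions or third codon
  positions.
* **Usage distance** — Σ_a (n_a/N) · ½ Σ_{c∈family(a)} |observed fraction −
  f_c|: the amino-acid-composition-weighted total-variation distance
  between the gene's within-family codon choices and the table.  Zero iff
  the gene matches the table's average usage for every amino acid present.
* **Sequence difference** — per-base Hamming distance between equal-length
  designs.

## Design strategies

**HC** back-translates every residue to its family's most-used codon
(alphabetical tie-break, as are all tie-breaks in the package).  On any
table whose required families have counts, the output CAI is exactly 1.0
and the design is deterministic.

**ECO** assigns one of six zones to each codon position (1-based):

| zone | default span | rule |
|------|--------------|------|
| START | 1 | ATG |
| CONSENSUS | 2 | best match to the start-context pattern |
| DESTABILIZED | 3–10 | least-used codon with a nonzero count |
| HEAD_HC | 11–45 | most-used codon |
| MIDDLE | remainder | average-usage matching |
| TAIL_HC | last 50 | most-used codon |

For proteins too short to hold every zone, overlaps resolve by precedence
START > CONSENSUS > DESTABILIZED > TAIL_HC > HEAD_HC > MIDDLE: the 5′ rules
are the most mechanistic (start context and mRNA structure around the
start codon), so they win, and the tail rule is stated unconditionally so
it beats the head span.  An 8-residue protein is therefore START,
CONSENSUS, then six DESTABILIZED positions.

Design choices that were genuinely open:

* *Start context.* The exact consensus differs across references, so the
  pattern is configurable; the default `G**` rewards a G as the first base
  after ATG (the most conserved position of Kozak-type contexts) and scores
  one point per matching non-`*` position, breaking ties by higher usage
  then alphabetically.
* *"Rarely used".* Interpreted as the minimal-nonzero-count codon —
  zero-count codons are excluded as unusable, and a frequency reading
  matches the rule's wording.  A `min_gc` alternative (closer to the
  structure-weakening rationale: AT-rich codons pair more weakly) is
  available behind a flag.
* *Middle region.* Two modes.  `quota` (default) apportions each amino
  acid's n occurrences by largest remainder on n·f_c (remainder ties
  alphabetical) and lays codons down by cycling them in descending-quota
  order, so per-family counts are within 1 of n·f_c deterministically.
  `stochastic` samples each occurrence from the family frequencies under a
  user seed; both modes are bit-stable given their inputs.
* *Stop handling.* The most frequent stop codon is appended by default
  (disable with `--no-stop`); the tail zone is counted over amino-acid
  positions, excluding the stop.

Every design verifies translate(dna) == protein before returning.

## Copy-number genotyping

The genotyper assumes the reference has been augmented with the cassette
sequence, so all integrated copies map to one known region — which is why
no segmentation is needed and a single-region ratio suffices (a deliberate
simplification of general CNV callers, which must first find the region).

Depth is counted in fixed bins (default 200 bp; 100/200/1000 bp compared by
`compare-bins`).  All intervals are 0-based half-open, including
`chrom:start-end` strings on the CLI — note this diverges from the 1-based
samtools region convention.  The baseline is the **median** bin count over
full-width bins outside the cassette: against ~1% of bins at repeat-region
depths, the median moves <2% where a mean would not be robust.  Bins only
partially overlapping the cassette belong to neither the region nor the
baseline; a trailing bin shorter than the bin size is kept, truncated, with
a warning, and excluded from the baseline.

The call is: depth ratio = region mean / baseline; copy estimate = ratio ×
ploidy (default 1, a haploid host); genotype = estimate rounded half away
from zero (6.5 → 7; the rounding rule is stated because conventions
differ).  Profiles with fewer than 10 baseline bins, no fully-contained
region bin, or a zero baseline are rejected as uncallable.

The simulator draws bin counts with mean `mean_bin_depth` outside the
cassette and mean × copies inside (partial-overlap bins pro-rated).
`dispersion` is the variance-to-mean ratio: 1 gives Poisson counts, >1 a
negative binomial with n = μ/(d−1), p = 1/d.  At the default study
conditions (500 kb reference, 5 kb cassette, 200 bp bins, mean depth 40,
Poisson), the region mean over 25 bins has a standard error of ~1.3 counts,
so integer genotypes up to 10 copies are recovered essentially always; the
acceptance script measures this directly.

`fit_copy_titer` is ordinary least squares of titer on copy number
(`scipy.stats.linregress`); R² is the squared Pearson correlation and the
p-value the two-sided slope t-test on n−2 degrees of freedom.  At least 3
strains and non-constant copy numbers are required.

## Synthetic fixtures

`generate_fixtures(seed)` emulates the workflow's inputs end to end:

* 60 CDS (150–450 aa) sampled from per-family Dirichlet codon biases mixed
  with a uniform floor, so every family has counts and every codon keeps a
  usable frequency; the first gene contains all 20 amino acids to guarantee
  family coverage.
* Test proteins of 8, 100, 120 and 300 residues (the 8-mer exercises the
  degenerate zone layout; 120 holds every zone at its default span).
* Depth profiles at 1, 6, 7 and 10 cassette copies — the copy levels of a
  characterized strain panel — at the default simulation conditions.
* A 20-strain copy-number/titer panel with a linear dose-response of
  30 mg/L per copy and 25 mg/L Gaussian assay noise over copies 1–10,
  chosen as a realistic signal-to-noise for a flask-scale terpene assay.

What the fixtures do **not** emulate: real genomes' GC/repeat structure and
mappability variation (depth here is exchangeable across bins, so the
median baseline is never stressed by systematic coverage waves), selection
on codon usage correlated with expression level, amino-acid composition
bias of real proteomes, and any saturation of the dose-response.  Passing
tests therefore demonstrate the correctness of the computations and their
statistical behaviour under the stated generative model, not calling
accuracy on real resequencing data — agreement of the simplified genotyper
with a full CNV caller on real libraries is untested by design.

## Problem sizes and numerical notes

The simulation-based checks use 200 replicates per copy level at copies
{1, 2, 6, 7, 10} (1,000 genomes per check), and the stochastic
middle-region check averages five 10,000-codon draws — at ~500 draws per
family, a single draw's total-variation distance from the target sits near
0.019 ± 0.002, so averaging is what makes the check statistically stable.
Geometric means are computed in log space; apportionment arithmetic is
exact integer; regression tolerances in tests are 1e-10 against closed
forms.  All randomness flows through numpy `default_rng` seeds; nothing
reads the wall clock.
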
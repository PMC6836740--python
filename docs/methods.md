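# Methods

## Model and assumptions

`pollenphase` phases a diploid genome by treating N sequenced haploid pollen
cells as a panel of binary classifiers for long, haplotype-pure fragments.
The model assumes:

* **Biallelic SNPs only.** The two haplotypes differ at point substitutions;
  structural variants and indels between haplotypes are out of scope for
  phasing (the mosaic module handles indels only by excluding gap columns
  from its diagnostic sites).
* **Haplotype-pure fragments.** Each fragment derives wholly from one parental
  haplotype. That holds for BAC clones and good long-read contigs; chimeric
  fragments are partially defended against by the anchoring coverage rule.
* **Gametes are recombinant but otherwise faithful.** Each cell's genome is a
  mosaic of the two parental haplotypes with crossovers; genotype errors from
  whole-genome amplification are modeled as independent allele flips.
* **Dropout is site- and cell-independent.** Each cell observes each SNP site
  independently with its own coverage fraction. Real multiple displacement
  amplification produces spatially correlated dropout and chimeric artifacts;
  neither is simulated (see Limitations).

## Barcodes

For fragment *f* and SNP site *s* on it, cell *c* is encoded as

* 1 if the cell's observed base equals *f*'s base at *s*,
* 0 if it differs **or the site was unobserved** in that cell.

Folding no-calls into 0 is the method's deliberate collapse: it makes every
barcode a total function of the cell panel at the cost of conflating absence
with disagreement. Two safeguards compensate. First, the minimum-support
filter discards SNP rows genotyped in fewer than `min_cells = 2` cells, so a
row is never dominated by a single observation. Second, the tri-state
match/mismatch/no-call matrix and a per-fragment observed-cell mask are kept,
so the optional masked distance (`PhaseParams.masked_distance`) can compare
only mutually observed bits; the default distance reproduces the collapsed
behavior. The fragment consensus bit for cell *c* is the majority over the
non-no-call entries of column *c*; an exact tie breaks to 0 and the bit is
flagged in a low-confidence mask.

Distances between barcodes are hamming distances (XOR, then popcount).
Per-SNP error correction by penalized bit-flipping is deliberately not
implemented; the minimum-support filter plus consensus majorities carry that
weight here.

## Phasing algorithm

The chromosome chain (window `W = 5`, margin `min_margin = 1`,
`min_snps = 3`):

1. Sort anchored fragments by position. Fragments observed in ≤ 1 cell are
   unphased (`single_cell_support`); fragments with fewer than `min_snps`
   retained SNP rows are unphased (`too_few_snps`) — one or two rows cannot
   outvote a single genotype error.
2. The first phaseable fragment's consensus seeds family A; its complement
   seeds family B. The orientation of the labels per chromosome is therefore
   arbitrary, and evaluation always optimizes the orientation per chromosome.
3. Each later fragment joins the family at the smaller hamming distance when
   the margin |d_A − d_B| ≥ `min_margin`, else it is unphased
   (`ambiguous_distance`). Ties never break randomly.
4. The winning family's running barcode is the bitwise majority over its last
   `W` members (window ties keep the previous bit), which lets the family
   barcode drift across crossovers one bit at a time. The other family's
   barcode is maintained from its own members, not forced complementary;
   complementarity is a diagnostic (see below).
5. A second pass re-scores every fragment against the final piecewise family
   barcodes at its own position; assignments that flip between passes are
   demoted to `ambiguous_distance`. This guards against a poorly chosen seed
   fragment.

`PhaseParams.min_top_type_fraction` can additionally unphase fragments whose
most frequent barcode type is rare among their SNP rows. It defaults to **off
(0.0)**: a fragment straddling a crossover of a single cell legitimately
carries two barcode types at comparable frequency (they differ by one bit),
so a frequency gate misfires exactly on the most informative fragments. The
knob remains for noisy real data where heterogeneous barcode types indicate
collapsed repeats rather than recombination.

**Complementarity diagnostic.** At any position the two family barcodes
should be complements. Because each family's track is sampled at its own
member positions and the window majority needs ⌈W/2⌉ members to turn over, a
genuine crossover of cell *c* produces a transient violation at bit *c*
between the two families' updates. The diagnostic therefore reports violating
(position, bit) pairs rather than a boolean; the tests assert that in
noise-free simulations every violation is explained by a true crossover of
the offending cell nearby, and that with no recombination the list is empty.

## Anchoring

Desk-scale anchoring uses canonical k-mers (k = 21, odd, in [11, 31]) instead
of an external aligner: matching k-mer start positions on the fragment are
expanded to k-length intervals and their union length, divided by fragment
length, is the breadth of coverage. A fragment is assigned to the best
chromosome iff coverage ≥ 0.80; exact ties between the two best chromosomes
are reported `ambiguous` rather than guessed (the underlying rule does not
define tie handling, and short fragments inside repeats can legitimately
reach 80% twice). K-mers occurring at more than `max_hits = 10` locations are
dropped from the index so that repeats — more than half of a typical
heterozygous tree genome — cannot dominate the vote. In simulation the index
is built over both haplotypes of the reference under the same chromosome ids;
haplotype identity is never taken from anchoring. Real aligner output enters
as PAF, with the same union-coverage and 80% rules applied per
(query, target) pair. The anchor position estimate is the median of matched
k-mer reference offsets plus half the fragment length (or the target-interval
midpoint for PAF).

## Crossover detection

For cell *c* and chromosome *k*, every phased fragment on which *c* was
observed contributes one track point: phase A when (fragment called A and
consensus bit 1) or (called B and bit 0), else B. Events are switches in the
run-length encoding whose new run persists for ≥ `min_run` informative
points; runs shorter than `min_run` — including terminal runs, whose evidence
cannot be distinguished from noise — are suppressed and adjacent equal runs
merged. `min_run = 2` (default) suppresses single-point flickers from
amplification errors; `min_run = 1` reproduces the literal switch rule with
no smoothing. The event interval is (last point of the old run, first point
of the new run], and the summary reports total events and the mean per
(cell, chromosome) pair. The landscape bins event midpoints by relative
chromosome position and reports the fraction within the outer 20% of each
end (a uniform landscape gives 0.4).

**Resolution.** A fragment's bit for cell *c* is a majority vote over the
fragment's SNP sites, so the track has fragment-scale resolution: a crossover
close to a fragment midpoint can land on either side of it (SNP-count
fluctuations of order sqrt(sites) around the midpoint), a crossover outside
the span of informative fragment midpoints is invisible, and a
double-crossover segment shorter than the fragments covering it never flips
any vote. `pipeline.truth_projected_tracks` makes this exact in simulation:
it projects the ground truth through the same majority votes, defining
precisely which switches are expressed in the observable data. The noise-free
acceptance gate asserts that detected events equal that projection exactly;
the noisy gate asserts that every projected switch is recovered (matching by
interval overlap, which tolerates the one-point boundary shifts the majority
vote permits). Near chromosome ends, where crossovers concentrate, events
beyond the outermost fragment midpoints are undetectable, so the detected
terminal fraction understates the simulated end bias — a property of
fragment-resolution gamete data, not of the detector.

## Mosaic gene classification

Each haplotype copy of a gene is globally aligned to the reference copy with
affine gap penalties (match +1, mismatch −1, gap of length L costs 4 + L;
genes up to 50 kb). Biopython's pairwise aligner provides the dynamic
program; among co-optimal alignments its deterministic first traceback is
used, and the tests pin the score to an independent exhaustive oracle.
Reference positions where the aligned A and B bases are both present and
differ are diagnostic sites (`MATCHES_A` / `MATCHES_B` / `NEITHER` by the
reference base); indel-only columns are not diagnostic. Classification:

* no diagnostic sites → `identical_AB`;
* NEITHER sites strictly more than half of all sites → `unresolved` (such
  genes match neither haplotype, as a minority of validated loci do);
* both haplotypes matched at ≥ `min_sites` (default 1) each → mosaic, with
  the minority haplotype's sites as the errors: any exonic minority site
  makes it `mosaic_exon`, else `mosaic_intron` (exon takes precedence because
  exonic errors are the ones that corrupt gene models);
* otherwise consistent with the single matched haplotype.

A count tie takes the segment entered at the first switch as the minority —
deterministic, and symmetric in everything except the tie itself.

## Simulator

The generator's defaults are the study conditions: heterozygosity 1.02%
(per-base Bernoulli, so SNP counts are Binomial(L, 0.0102)); 12 cells;
per-cell breadth of coverage uniform on (0.50, 0.78) — the reported per-cell
range with its median near 66%; genotype error 1e-3 per observed call
(amplification error is not quantified in the source data; the rate is a
config knob and every simulated error is flagged in truth); Poisson(1.3)
crossovers per chromosome per gamete with positions from a symmetric
Beta(0.5, 0.5) scaled to chromosome length, a minimal density with the
observed concentration at chromosome ends; fragments 10–120 kb, chromosome
chosen proportional to length, haplotype by fair coin. No obligate crossover
is enforced, no crossover interference or gene conversion is modeled, and
dropout carries no spatial correlation or copy-number bias. Coordinates are
0-based half-open, forward strand.

Gene triplets for the mosaic module are generated separately
(`simulate_gene_triplets`): 3 kb genes with three exons covering 40%, the
same heterozygosity, and a class mix of consistent-A/consistent-B/identical/
mosaic; mosaic references splice an A-prefix to a B-suffix at a uniform point
in the middle half. Truth labels derive from the realized construction, not
the drawn intent (a splice with no differing site on one side is truly
consistent).

What passing the simulated gates does **not** show about real data: robustness
to correlated dropout, chimeric amplification products, collapsed repeats
that defeat anchoring, mapping and SNP-calling errors, or haplotype-impure
fragments. The simulator's scope is the barcoding/phasing/crossover/mosaic
logic itself.

## Problem sizes and numerical choices

The test and acceptance runs use 2 chromosomes at desk scale: 200 kb with 300
fragments and full coverage for the exact-recovery gate (fragment midpoints
every ~1.3 kb), and 1 Mb with 300 fragments for the noisy robustness gate
(midpoints every ~6.7 kb, comfortably above the SNP-count noise window of
roughly ±1 kb within which a fragment's majority vote near a breakpoint can
go either way — that is also why event matching allows one informative point
of slack). Ten fixed seeds drive the robustness gate; the accuracy criterion
is the mean over seeds. All randomness flows from numpy `default_rng` seeded
per stage, so every artifact is bit-reproducible from its config.

## Known limitations

* Phasing of unanchored fragments (e.g. by overlap chaining) is out of scope;
  they are reported `UNPHASED(unanchored)`.
* The greedy chain is order-dependent by design; the second pass removes the
  seed-fragment dependence but a pathological fragment ordering with margin 1
  can still unphase borderline fragments rather than mis-assign them (ties
  always fall toward UNPHASED).
* Crossover intervals are bounded by fragment midpoints, not SNPs; breakpoint
  localization is fragment-scale.
* The mosaic aligner is quadratic; genes beyond 50 kb are rejected rather
  than banded.
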
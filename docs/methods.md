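# Methods

`cobarscaf` orders and orients the contigs of a draft assembly using the
co-barcoding information of a synthetic-long-read (SLR) library — stLFR-style
data in which short reads carry the barcode of the long DNA fragment they
were sampled from — then refines the scaffolds locally with paired-end links
and converts linkage strength into gap sizes.  This note describes the model,
the parameters that matter, the synthetic data the package tests itself on,
and the numerical choices behind the implementation.

## Scaffolding model

Reads sharing a barcode come from one long fragment (ideally exactly one per
barcode, as in stLFR with its ~50 million bead barcodes).  When a fragment
overlaps two contigs, uniquely mapped reads with its barcode appear on both,
so the set of shared barcodes measures physical proximity: the expected
number of fragments spanning two loci, and hence the statistical correlation
of their barcode sets, decreases monotonically with their genomic distance.
The pipeline uses this signal at three scales, always from global to local:

1. **ordering** of long "seed" contigs on a genome-wide scaffold graph,
2. **orienting** each contig within its ordered scaffold,
3. **local scaffolding** of the remaining short contigs into gaps using
   paired-end links, followed by **gap size estimation**.

### Correlation statistic

The correlation between contigs *m* and *n* is the maximal Jaccard
similarity over pairs of fixed-size bins, one from each contig:

    JS(m, n) = max_{i,j} |B(bin_i^m) ∩ B(bin_j^n)| / |B(bin_i^m) ∪ B(bin_j^n)|

where `B(·)` is the set of barcodes of uniquely aligned reads starting in a
bin.  Taking the maximum over fixed-size bins removes the dependence of the
raw shared-barcode count on contig length, and the Jaccard normalisation
suppresses the depth fluctuations of randomly sheared fragments.  Bins
(default 5 kb) are chopped from both ends of a contig toward the middle with
no gap or overlap; the remainder shorter than one bin is kept as a short
middle bin by default so that the union of bin sets conserves the contig's
barcode set (a flag drops it).  Bin pairs whose barcode union is below
`min_barcode_union` (default 10) contribute JS = 0 — a ratio of two tiny
counts carries no usable ranking information.

An optional MinHash-style speed-up subsamples the barcode universe: each
barcode receives a keyed 64-bit hash and the `minhash_ratio` fraction with
the smallest hashes is kept, identically in every bin, so sampled JS remains
a consistent estimator of full JS.  Ratio 1 reproduces exact JS bit for bit.

### Data preparation

Only reads with a unique alignment provide barcodes.  "Unique" is
operationalised as primary alignment with mapping quality ≥ `mapq_min`
(default 30); a flag switches to XA-tag-based multi-hit detection instead,
since aligners differ in how they expose multi-mapping.  Reads carrying the
null barcode sentinel (`0_0_0`) are excluded from barcode indexing but still
contribute paired-end links.

Seed contigs are long (≥ `seed_min_length`, default 7 kb) and depth-typical:
per-contig depth is (unique reads × read length) / contig length, and seeds
must fall inside `depth_window` (default [0.5, 1.5]) times the mean depth of
long contigs.  The window removes collapsed repeats (inflated depth) and
junk contigs (depleted depth); the mean is computed over long contigs only
so short fragmented contigs do not drag it down.

### Ordering

Seeds become nodes of an undirected scaffold graph with an edge wherever
JS exceeds `js_threshold` (default 0.1), weighted by JS.  Because higher JS
means closer, each component's *maximum*-JS spanning tree is computed with
Prim's algorithm (equivalently, a minimum spanning tree on 1 − JS).  On
three adjacent contigs this deletes the weakest of the three correlations —
the non-adjacent pair — which is the elementary ordering move.

Tree nodes are classified by degree: tip (1), linear (2), junction (> 2).
A branch walks from a junction through linear nodes until a tip or another
junction; a branch ending at a tip with fewer than three nodes is a *tip
branch*, anything else is *long*.  A junction with more than two long
branches is a *long junction*; any other junction is a *tip junction*.

Long junctions are strongly associated with misassembled (chimeric) or
repetitive seeds, which attract spurious edges from several genomic
neighbourhoods at once.  The screening pass iterates: build the spanning
forest, classify, delete all long-junction *nodes* from the graph, rebuild —
until no long junction remains, an iteration cap (default 5) is hit, or the
cumulative removed fraction of seeds would exceed `screen_removal_ratio_cap`
(default 0.02, protecting connectivity).  When the budget cannot cover all
long junctions, the worst (most long branches, then highest degree) go
first.  Afterwards tip branches are pruned to a fixed point — pruning can
merge a junction into a path and expose new tip branches, so the pass
repeats; pure-path components are never touched.  The branches of the final
forest become ordered scaffolds; junction nodes and singletons emit as
single-contig scaffolds, and screened/pruned seeds join the unscaffolded
pool.

Determinism: Prim starts each component at its lexicographically smallest
node and breaks weight ties by the lexicographically smallest (inside,
outside) node pair, so identical inputs give identical trees.

### Orienting

Each contig is split at its midpoint into a head (5′ half) and tail, and
each of up to `orient_window` (default 3) neighbours per side casts a vote:
a preceding neighbour supports the *up* state (same direction as the
scaffold) when JS(head, neighbour) > JS(tail, neighbour), and a following
neighbour supports it for the reversed comparison.  The majority of
non-abstaining votes decides; exact ties (including singletons) default to
up with a low-confidence flag, preserving contiguity while letting
downstream users mask those contigs.

The neighbour votes with its pooled barcode set rather than one of its
halves.  The decision is carried by the *target's* head/tail asymmetry, and
pooling makes the vote exactly antisymmetric under reversing the scaffold:
reversing the order flips every non-tie orientation, which is the defining
property of an orientation that is relative to its scaffold.  Votes are
unweighted.

### Local scaffolding

The unscaffolded pool (non-seeds, pruned tips, screened seeds) is inserted
into scaffold gaps using paired-end evidence.  Assuming a forward–reverse
library, a forward read points off its contig's tail and a reverse read off
its head, so a read pair spanning two contigs implies which ends face each
other; reads farther than `pe_max_end_distance` (default 1000 bp) from the
implied end are ignored.  Aggregated junctions supported by at least
`pe_min_support` (default 3) pairs become directed links.

For each gap, pool contigs with JS ≥ `candidate_js_threshold` (default half
of `js_threshold`) to either flank are candidates — the co-barcoding filter
keeps the local graph small and repeat-safe.  A depth-first search
enumerates simple paths from the left flank's exit end to the right flank's
entry end over (contig, orientation) states, up to `max_path_nodes`
intermediates; the fewest-node path wins, ties broken by total support, then
lexicographically.  A direct flank-to-flank link confirms the gap without
insertion.  Scaffolds are processed in descending span order and gaps left
to right; an inserted contig leaves the pool, so no contig is placed twice,
and flanking contigs are never reordered or reoriented.

### Gap size estimation

The JS–distance relation is calibrated on the input assembly's own long
contigs, where intra-contig bin-pair distances are known (a standalone tool
has no reference genome to calibrate against).  Bin pairs are bucketed by
centre-to-centre distance; bucket means are fitted with an ordinary
least-squares line over the range where they are strictly decreasing and
above a noise floor, and the line is inverted to map an edge's JS to a
distance.  Subtracting the distance from each best bin's centre to the
contig end facing the gap converts centre-to-centre distance into a gap,
clamped to [`gap_min`, `gap_max`].  JS above the invertible band means
"closer than resolvable" (`gap_min`); below it, `gap_max`.

Numerical choices, all visible in the calibration dump:

- `calib_bucket_width` defaults to the bin size.  Because bins are chopped
  from both contig ends, bin-pair distances concentrate on multiples of the
  bin size; finer buckets alternate between well-populated and nearly empty,
  and the near-empty ones carry only sampling noise.  Buckets with fewer
  than `min_pairs_per_bucket` (100) pairs are skipped outright.
- `calib_max_distance` defaults to 50 kb, the fragment-length scale.  The
  underlying decay is approximately exponential with a scale of roughly
  half the fragment mean, so a straight line can only represent it over
  about one fragment length; beyond that the relation flattens into noise.
- After the first fit the invertible band is trimmed: the line is trusted
  only where its residual is below half a bucket of distance-equivalent
  (|slope| × bucket/2), and the fit is repeated once on the trimmed range.
  The model's `js_lo`/`js_hi` report exactly the band where inversion is
  claimed.
- When no contig is long enough to calibrate at any scale (the pipeline
  halves `calib_max_distance` until it gives up), co-barcode gaps fall back
  to `default_gap_size` (100 bp).

Junctions established by paired-end evidence alone receive a fixed 11 bp
gap: with ~350 bp inserts the method cannot resolve such gaps any further,
so a uniform small constant is assigned.

## Synthetic data

The simulator generates the full study system: a uniform random genome; a
draft assembly cut from it (lengths ~ Normal(mean, 0.3 × mean) clipped at a
minimum, each contig reverse-complemented with probability 0.5, shuffled and
renamed); barcoded fragments; and read pairs, emitted directly as an
alignment table through the truth map (the aligner-free path that all tests
use), optionally as FASTQ with stLFR-style `name#barcode` read names.

Reference conditions (the package defaults): 2 Mb genome, ~200 contigs of
mean 10 kb, fragments of mean 50 kb at 10× physical coverage, exactly one
fragment per barcode, 100 bp reads.

Choices where the study conditions left the design open:

- **Fragment lengths** are gamma(shape 3, mean 50 kb), modelling
  size-selected high-molecular-weight DNA: the distribution is broad
  (CV ≈ 0.58) but does not put most of its mass on very short fragments the
  way an exponential would.
- **Read density** defaults to 2.0 pairs per kb of fragment.  This is a
  scaled-down design decision: a real stLFR library pairs far higher
  fragment coverage (hundreds-fold) with sparser per-fragment sampling
  (~0.4 pairs/kb, one read every ~2.5 kb).  Scaling the fragment count down
  ~90-fold while keeping per-fragment sparsity would leave the library at
  sub-1× read coverage, where the paired-end stage cannot operate at all.
  Instead each simulated fragment is sampled densely enough that its
  presence in every 5 kb bin it overlaps is detected with probability ≈ 1,
  making each of the few fragments fully informative; the remaining JS
  noise is fragment-placement noise, which the fixed 10× physical coverage
  controls.  Genome read coverage ends up at ~4×.
- **Insert sizes** are a mixture of a narrow Normal(350, 35) mode and a 20%
  lognormal tail capped at 3 kb — non-Gaussian and long-tailed, with the
  mode matching the observed ~250 bp distance between sorted mate positions
  at 100 bp reads.
- **Chimeras** (misassembled contigs) concatenate two distant intervals,
  possibly on opposite strands, consuming both; **collapsed repeats** merge
  a contig with a distant same-length donor interval whose reads map onto
  it, doubling its apparent depth.  Truth records both source intervals.

What the simulator does *not* model: sequencing errors, PCR duplicates,
barcode collisions beyond the fragments-per-barcode setting, chimeric read
pairs, GC bias, or an assembler's actual error modes.  Passing tests on this
data show the algorithms recover order/orientation/structure from ideal
co-barcoding signal at scaled-down coverage; they do not certify performance
on real libraries, where alignment artefacts and library non-uniformity add
error modes the simulator omits.

## Evaluation

Adjacent contig pairs in output scaffolds are classified against the truth
map by the number of (non-chimeric) contigs lying strictly between their
genome intervals: 0 → 1-order, 1 → 2-order, ≥ 2 → high-order; any pair
touching a chimeric contig is an error edge.  Orientation accuracy is
measured after normalising each scaffold by the global flip that maximises
agreement — orientation is only defined relative to the scaffold.  NG50 is
computed against the known genome size.  These truth-map classes stand in
for reference-alignment-based misassembly calling, which is out of scope.

## Known limitations

- At 10× fragment coverage the orientation signal is carried by fragments
  with an endpoint inside the target contig (~2 expected per 10 kb contig);
  when none exists, head and tail barcode sets coincide and every vote
  abstains.  Across seeds, orientation accuracy on the reference conditions
  ranges roughly 0.91–0.99; real libraries with far deeper physical
  coverage do not sit near this floor.
- Ordering accuracy is likewise seed-dependent (~0.95–0.98 of adjacent
  output pairs within 2-order of truth at the reference conditions).
- The linear JS–distance model is a local approximation of an exponential
  decay; gaps outside its invertible band are clamped rather than
  extrapolated.
- Screening is budgeted at 2% of seeds; with much higher misassembly rates
  it removes only the worst junctions.
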
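# Methods

## The measurement problem

A targeted repeat amplicon has the structure
`upstream_flank + unitᵏ + downstream_flank`, with `unit = GAA` for the
frataxin locus. Two properties of real data drive the design here:
per-molecule repeat counts vary within one individual (somatic mosaicism),
so a sample yields a *distribution* of counts per allele rather than a
single number; and long-read platforms introduce percent-scale indel
error, so single-read counts and single-read sequence are both noisy.
Every stage is therefore built around aggregation: modes over read-count
histograms for sizing, majority votes over aligned reads for sequence,
and cross-strand agreement for interruption calls.

## Per-read counting

Orientation and tract location use the `k` flank bases adjacent to the
repeat on each side ("anchors", default `k = 30`), placed by infix edit-
distance alignment (edlib) in both the read and its reverse complement;
the orientation with the larger summed anchor identity wins. The count is
`round((inner_anchor_gap) / 3)`, rounded half-up. Counting from the tract
*span* instead of walking GAA motifs makes the count insensitive to
substitutions inside the tract; only indels move it, by ±1 unit per 3 bp
of net length change.

Defaults: anchor length 30 bp and minimum mean anchor identity 0.80. At
the 10% total error ceiling the expected anchor identity is ≈ 0.90, while
the best chance placement of a 30-mer in an unrelated sequence sits far
below 0.80, so the threshold separates real amplicon reads from junk with
a wide margin on both sides. Both values are exposed as flags. Reads
containing N are handled by treating N as a mismatch everywhere.

## Mode-based biallelic genotyping

The allele estimate is the repeat length with the most supporting reads
in its region of the histogram. At expanded lengths (~1000 units) with
mosaicism SD ~10 units, the raw integer histogram of 50–100 reads is
sparse and its argmax is unstable, so the caller:

1. builds the integer histogram at bin width 1;
2. smooths it with a centred moving **sum** of width 5 (an odd width keeps
   the window symmetric; a sum rather than a mean keeps supports integral);
3. takes the smoothed argmax as allele A's region, reporting the raw mode
   inside that window — on clean data (e.g. 500 reads all at 8) smoothing
   therefore changes nothing;
4. masks all counts within 50 units of allele A and repeats the search;
   the second peak must hold ≥ 3 raw reads, otherwise the sample is called
   homozygous.

Ties break toward the smaller count: deterministic, and conservative in
the sense that the clinically dominant shorter allele is favoured.
`min_separation = 50` units reflects that a mosaic cloud (SD ≤ ~10 units)
spans a few tens of units while genuinely distinct alleles in this assay's
working range differ by ≥ ~130 units; one cloud is never split into two
alleles, and no real pair is merged. All three caller parameters are
exposed on the CLI.

## Consensus, purity, interruptions

Reads within ±20 repeats (inclusive) of the called allele feed the
consensus, separately per strand. The backbone is the read whose count is
closest to the allele estimate (ties: higher anchor identity, then
smallest read id). All other tracts are globally aligned to the backbone
tract with edlib (unbanded — at amplicon scale edlib is fast enough that
an explicit band would only risk rejecting legitimate high-error reads;
results stay deterministic). Columns are majority-voted with deletions
competing as a symbol and ties keeping the backbone base; an insertion
between backbone columns is emitted when more than half the reads carry
one there. Minus-strand tracts are reverse-complemented before alignment,
so all consensus output is in sense (GAA) orientation.

Purity aligns the consensus against `unit^round(len/3)`: percent matches
and percent indels are per alignment column, rounded half-up to integers
(matching how such tables are conventionally printed — note that a
single interrupted unit inside a ~750 bp tract legitimately rounds to
100% matches); copy number is the consensus length in units.

**Interruption calling.** The consensus tract is decomposed into maximal
runs of the exact unit; every internal inter-run segment is a candidate.
The candidate motif is spelled as the disrupting segment plus the first
complete unit after it — chosen so that the canonical FRDA interruption
`GGAGAA` spliced between GAA units is reported back verbatim (`GGA` gap +
`GAA` unit). Two filters make calls robust:

- *Phase filter.* A disrupting segment that occurs somewhere inside the
  endlessly repeated unit (e.g. `AA` or `GA` in a GAA tract) only changes
  tract length; it is indistinguishable from a residual consensus indel
  and is reported as indel noise, never as a motif interruption. This
  matters because alignment-degenerate insertion errors in a long pure
  repeat stack at one canonical column on *both* strands, and without the
  filter they can masquerade as strand-validated interruptions. The cost
  is a documented blind spot: a true interruption composed purely of
  in-phase repeat bases would be missed.
- *Cross-strand validation.* A candidate is validated only when the other
  strand's consensus shows the identical motif within ±5 units (alignment
  jitter can shift consensus coordinates by a few units; the tolerance is
  a flag). The validated offset is the half-up mean of the two strand
  offsets, making the call symmetric under strand exchange.

## Statistics layer

Pearson correlations between sizing methods are computed on
pairwise-complete observations (needed because one manual consensus entry
in the packaged tables is missing), with the n used reported per pair.
Genotype–phenotype analysis is ordinary least squares of age at onset on
allele length; R² equals the squared Pearson coefficient and is reported
as a whole percent. Between-method offsets are signed means over all
alleles present in both methods. For reporting, r is rounded to 2
decimals, R² to whole percents and offsets to integers; full precision is
kept internally.

## Synthetic data: what it emulates and what it does not

The simulator emulates: two repeat alleles per sample; per-read Gaussian
count jitter (rounded, truncated at zero) standing in for somatic
mosaicism — the distributional law of real mosaicism is not established,
so Normal is used as the simplest symmetric choice and is a documented
assumption; per-base substitution/insertion/deletion errors drawn
mutually exclusively per position (platform-scale envelope 0–10%, with
artefactual indel content of a few percent typical of nanopore amplicon
consensus); both strands; spliced interruption motifs; constant Q12
quality strings (qualities are never used downstream). One RNG stream per
sample, consumed in read-id order, makes output byte-reproducible and
event logs replayable.

It does **not** emulate: signal-level (squiggle) behaviour, basecaller-
specific error spectra (e.g. homopolymer-length biases), chimeric or
truncated reads, barcodes, or coverage imbalance between alleles beyond
the configured read counts. Consequences for interpretation: passing
recovery tests here show the sequence-space logic is sound under iid
errors, not that a specific basecaller's biased errors are handled. In
particular, a systematically deletion-biased error process shifts every
read's count down proportionally to tract length; the caller then
faithfully reports the mode of the *observed* counts, which for a
1000-unit allele at 5% unbalanced deletion error sits ~50 units below
truth. Recovery guarantees are therefore stated (and tested) under
indel-balanced error mixes; unbalanced real-world error is a calibration
concern for the assay, not something the mode rule can undo.

## Problem sizes and study conditions used in tests

Simulation-based tests use 50–100 reads per allele, allele pairs spanning
120–1100 units (the assay's validated working range), jitter SD ≤ 10
units, total error ≤ 5%, and 20 seeded replicates per guarantee;
interruption-recovery runs use 60 reads per sample (~30 per strand) at 3%
total error with `GGAGAA` spliced at unit 100 of a 257-unit allele.
These sizes keep every stage's behaviour measurable against truth while
remaining desk-scale.

## Numerical and degenerate-input conventions

- All count/percent rounding is half-up (`floor(x + 0.5)`), not banker's.
- Coordinates are 0-based half-open on the sense-oriented read.
- A read whose downstream anchor lands before the upstream anchor yields
  an empty tract (count 0), not a negative span.
- Empty count distributions, constant statistic vectors, < 3 complete
  pairs, and reads shorter than the flank budget raise errors naming the
  offending quantity; a read shorter than an anchor is flagged `fail`
  rather than raising.
- Full-deletion of a zero-repeat template would emit an empty sequence;
  the simulator substitutes a single `N` so FASTQ stays well-formed.

## Known limitations

- Interruptions whose content is in-phase with the repeat are invisible
  (see phase filter above).
- More than two alleles (e.g. tumour subclones) are out of scope; the
  caller reports exactly one or two modes.
- The consensus is a majority vote, not a partial-order alignment; at
  error rates well above ~10% or with < ~10 reads per strand, residual
  indel noise in the consensus grows and purity metrics degrade before
  genotype calls do.
- Length-based sizing (`count_from_length`) assumes full-length amplicon
  reads; fragmented reads would need size selection upstream.
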
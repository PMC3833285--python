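# Methods

## In silico digestion model

A restriction enzyme is a named IUPAC recognition sequence (4–8 bp) with a
top-strand cut offset in `[0, len(site)]`, REBASE style (HpaII C^CGG → offset
1; Kzo9I ^GATC → offset 0). Scaffolds are linear molecules: cut positions are
`site_start + cut_offset` for every (possibly overlapping) site occurrence,
coincident cuts collapse, and fragment lengths are the successive differences
including the two terminal fragments. Including terminals buys an exact
conservation law — `Σ length·count = genome length` for every digestion —
that the test suite checks on every run; their effect on a genome-scale
diagram is negligible. All built-in panel enzymes are palindromic under IUPAC
expansion, so double-strand recognition reduces to a top-strand scan;
non-palindromic enzymes are accepted and scanned additionally with the
reverse-complement pattern, cuts mapped to top-strand coordinates.

Degenerate matching: a pattern character matches a genome base iff the base
lies in its expansion set, and a genome `N` matches nothing — including
pattern `N` — so N-runs in draft assemblies cannot fabricate sites. The
shipped enzyme table (`data/enzymes.tsv`) is plain TSV, overridable without
code changes.

## Peaks, gel visibility and cross-enzyme concordance

A length `L` is a *distinct peak* when its count reaches `min_count`
(default 100 at genome scale; tests scale this with the data), strictly
exceeds every neighbour within ±`window` bp (default 5; equal counts are
awarded to the smaller length) and reaches `min_prominence` (default 5)
times the median neighbour count, absent lengths counting as zero. The
source publications never define "distinct peak", so these are package
defaults, chosen to pick isolated single-bin spikes out of the smooth
exponential background of random-site fragments.

Gel-band visibility is modelled by combined mass: a 1 bp bin is callable as
a band when `length × count` reaches a configurable fraction of the total
digested DNA (default 0.05%). This reproduces the qualitative phenomenon
that a very short but abundant sub-fragment can dominate a count diagram yet
stay invisible on a gel. The default threshold is a package invention; real
detection limits depend on stain, load and gel.

Cross-enzyme candidates are single-linkage clusters of peak lengths within
±`tolerance_bp` (default 5) across enzymes; a cluster supported by at least
two distinct enzymes is reported at the median member length. Same-size
fragments under unrelated recognition sequences indicate tandem arrangement
because only a unit repeated in head-to-tail fashion yields the monomer
length independently of site position.

## Tandem-array scanner

A purpose-built detector, deliberately not a reimplementation of Tandem
Repeats Finder's probabilistic model (whose parameterisation for the
original genome-scale counts is unknowable); it is validated by
planted-truth recovery instead.

1. *Seeding*: positions whose exact k-mer (k = 12) recurs at a lag within
   `[min_period, max_period]` (defaults 40–500 bp) are seed matches; only
   consecutive occurrences are paired, so inside a clean array the lag is the
   period itself. Implemented with a vectorised polynomial k-mer encoding and
   a stable argsort; windows containing N are excluded.
2. *Clustering*: seeds close in position with compatible lag (±max(3, 8%)
   of the lag) form candidate regions; harmonic lags (2×period) form separate
   candidates that lose the later overlap resolution to the fundamental.
3. *Verification*: unit boundaries are walked left and right from an anchor
   copy with infix (edlib) alignment inside a slack window (12% of the
   period), which keeps the frame in phase across small indels; terminal
   partial copies are recovered by ungapped homology with the adjacent copy
   (stop when mismatches exceed 25%). Adjacent units are compared by global
   alignment; an array is kept when it has ≥ `min_copies` (3) units and mean
   adjacent identity ≥ `min_identity` (75%).
4. *Reporting*: period = median segmented unit length (divergent families
   are therefore quoted as 171–172-style ranges by neighbouring-bin pooling);
   copy number = span/period; overlapping candidates are resolved greedily by
   copy_number × identity, ties leftmost.

The default period window is 40–500 bp; the narrower 40–400 bp variant used
in some analyses is reachable via `--max-period`.

Census: `unit_count` sums `round(copy_number)` over arrays per period bin,
`cluster_count` counts arrays; totals are conserved by construction. Pooled
family consensi rotate each per-array consensus to the circular offset best
matching the first array (IUPAC-compatible Hamming), project it onto the
reference columns by global alignment, and condense the stack column-wise.

## Consensus and circular site maps

Column rule: bases with frequency ≥ 0.25 enter the IUPAC code set unless a
single base reaches 0.75, in which case the column is that base. The
thresholds are package choices (the published consensi do not state their
rule); they reproduce S/W/M codes for 50/50 columns and plain bases for 90/10
columns. Columns more than half gapped are dropped. Degenerate input
characters contribute fractional weight over their expansion set, so a
consensus of consensi is well defined.

Site maps are computed on the circularised monomer (sequence plus its first
`len(site) − 1` bases) with intersection semantics — pattern and consensus
expansion sets must overlap — because the consensus itself is degenerate.
Predicted fragments are the circular gaps between cut positions and sum to
the monomer length whenever at least one site exists; digesting a long exact
array reproduces them as interior fragment lengths, which the tests verify.
Intersection semantics deliberately err permissive on highly degenerate
consensi: a site that is present in only part of the family (e.g. destroyed
by a point substitution in a sub-family) still appears in the consensus map,
mirroring how a consensus can over-predict digestion of individual copies.

Percent identity: global alignment, match +1, mismatch −1, gap −2,
IUPAC-compatible pairs counted as matches, identity = matches / alignment
columns.

## Cluster tiling

`tile_cluster` repeatedly takes the best remaining local alignment of the
consensus against unannotated sequence (score-descending; leftmost interval
on ties; among co-optimal tracebacks the aligner's first enumeration, which
is deterministic), masks it, and stops when the best match falls below
`min_identity` (80%) or `min_match` (20 bp). Local gap costs are stiffer
(open −6, extend −1) than in global identity scoring: with cheap gaps, local
matches chain across non-homologous spacer sequence at ~75% identity and
outscore clean short fragments, ending the greedy loop before they are
annotated. Because local alignment trims mutated terminal columns — which
would turn an exact-length copy into a spurious length variant — up to
`length_tolerance` dropped edge columns are rescued, clamped to the free
interval so nothing is stolen from already-annotated segments.

Classification: `short_fragment` ≤ 35 bp; `truncated5p` starts ≥ 8 bp into
the consensus and reaches its 3′ end; `full` matches the consensus length
exactly; every other match is a `full_variant` (length histogram reported),
so 170/173/175 bp copies with small internal indels are listed as variants
next to the exact full units. Unmatched stretches become spacers; the
segments always partition the region exactly, and each short fragment's
downstream hexanucleotide is reported (not used for classification).
Lowering `min_identity` never decreases the number of non-spacer segments:
the pick sequence is threshold-independent and the threshold only decides
where it stops.

## Synthetic data generator

Backgrounds are i.i.d. with configurable GC content (default 0.40, a typical
Drosophila genome-wide value). Arrays are head-to-tail stacks of a unit;
each copy independently resolves IUPAC positions uniformly over the
expansion set (so polymorphic columns are recoverable as codes), then
mutates: substitutions uniform over the three alternative bases, single-base
indels with equal insert/delete probability. Remnants are 5′-prefix copies
of a unit, interspersed rather than tandem (transposon-remnant style).
Features are spliced into the background at positions ≥ `min_separation`
apart, so output length = background + planted lengths, and every feature is
recorded in a truth BED. Identical specs give byte-identical output.

The three-family fixture (`make_paper_like_genome`) plants, on two 1 Mb
scaffolds: 15 clusters of a 225 bp unit (one CCGG, one GTAC, two CATG;
1% substitutions), 22 clusters of a 154 bp unit (two GATC sites 36 bp apart
circularly plus one AGCT; 8 of the clusters carry a single-base change that
destroys the second GATC site; 0.8% substitutions), 15 clusters instantiated
from the published 172 bp degenerate consensus at 8–10% substitutions *plus
1% indels*, and 30 interspersed 154-unit 5′ remnants. The indel component of
the 172 bp family is essential to the modelled phenomenon: substitutions
never change fragment lengths, so divergence alone would only thin a
digestion peak, whereas length-changing variation scatters it below calling
prominence while the tandem census still records the family. Copy numbers
(18–40 per cluster) give each family several hundred units — enough for
genome-scale peak-calling defaults on a ~2.26 Mb fixture that runs through
the whole pipeline in a few seconds.

What the generator does not emulate: higher-order repeat structure,
recombination/gene-conversion homogenisation gradients, composition bias of
real heterochromatin, sequencing/assembly artefacts beyond N-gaps. Passing
planted-truth tests therefore demonstrates algorithmic correctness under the
stated noise model, not performance on real draft assemblies; in particular
the original genome-scale TRF cluster/unit counts are not reproduced here,
by design.

## Problem sizes and numerical choices

Tests run on scaled-down instances chosen to keep the suite quick while
preserving the phenomena: recovery properties use 20 seeded ~100 kb genomes
(periods 60–400 bp, 5–50 copies, 0–3% substitutions) and 20 seeded ~2–3 kb
clusters; the end-to-end fixture is ~2.26 Mb. Ties everywhere break toward
smaller lengths / leftmost positions; all randomness flows through explicit
integer seeds; degenerate inputs (empty genomes, inverted intervals,
offset-out-of-range enzymes, N-runs) raise typed validation errors.
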
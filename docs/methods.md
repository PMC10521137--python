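# Methods

## Fork-progression analysis

### Signal model

TrAEL-seq captures the 3′ end of the nascent leading strand at a
replication fork, so each mapped read is informative only through the base
immediately 5′ of the strand break: every read is truncated to that single
nucleotide (interval start on the forward strand, interval end − 1 on the
reverse strand; coordinates are zero-based, half-open everywhere, BED
dialect on disk). Reads in non-single-copy regions (rDNA, 2-micron, mtDNA,
sub-telomeres, Ty/LTR) are removed with a BED exclusion mask under union
semantics. Retained single-nucleotide counts are summed in running windows
(default 1,000 bp window, 100 bp step — both configurable, since the
appropriate scale depends on read depth) and scaled to reads per million.
The RPM denominator defaults to the reads retained after masking, which
makes the tiling conservation law exact (a non-overlapping tiling sums to
10⁶) and independent of how much of the genome was masked; a
total-mapped-reads denominator is available as a switch.

### Active origins

In an arrest-and-release experiment every *fired* origin is flanked by two
forks, so origins accumulate break-end signal in their vicinity. Each
candidate origin is scored by total signal in a 10 kb centred window and
the lowest-scoring 40% are discarded (both numbers configurable). The
retained count is `ceil(0.6 n)`; the ranking is a stable descending sort on
a coordinate-sorted catalogue, so ties at the cut boundary retain the
earlier-coordinate origin deterministically. When several conditions share
one catalogue the score is computed on a designated reference condition so
that all samples use the same active set.

### Probes, smoothing, peaks, distances

Each active origin gets two 20 kb probes, upstream and downstream, binned
at 100 bp. The upstream axis is reversed so both probes read
"distance from origin"; under this orientation each probe is expected to
contain exactly one fork peak. (The alternative reading — one folded 40 kb
probe per origin — would not let a multi-peak filter flag probes spanning a
second origin, which is why the two-half-probe interpretation is used.)

Smoothing is classic loess: at every bin the 15 nearest bins are fitted
with a weighted 2nd-order polynomial under tricube weights and the fit is
evaluated at the bin. On the uniform probe grid the interior stencil is
translation-invariant, so the interior is one convolution and only edge
bins are solved individually; this makes genome-scale smoothing O(n). The
local model contains all quadratics, so constants are reproduced exactly
and quadratics to numerical precision; an all-zero probe smooths to
all-zero. The span and order are configurable; 15/2 are the defaults used
throughout.

Peaks are local maxima of the smoothed vector whose prominence is at least
half the vector maximum (prominence fraction 0.5) and which are at least
2,000 bp apart (higher peak wins a conflict; ties break to the lower
coordinate). Local maxima and prominences come from
`scipy.signal.find_peaks` / `peak_prominences`; the thinning rule is
implemented on top and the whole detector is verified in the test suite
against an exhaustive scan with walk-out prominence. No published
peak-calling rule exists for this analysis, so the prominence fraction and
separation are declared defaults, not inferred constants.

A probe with more than one peak spans a second origin and is dropped from
distance statistics. The fork distance of a retained probe is the oriented
coordinate of the global smoothed maximum (bin left edge; resolution is one
probe bin, 100 bp); it is undefined for empty, multi-peak or truncated
probes (probes crossing a chromosome end are flagged and excluded by
default). Ties at the maximum report the smallest distance and are logged.

The genome-wide fired-origin count applies the same bin/smooth/peak-call
machinery per chromosome (prominence relative to the per-chromosome
maximum) and divides the peak total by two, because each fired origin
launches two diverging forks. An odd total is floor-divided with a warning.

### Group statistics

Per biological replicate, the median fork distance over retained probes is
the unit of analysis. Conditions are compared by ordinary one-way ANOVA on
replicate medians with all g(g−1)/2 pairwise comparisons under Tukey HSD
(Šídák and Bonferroni on pairwise Welch t-tests are selectable). Groups
with a single replicate are excluded from pairwise testing with a warning
but still enter the omnibus test. Under a simulated null the family-wise
rejection rate is nominal (checked over 200 simulations in the acceptance
suite).

## Proximity-labelling enrichment

Raw LFQ intensities are processed in a fixed order: (1) absent
protein/sample/replicate rows are completed as intensity 0; (2) every zero
is converted to 1 so ratios are defined; (3) each intensity is divided by
the control protein's intensity in the same sample/replicate (the control
is an endogenously biotinylated carboxylase present in every run, and maps
to exactly 1); (4) normalised values are averaged per sample;
(5) enrichment coordinates are x = log(avg₃/avg₂) and y = log(avg₃/avg₁),
log base 2 by default (hit calls are base-invariant given matching
thresholds). Zero-imputation precedes normalisation so the rule covers
numerator and denominator uniformly.

A protein is a hit iff x > 1 and y > 1 (both thresholds configurable and
recorded in output provenance; no published threshold values exist, so
these are declared defaults). Two exact invariants follow from the
construction and are enforced by tests: the control protein sits exactly at
(0, 0) and is never a hit for positive thresholds, and multiplying all
intensities of one replicate by any constant cancels in the control
normalisation, leaving every enrichment unchanged.

A deliberate artefact is preserved: when a protein drops out of entire
replicates, the zero→1 rule places it on a diagonal in the (x, y) plane and
can make genuinely background proteins look enriched (two dropouts in both
reference samples inflate both ratios ~3-fold at n = 3). This mirrors the
behaviour of the published rule; consequently perfect truth recovery is
only guaranteed by the simulator's default dropout-free tables, and the
dropout parameter exists to reproduce the artefact, not to be corrected
away.

## Nuclear fluorescence

CTNF = integrated density − area × mean background fluorescence, evaluated
per cell from a measurement table (image segmentation is out of scope; the
package consumes per-cell measurements). Negative CTNF values are retained
and flagged rather than clipped — they are informative about background
over-estimation. The nuclear/cytoplasmic ratio uses mean intensities
(whether published ratios used means or integrated intensities is not
stated; means make the ratio invariant to nucleus size). Cells with zero
cytoplasmic signal are excluded with a warning. Groups are compared with a
two-sided Welch t-test by default (the equal-variance Student variant is
selectable).

## Synthetic-data generators

The fork simulator emulates a population released from an HU arrest: each
origin fires with a given probability; each of its two forks sits at an
independent draw from a Normal(mean, spread) truncated at 0 (no
distributional form is published; the truncated Normal is the minimal
choice consistent with a mean and spread); read ends scatter Normally
around the fork (default 300 bp); strand labels follow the
leading-strand convention (rightward forks label the forward strand) with a
default leading fraction of 0.8, since the method is known to prefer the
leading strand but no fraction is published; background reads are uniform
(0.2 reads/kb) and duplicates are verbatim copies (2%) emulating PCR
duplicates normally removed upstream. Read-count accounting is exact:
emitted = fork + background + duplicates. The default desk scenario is
2 × 500 kb chromosomes with 10 origins ≥ 60 kb apart and 200 reads per
fork — sizes chosen for statistical power at desk scale, not to match any
particular sequencing depth. The generator warns when origins sit closer
than twice the probe half-width, which breaks the one-origin-per-probe
assumption.

What the simulator does *not* emulate: mappability structure, sequencing
error, UMI chemistry, replication timing gradients, fork stalling
heterogeneity, or passive replication. Passing recovery tests therefore
demonstrate correctness of the analysis logic on idealised fork signal, not
robustness to every artefact of real libraries.

The LFQ simulator draws per-protein base intensities log-normally
(scale 10⁶, log-SD 1), applies class multipliers (8-fold by default) —
tag-specific proteins up wherever the tag is present, treatment-enhanced
proteins up only in the tagged + treated sample — and multiplies
log-normal replicate noise (log-SD 0.2, a realistic LFQ CV). Default
tables are dropout-free; the control protein is never dropped at any
dropout setting. The fluorescence simulator shifts the interaction group's
nuclear/cytoplasmic ratio by a stated number of ratio-SDs and constructs
integrated density as area × (nuclear + background) so the CTNF formula
recovers the nuclear signal exactly.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and parameters give byte-identical outputs, including on-disk files.
* Problem sizes in the test and acceptance suites (2–3 chromosomes of
  500–700 kb, 10–30 origins, 100–200 simulations) are desk-scale choices
  that keep every statistical check well-powered while remaining fast.
* Windows whose start lies inside the chromosome are generated even when
  they extend past the end, so a step-equals-width tiling covers every
  position exactly once (conservation law).
* The activity filter, probe construction and peak calls are deterministic
  given their inputs; the only logged nondeterminism-adjacent events are
  explicit warnings (masked reads, truncated probes, multi-peak probes,
  excluded cells, odd peak totals).

## Known limitations

* Fork distance resolution is one probe bin (100 bp); distances are bin
  left edges, so a planted fork is recovered to within one bin, not
  exactly.
* The activity filter assumes a shared reference condition; scoring each
  condition separately would change the active sets and is intentionally
  not the default.
* The fired-origin count assumes well-separated forks; forks closer than
  the peak separation merge into one peak and bias the count down.
* The enrichment analysis performs no statistical test per protein (no
  variance model, no FDR); hits are threshold crossings, as in the
  procedure it implements.
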
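# Methods

This note documents the models, parameter choices and numerical conventions
behind `bcstarprom`, and what the simulation-based tests do and do not show.

## Library model

A construct is `backbone — NheI — promoter — HindIII — reporter stub —
constant spacer (20 nt) — barcode (20 nt) — XbaI — backbone`. The promoter
is six tandem 84-bp repeat units, each a 68-bp random core between fixed
8-bp flanks shared across the library. Internal coordinates are 0-based
half-open; the screen-read trimming API speaks the field's 1-based
inclusive convention (index positions 1–6, barcode 27–46) and converts at
the boundary.

The published design fixes the restriction landmarks and repeat geometry
but not the flank/backbone sequences, so the packaged template uses
arbitrary constants generated once from a fixed seed and screened to be
free of spurious landmark sites. The reporter stub is sized so the
NheI–XbaI fragment is 2275 bp, and carries single ApaI, FspI and HincII
sites placed >200 bp from both fragment ends, so reopening a
barcode–promoter circle at any of them leaves the junction readable.

**Barcodes.** The degenerate pattern `HHDDDDHHBBVVDDDDHDBV` admits three
nucleotides per position (H = A/C/T, D = A/G/T, V = A/C/G, B = C/G/T),
giving 3²⁰ ≈ 3.5 × 10⁹ barcodes — vast excess over library size, which is
why a barcode observed with two promoters is treated as a chimera and
dropped rather than resolved by majority. Sampling is uniform per position
with rejection of duplicates; the simulator additionally rejects barcodes
that would create a spurious NheI/XbaI/HindIII site in their constant
context (such plasmids would not survive cloning). The same clonability
screen applies to random cores: a repeat containing one of the three
cloning hexamers is resampled. The linearization enzymes (ApaI, FspI,
HincII) are *not* excluded from cores — their occasional occurrence near
the junction is exactly the failure mode the three-aliquot redundancy
exists to absorb, and the simulator reproduces it.

**Sample indexes.** 6-nt indexes at pairwise Hamming distance ≥ 3, built by
greedy randomized search with a configurable attempt cap (the construction
method is a design choice; the distance property is what matters and is
re-verified by brute force). Distance 3 makes radius-1 balls disjoint, so
demultiplexing corrects exactly one substitution unambiguously
(`max_mismatch` default 1; raising it beyond 1 is refused).

## Association

Junction reads model the circularization strategy: the NheI–XbaI fragment
is self-ligated, bringing the barcode (fragment 3′ end) next to the first
repeat (fragment 5′ start); reads are 150 nt = 40 nt of barcode-side
context + 110 nt of promoter-side context. Parsing anchors on the constant
spacer, the NheI hexamer and the left flank, each tolerating ≤ 1
substitution; barcodes are matched verbatim (the random 3²⁰ space gives no
guaranteed minimum distance, so error correction would corrupt rather than
rescue). Long reads are modeled as full-fragment sequences with a
substitution error rate; hairpin-adapter/consensus machinery of long-read
instruments is out of scope. A reverse-complement retry makes long-read
parsing orientation-free.

Support filtering is strictly `> 50` reads (default, configurable).
Conflicting barcodes (two promoters above threshold) are excluded and
reported — with the barcode space in such excess, true collisions are
vanishingly rare, so conflicts indicate artifacts. Promoters with several
barcodes are reported separately: they are legitimate and serve as internal
replicates.

## Quantification

**Median normalization** follows
`value' = value / median(sample column) × median(all table entries)`.

**Fold changes** divide by the mean of the control columns (all vehicle
time points plus every time-0 sample; replicates with reduced control
series simply average whatever control columns exist). Fold changes are
computed from the per-column median-scaled component, which the normalized
table carries alongside the display values: the global rescaling constant
is a common factor of numerator and denominator and cancelling it
structurally (rather than numerically) makes fold changes, scores and
rankings *bit-for-bit* invariant to rescaling any sample's counts.

**Pseudocount** defaults to 0. The count table is filtered to barcodes
present in every sample before quantification, so zeros cannot reach the
fold-change step; a nonzero pseudocount on the count scale would break
exact depth invariance. It remains configurable for unfiltered tables.

**Ranking** uses `score = mean FC(drug, t ∈ {1,2,4,8} h) / mean FC(control,
same times)`, descending, ties broken lexicographically by barcode. This
score, being a time-series average, favors immediate-early responses —
late-peaking inductions contribute fewer high time points — so per-time
rankings can be derived from the fold-change table when delayed responders
are the target.

**Clustering** merges the top-20 promoters per replicate ranking and
applies complete-linkage agglomeration on Euclidean distance over log2
fold-change profiles, cutting at 4 groups by default (the tree-cut
criterion is a package choice; the linkage and metric follow the screening
convention). Promoter profiles average their barcodes' fold changes.
Sorting the merged set before clustering makes assignments deterministic.

**CV gate**: sample standard deviation over mean, kept iff CV < 0.12 —
the transfection-uniformity criterion generalized to any replicate set.

## Motif analysis

PFMs are parsed from JASPAR text (bracketed or raw 4-row) via Biopython.
Log-odds use a uniform 0.25 background with a total pseudocount of 0.8 per
column split equally across bases; scanning reports every offset/strand
whose *relative* score `(score − min) / (max − min)` reaches the threshold
(default 0.85, JASPAR community convention; the synthetic-panel tests use
0.95 because sharp, near-deterministic count matrices make one-mismatch
windows pass at 0.85, which would flood the incidence sets). Scanning
targets the concatenated 68-nt cores — the flanks are constant library-wide
and would yield uninformative shared hits. Reverse-strand hits are mapped
to forward coordinates; strand symmetry is property-tested.

**Set enrichment** is classic weighted-KS GSEA re-implemented for motif
sets over the promoter response ranking (the screen's original adaptation
is documented only in outline, so this is a reconstruction with every
choice exposed): member positions weighted by `|log2 score|^p` with
exponent 1 (unweighted fallback when all member weights are zero), ES =
signed extreme of the running sum, significance by promoter-label
permutation `p = (extreme + 1) / (n_perm + 1)` (never zero), BH FDR across
the panel. Null calibration over random sets is KS-tested for uniformity in
the suite.

## Simulator

The generator's defaults are the study conditions: 3000 plasmids, six
repeats, times 0/1/2/4/8 h, one drug plus vehicle (10 samples), baseline
abundances log-normal with μ = 2, σ = 0.8 in log10 read units (a wide
basal-expression spread spanning ~3 orders of magnitude), 10% of promoters
duplicated under extra barcodes, and four planted response groups (0.5% of
plasmids each): immediate-early CArG responding to both drugs, a strong
single-drug CArG group (amplitude 29, matching a 30-fold responder),
delayed NFkB-like and delayed AP-1-like groups. Induction follows the
gamma-like pulse `1 + A·(t/τ)·e^(1−t/τ)`: exactly 1 at t = 0, peak fold
change 1 + A at t = τ; published kinetics are shown graphically only, so
the functional form is this package's choice (immediate-early τ ≈ 1–2 h,
delayed τ ≈ 3–4 h). Counts are multinomial given depth — the minimal noise
model; no quantitative count-noise model is published. Reads carry i.i.d.
substitutions only (adequate for fixed-layout amplicons), constant
placeholder qualities, and exact per-barcode multiplicities. Exonuclease
removal of non-circularized molecules is modeled by simply not emitting
unligated fragments. A repressor-interference group can be emulated with a
negative amplitude; it is off by default.

What passing tests show — and don't: with zero error the pipeline is exact
by construction (association recovery, count identity), and at realistic
depths ranking and enrichment recover planted truth. Real data add PCR
amplification bias, duplicate structure, quality-dependent errors and
cross-sample contamination, none of which the generator emulates; the
tests validate the pipeline's correctness and statistical calibration, not
robustness to those artifacts.

## Problem sizes in the test suite

Simulation-based checks run at desk scale chosen to keep the suite brisk
while preserving the relevant statistics: association recovery on 500
plasmids at 60× junction coverage; count identity on 3000 barcodes × 10
samples × 10⁵ reads/sample; ranking recovery with 20 planted amplitudes
(4–30) among 3000 barcodes at 10⁶ counts/sample (count-level, the
read-level identity being established separately); enrichment calibration
with 200 random sets at 999 permutations; motif recovery on a 1500-plasmid
screen against a 20-motif panel.

## Known limitations

* Promoter identity is established by exact core matching against the
  library manifest; de-novo promoter clustering from reads (needed when no
  manifest exists) is not implemented.
* The enrichment score's immediate-early bias (above) is inherited from
  the ranking definition.
* The insert length bookkeeping records 6 × 84 = 504 bp per promoter;
  cloning overhangs that pad the physical insert are not modeled.
* Plotting is intentionally minimal: all artifacts are TSV and feed
  standard tools.
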
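# Methods

This note documents the models and numerical choices behind `fourcat`, in
the spirit of a methods supplement: what each stage assumes, which knobs
matter, what the synthetic data does and does not emulate, and where the
design was genuinely open.

## Coordinates and formats

All intervals are 0-based half-open (BED convention), declared once and used
everywhere. Genomic text outputs are sorted by (chrom, start) so reruns are
byte-diffable. Formats touched: FASTA, BED, bedGraph, TSV, JSON.

## In-silico digestion

Fragments are delimited at the first base of each recognition-site
occurrence — a blunt-cut abstraction that ignores real enzyme overhangs
(± 4 bp, irrelevant at 2 kb window resolution). Matching is
overlap-tolerant and honours IUPAC degeneracy in the site; an `N` in the
*sequence* matches only fully degenerate site positions. The catalogue
carries the two enzymes of the two-step 4C design, DpnII (`GATC`) and Csp6I
(`GTAC`). Viewpoints are accepted as a (chrom, position) pair and resolved
by half-open containment; primer-based viewpoint design is out of scope.

## Synthetic 4C experiment

The generator emulates a promoter-viewpoint 4C assay in two conditions
("quad", "sol") with two replicates each.

* **Genome**: random ACGT with recognition sites at their natural ~1/256
  density plus a forced site every 5 kb (no fragment exceeds 5 kb).
  Defaults: a 5 Mb viewpoint chromosome and two 2 Mb trans chromosomes —
  large enough for > 2400 testable cis windows and several 1 Mb bins, small
  enough that a full four-sample experiment simulates and analyses in well
  under a second.
* **Cis reads** land on fragment *f* with probability ∝
  `len(f) · (1 + d/d0)^(−α) · effect(f)`, with `d` the midpoint distance to
  the viewpoint, defaults `α = 1`, `d0 = 10 kb` (a standard polymer-contact
  decay shape). The fragment-length factor makes *windowed* intensity a
  smooth function of distance; without it, window counts track the
  Poisson-varying number of fragments per window (≈ 35% CV), which no
  count-based caller should be asked to absorb, and which is also the less
  physical model (capture scales with fragment size).
* **Effects**: a planted enhancer multiplies the weight of every fragment
  overlapping its footprint (summit ± width/2) by its per-condition effect
  (≥ 1). Default recovery architecture: five enhancers at effect 8, width
  1 kb — three active in both conditions, one specific to each.
* **Invalid reads**: a fixed fraction (default 0.10; a typical share for
  4C libraries) goes to the viewpoint fragment (undigested, 50%) and its
  two neighbours (self-ligated, 25% each).
* **Cis share**: default 0.45, within the 18–68% range observed for real
  libraries and above the 40% QC gate, so the gate passes at defaults and
  fails when the share is lowered.
* **Noise**: per-fragment Gamma multipliers at two levels — a
  condition-level multiplier (dispersion 0.025) shared by a condition's
  replicates, modelling tissue-specific contact landscapes, and a
  replicate-level multiplier (dispersion 0.025) independent per sample.
  The total per-sample dispersion of 0.05 keeps the Poisson caller's null
  behaviour inside its calibration band (measured mean significant fraction
  ≈ 0.04 with no planted effects) while producing imperfect replicate
  concordance. Real 4C libraries are far noisier (published replicate
  reproducibility can be as low as a few percent of sites); both dispersions
  are exposed so harsher regimes can be simulated deliberately.
* **Tracks**: each planted summit emits an H3K27ac peak and an ATAC peak
  (800 bp, jittered ≤ 200 bp) and a Gaussian ATAC signal bump (sd 150 bp,
  amplitude 20) over uniform noise in [0.5, 1.5] per 100 bp bin; promoters
  cover the viewpoint ± 1 kb. Decoys: three ATAC-only peaks, three
  H3K27ac-only peaks, and one both-marks region annotated as a (decoy)
  promoter, so every exclusion rule of the screen is exercised.
* **Determinism**: every artifact is a pure function of
  (seed, condition, replicate) via `numpy` `SeedSequence` streams.

A second preset, `contrast_config`, models two strongly divergent
conditions: a 12 Mb viewpoint chromosome with eight enhancer domains of
8 kb contact footprint, three specific to each condition, spread over
distinct 1 Mb bins. It exists because condition separation in clustering
and PCA of binned interaction-site profiles requires condition-specific
architecture in several bins; with calibrated per-window noise, two
single-window differences cannot move a Pearson dendrogram.

**What the generator does not emulate**: sequence-level reads (FASTQ), PCR
duplicates, mappability/repeat masking, fragment-end bias, trans-contact
structure (trans reads are uniform), and genome-scale chromosome counts.
Passing recovery tests therefore demonstrates the pipeline's statistical
logic, not robustness to alignment artifacts or real-genome bias.

## Interaction calling

Only cis windows are tested; trans windows are reported but never called
(the downstream screen is cis-restricted anyway). Windows overlapping
viewpoint ± 10 kb are excluded from background fitting and calling: the
over-represented near-cis zone would otherwise dominate the background.
The background mean per window is the running median of counts over 101
distance-ordered cis windows (centre-aligned, shrinking at the ends),
floored at 0.5 so empty stretches keep a proper null; the test is a
one-sided upper-tail Poisson p-value, BH-adjusted over all tested windows,
significant at padj < 0.05. Fewer than 101 testable cis windows is an
error (the genome is too small for the background model).

Two properties of this analogue are worth knowing. First, in the steep part
of the decay the running median under-estimates the near side of its
101-window span, so windows within roughly 100 kb of the viewpoint are
called liberally — biologically defensible (they are genuine proximity
contacts) but not conservative. Second, with Gamma noise the Poisson tail
is mildly anti-conservative; at the default dispersions the measured
significant fraction under no planted effects stays ≈ 0.04.

Reads are credited to the window containing their fragment's midpoint (no
splitting); "self-ligated" is defined as ± 1 fragment from the viewpoint
and "non-digested" as the viewpoint fragment itself; the cis QC gate is a
strict inequality (> 40%).

## Differential analysis

The test is a self-contained negative-binomial Wald analogue of the
standard count-based differential frameworks: median-of-ratios size
factors (falling back to total-count ratios if no window is positive in
all samples); log2FC = log2((mean_B + 1)/(mean_A + 1)) on normalised
counts; per-window method-of-moments dispersion pooled across conditions
and floored at 0.01; delta-method standard error of the log2FC; two-sided
normal tail; BH adjustment. SDIS ⇔ |log2FC| > 1 and padj < 0.05. The
construction guarantees exact label-swap antisymmetry (log2FC negates,
p-values unchanged) and exactly zero SDIS when the two conditions carry
identical counts. The default site set for testing is the union of the two
conditions' high-fidelity sets — a condition-specific contact absent from
one condition's set must still be testable — with the set exposed as an
argument.

## Enhancer screen

Rules are applied in a fixed order: drop interchromosomal sites; require
≥ 1 bp overlap (half-open) with both an H3K27ac and an ATAC peak; drop
sites overlapping any promoter; merge abutting/overlapping survivors into
regions; emit per region the window of ≤ 1000 bp maximising *integrated*
ATAC signal (value × covered bp — robust to bedGraph run fragmentation),
ties broken leftmost, all-zero-signal regions flagged `zero_summit`. The
1 bp overlap predicate is the weakest consistent reading of "simultaneous
enrichment" and is deliberate; merging before summit selection makes one
broad element yield one candidate. The maximisation exploits that the
objective is piecewise linear in the window start, so only run-boundary
breakpoints need evaluation; an exhaustive per-base scan is kept as the
test oracle. Conservation annotation is ≥ 1 bp overlap with a conserved
element, reported per candidate with a summary fraction.

## Motif scanning

E-box scanning matches `CANNTG`; the pattern class is its own reverse
complement, so forward-strand offsets are reported once with strand "+".
PWM scoring is log-odds in bits with uniform background and pseudocount
0.01 applied as background-proportional smoothing; `N` in the sequence
contributes 0 at its position; both strands are scanned; the hit threshold
is 80% of the maximum attainable score. Ranking across candidates is
descriptive (best score, hit count); no enrichment null against shuffled
sequences is computed, deliberately, since any such null would be an
invention of this package rather than part of the workflow it implements.

## Pipeline and configuration

`PipelineConfig` carries every analysis threshold (window 2 kb, bin 1 Mb,
alpha 0.05, |log2FC| > 1, cis gate 0.40, correlation gate 0.4, width cap
1000 bp, overlap 1 bp) plus three knobs the underlying publications leave
unstated, marked `# artifact-default` in the source: the 10 kb
viewpoint-exclusion radius, the 101-window background span, and the 0.5
background floor. Configs serialise to JSON, reject unknown keys, and are
hashed into every run log. `run_pipeline` writes each stage's outputs to
`<name>.partial` and renames on stage success, so an aborted run leaves
its partial files identifiable; failures carry the stage name.

## Problem sizes

The shipped defaults — 9 Mb genome, 5 × 10^5 reads/sample, four samples —
make one end-to-end experiment ≈ 0.5 s, which is what lets the test suite
assert recovery across 25 independent simulations and null calibration
across 50, and keeps `scripts/acceptance.py` under a minute. These sizes
are the package's chosen study scale; all of them are config fields.

## Known limitations

* The caller's near-viewpoint liberality and mild anti-conservativeness
  under overdispersion (above) are inherent to the specified
  running-median + Poisson design.
* The moment-based dispersion with two replicates per condition is a crude
  estimator; the 0.01 floor prevents degenerate zero-variance windows from
  dominating, at the cost of slight conservatism for truly low-dispersion
  windows.
* Candidate enhancers inherit peak/promoter annotations from the ≤ 1 kb
  summit window; a summit window can in principle sit in a mark-free gap
  of its merged region, in which case its own peak-id lists are empty even
  though the region satisfied the enrichment rules.
* Trans interactions are never called significant and the screen is
  cis-only by construction.
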
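# Methods

`sepmap` implements the computational core of a splicing-sensitive
microarray study in a transgenic-mouse muscle model: event-level calling of
alternative-splicing changes by separation score, SAM-style differential
expression, k-mer word enrichment around regulated cassette exons, and the
positional "RNA map" of a splicing-factor motif with a resampled background
null.  A synthetic-data generator with known ground truth makes every stage
testable without any external download.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Separation score (Sepscore)

For an alternative event with inclusion-reporting probes I and
skip-reporting probes K, and two sample groups A and B,

    S = median_{p in I} log2( mean_A(p) / mean_B(p) )
      - median_{p in K} log2( mean_A(p) / mean_B(p) )

where `mean_G(p)` is the linear-scale group mean of probe p.  Positive S
means relatively more exon inclusion in group A.  Properties used by the
tests: exact antisymmetry under a group swap, exact invariance under a
global rescaling of all intensities, and robustness of the probe-level
median to individual outlier probes.  Because S is a difference of medians
of per-probe log-ratios, a uniform expression change of the host gene
cancels.  Intensities are floored at 1.0 on the linear scale before logs
(configurable) so that a zeroed probe cannot produce an infinite ratio.
Intron-retention events map their intron probes to the "inclusion" role and
the spliced-junction probe to "skip"; alternative 5'/3' events pass through
their include/skip probe sets unchanged, so one formula serves all event
geometries.

## Permutation q-values and the call rule

Significance comes from balanced relabeling of the samples.  With 3
replicates per group there are C(6,3) = 20 balanced assignments; the
identity and the full group swap reproduce the observed statistic (the swap
only flips its sign) and are therefore excluded, leaving 18 informative
assignments that are enumerated exhaustively.  For an event with threshold
t = |S|,

    FDR(t) = mean over permutations of #{ permuted |S| >= t }
             / #{ observed |S| >= t }

clipped to [0, 1]; the q-value is the minimum FDR over thresholds at or
below t, which enforces monotonicity in |S|.  "q = 0" therefore has the
operational meaning that *no* permuted score anywhere in the dataset
reached the event's threshold.  An event is called changed when
|S| >= 0.3 (boundary included) and q = 0; classes are

* induced:     S >= +0.3 and q = 0
* repressed:   S <= -0.3 and q = 0
* background:  |S| < 0.3 and q > 0.2
* unclassified otherwise.

The repressed rule is written with an explicit negative threshold: a rule
of the form "S < 0.3" would overlap the induced class and is read as a sign
typo.  The background class is defined on q (not a raw p), matching the use
of these events as the null pool for the motif analyses.  The same
permutation engine generalizes to larger groups (exhaustive up to 20,000
assignments, seeded sampling beyond that), but the 3-vs-3 design is the one
the defaults target and the only one the q = 0 semantics is calibrated for:
with 18 permutations the smallest nonzero FDR contribution is 1/18 per
exceedance, so q = 0 is attainable yet strict.

## SAM-style differential expression

Gene expression per sample is the median log2 intensity over the gene's
constitutive probes only.  The moderated statistic is

    d = (mean_A - mean_B) / (s + s0)

with s the pooled standard error of the mean difference and s0 the 5th
percentile of the gene-wise s distribution.  The percentile rule replaces
the classical coefficient-of-variation optimization of s0: it is
deterministic, one line, and transparent; with thousands of genes the two
choices move d by a few percent at most, far inside the permutation noise
of a 3-vs-3 design.  The test is two-class unpaired.  q-values reuse the
permutation engine (s recomputed per relabeling, s0 held at its observed
value).  Selection requires |log2fc| >= 1 — "at least 2-fold", boundary
included, the same convention as the Sepscore threshold — and q < 0.05.

Fold-change profiles across comparisons are clustered by average-linkage
agglomeration under distance 1 - Pearson correlation (via
`scipy.cluster.hierarchy`).  A constant profile has no defined correlation;
its distance to everything is set to 1 (the uncorrelated value) and a
warning is logged.  Leaf order is deterministic with ties broken by input
order, and the tree is also rendered as Newick text.  The pipeline's
simulated study has a single TG-vs-WT comparison, for which a correlation
distance is undefined, so `run_pipeline` does not invoke clustering; the
operation is exposed through the library and the `expr --cluster-matrix`
CLI for multi-comparison matrices.

## Word enrichment

For each 6-mer, exons are scored for *containment* (at least one exact
occurrence, sense strand, N never matches) within a window of flanking
intron — by default the first 150 nt of downstream intron.  The 2x2 table
(test/background x contains/does not) is tested with a two-sided Fisher
exact test; two-sided is the conservative default since the direction of
enrichment is not known in advance.  Odds ratios apply a Haldane 0.5
correction when a cell is zero.  Benjamini–Hochberg adjustment across the
4096 words is reported alongside the raw p, but the ranking (and the
planted-motif recovery benchmark) uses the raw p, treating the scan as a
screening step.  Exons shorter than the window are truncated and still
count in the set size.

## RNA map and the resampled background envelope

The positional map slides a 50-nt window in 5-nt steps across the first
150 nt of downstream intron (21 windows, starts 0..100).  Per window,

    freq = (total occurrences fully contained in the window, summed over
            events) / (number of events)

Occurrences are counted, not reduced to presence/absence, and an occurrence
belongs to a window only when fully contained (start >= w and
start + |motif| <= w + width) — unambiguous and conservative at window
edges.  The null band draws `n_samplings` = 100 subsets of `sample_size`
background events without replacement, computes each subset's per-window
frequency, and reports the mean and the empirical 2.5th/97.5th percentiles.
When two regulated sets are contrasted, `sample_size` is the size of the
smaller set.  Windows with test frequency strictly above the upper bound
are reported as contiguous enriched runs with their peak window.

Known calibration property: the percentile envelope is mildly
anti-conservative as a 95% interval for an *independent* test set of the
same size.  Two mechanisms, both inherent to the resampling design rather
than to this implementation: (a) subsampling a finite pool of N events
underestimates the superpopulation spread of an independent set by the
factor sqrt(1 - n/N); (b) the empirical 2.5/97.5 percentiles of 100
samplings form an interval with expected coverage near (98-3)/101 ~ 94%
even in the continuous, infinite-pool limit.  At the benchmark's sizes
(n = 800 drawn from N = 12,000) the realized coverage is ~92-93%; at pool
fractions like 260/821 it would drop toward ~89%.  Users comparing a test
set against a barely larger background pool should expect the band to be
tight.  A normal-approximation band (mean +- 1.96 sd over samplings) can be
obtained from the returned sampling means if preferred.

## Bench statistics

* PSI = 100 x inclusion / (inclusion + skip); the skipping rate is its
  complement.  Clamped to [0, 100] against float rounding.
* The different-from-wild-type decision is a two-sample Student t-test
  (equal variance) at alpha = 0.05; with n = 3 per group the equal-variance
  form is the sensible default and Welch is available behind a flag.  Two
  constant identical groups give p = 1 rather than an error.
* Fusion index = 100 x (nuclei in MHC-positive myotubes with >= 3 nuclei) /
  (total nuclei); totals below 1500 are accepted with a logged warning.
* Comparative-CT: fold = 2^(-ddCt) with ddCt the target-minus-reference Ct
  difference in test minus the same difference in control.
* Half-life: least-squares fit of ln(abundance) on time; t1/2 = ln2/|slope|.
  The log-linear form is closed-form and exactly right for single-phase
  exponential decay; a non-negative slope returns infinity ("non-decaying")
  rather than an error.
* RIP enrichment = (IP/input) / (IgG/input); separate inputs for the IP and
  IgG aliquots are supported, and a zero IgG signal is an error that
  suggests a pseudocount rather than silently producing infinity.

## Synthetic data: what it emulates and what it does not

`gen_probe_dataset` draws log2 intensities as

    baseline + probe affinity N(0, probe_sd)
             + group effect + replicate noise N(0, replicate_sd)

and exponentiates, i.e. log-normal intensities with i.i.d. Gaussian
measurement noise per probe x sample — the standard first-order microarray
error model.  A planted splicing change of magnitude s moves inclusion
probes by +s/2 and skip probes by -s/2 (log2) in the transgenic group, so
the true Sepscore equals s exactly in expectation while the host gene's
summarized expression is unchanged, isolating splicing from expression.
Planted signs are random per event.  Expression changes move constitutive
probes only.  Defaults describe the emulated study: two genotypes, 3
replicates per group, ~0.2 log2 units replicate noise, 10% of events
planted at |S| = 0.6, 10% of genes at 1.5 log2fc.

`probes_per_role` defaults to 16: splicing-sensitive designs report
inclusion through exon-body plus both flanking junction probe sets (about
three probe sets of 4-6 probes each).  At that count the probe-median
Sepscore has a standard deviation of roughly 0.07 under the default noise,
which a design power analysis shows is what gives the q = 0 call rule >=90%
sensitivity for |S| = 0.6 effects — the same power reasoning an array
designer applies when sizing probe sets.

`gen_exon_sequences` writes i.i.d. background sequence from a configurable
base composition (uniform by default) and, for non-background classes,
plants one motif copy per exon with probability `plant_prob`, uniformly
within `plant_window` (default 70-90 nt downstream of the 5' splice site,
bounds inclusive).  Planting overwrites the background letters at the
chosen offset; spontaneous occurrences elsewhere are left in place and are
deliberately *not* recorded as planted, mirroring real sequence where a
motif search cannot distinguish provenance.  One copy per exon keeps the
per-exon "contains a site" picture simple; multi-copy planting would be a
config extension.

Not simulated: probe cross-hybridization, scanner saturation, sequence-
dependent probe affinity, intron length variation, dinucleotide or higher-
order sequence composition, and splice-site consensus structure.  Passing
benchmarks therefore demonstrate the correctness and calibration of the
*algorithms* under the stated error model, not performance on real CEL
data.

## Problem sizes and determinism

The shipped benchmarks use 1000 events x 6 samples for calling (5 seeds),
300 test / 800 background exons for motif recovery (20 seeds), and 800 /
12,000 exons x 400 replicates for envelope calibration — sizes chosen so
each property is measured with low estimator variance while the whole suite
runs in a few minutes on one CPU.  All randomness flows from explicit
seeds: generators take a seed in their config, resampling takes a
`numpy.random.Generator`, exhaustive permutation q-values are
deterministic by construction, and the pipeline derives every stream from
its single seed — rerunning a pipeline reproduces byte-identical artifacts,
which the manifest's SHA-256 hashes make checkable.

## Limitations

* The q = 0 calling semantics is tied to small exhaustive permutation sets;
  with many replicates (where the permutation count explodes) a sampled
  null makes q = 0 a random event, and a conventional q-threshold should be
  used instead.
* The Fisher screen tests containment, not occurrence counts, so very long
  windows saturate (every exon contains every common word); the window is
  the sensitivity dial.
* The envelope's mild undercoverage (above) is inherited from the
  resampling design.
* Only the downstream-intron map is built; upstream and exonic maps would
  be straightforward variants but are out of scope.
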
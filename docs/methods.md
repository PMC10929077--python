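# Methods

## Read-level classification

A likelihood-ratio caller assigns each read, at each CpG unit, a natural-log
likelihood ratio Λ of the methylated versus unmethylated model. By Wilks'
theorem −2 log Λ is asymptotically χ² with degrees of freedom equal to the
dimensionality difference (here 1), so a level-α per-read test thresholds the
LLR at ½·χ²₁₋α,1. `llr_threshold_from_alpha(0.05, 1)` evaluates the quantile
with `scipy.stats.chi2.ppf`, giving 1.9207 (critical value 3.8415); we quote
the conventional rounded cutoff ±1.921. The ambiguous interval
[−t, +t] is closed: a read exactly at the boundary is excluded from rate
estimates, which makes the classification a strand-symmetric mirror under
LLR sign flip.

Probability callers (modified-base BAM tags) have no published per-read
cutoff; the defaults `prob_low = 0.2`, `prob_high = 0.8` are this package's
choice, exposed in `CallerConfig`. ML tag integers encode probability bins;
we decode the bin midpoint, (ML + 0.5)/256.

## Units, aggregation and covariates

CpG C positions within `unit_gap = 10` bp chain transitively into units, so
a unit may span more than 10 bp end to end; the metric is the gap between
consecutive C positions (the motif-interval alternative is not used). All
coordinates are 0-based half-open; CpGs are keyed by the forward-strand C,
and reverse-strand evidence keeps its strand label.

Per unit and sample:

- rate = n_meth / (n_meth + n_unmeth), undefined when no unambiguous read;
- FRR = (n_meth + n_unmeth) / coverage, with coverage counting *all* reads
  including ambiguous ones;
- strand bias = |rate₊ − rate₋|, undefined when either strand lacks an
  unambiguous read — undefined does not fail QC (low coverage is already
  penalized by the coverage filter, failing it twice would double-count);
- every CpG site of a unit inherits the unit rate on expansion.

The sample-level methylation level pools reads, not units:
Σ n_meth / Σ (n_meth + n_unmeth).

## Quality filters

All five cutoffs are inclusive at the boundary (strand bias ≥ 0.2,
FRR ≤ 0.5, coverage ≤ 0.5× or ≥ 1.5× the dataset mean) and configurable in
`QCConfig`. Variant proximity is measured from CpG C positions (not unit
interval ends) to variant positions (VCF POS − 1; indel starts included),
window 5 bp.

Dark regions are derived from short-read pileup statistics per base: a base
is dark iff ≥ 90% of overlapping reads have MAPQ < 10 *and* depth < 5 *and*
mean base quality < 20. "On average" in the defining criteria is ambiguous
between per-base and per-region evaluation; per-base was chosen for
determinism and streaming, and the thresholds are configurable. A base with
no pileup record inside the track's span counts as depth 0 and is therefore
dark; outside the recorded span nothing is assessed (a finite track cannot
be extended indefinitely). Maximal dark runs shorter than 30 bp are dropped.

`filter_hq` reports both the any-reason partition (disjoint, exhaustive) and
per-reason tallies; a unit failing several filters counts once in non-hq and
once per reason, so reason counts may exceed the non-hq total.

## Concordance statistics

APC averages rates per CpG across each dataset's samples (unweighted over
samples with a defined rate), then takes Pearson r over the complete-case
intersection; its 95% CI uses the Fisher z-transform with SE 1/√(n−3). MAD
is the mean absolute rate difference with a normal-approximation CI
(mean ± 1.96·SE); both statistics are symmetric in their arguments.

Methylation-state categories partition [0, 1] at 0.15 / 0.5 / 0.85. The
published bin endpoints overlap; our convention is half-open bins with the
top closed, assigning a boundary value upward (0.15 → low, 0.5 → inter,
0.85 → methylated). The confusion matrix rows are reference categories,
columns the query's; correct fraction = diagonal / row sum, with
off-diagonal calls additionally histogrammed by |Δrate| (edges 0.1, 0.25,
0.5 — a reporting choice).

TSS profiles bin the signed site–TSS offset (sign flipped for minus-strand
genes) at 50 bp over ±flank; a site near several TSSs contributes once per
incidence, and no deduplication is applied. CpG counting per sample counts
sites with a defined rate, each unit contributing its site count when
expansion is requested.

## The synthetic-data generator

The generator's defaults define the study conditions used by the tests and
the acceptance script; they are fixed, not tuned per run.

| parameter | default | why |
|---|---|---|
| `coverage_mean` | 20× Poisson per unit | typical long-read WGS depth |
| gap mixture | 30% gaps in 2–10 bp, else 11–300 bp | yields both singleton and multi-CpG units under the 10-bp rule |
| `mixture_weights` | (0.2, 0.1, 0.7) | bimodal blood-like methylome, overall level ≈ 0.73 |
| `beta_params` | Beta(1,20) / Beta(5,5) / Beta(20,1) | sharp unmethylated/methylated modes, diffuse middle |
| `llr_mu`, `llr_sigma` | 3.0, 1.0 | ≈ 14% ambiguous reads at ±1.921 — a deliberately imperfect caller |
| `artifact_fracs` | 0.0375 per class (15% total) | enough artifact units for stable sensitivity estimates |
| `strand_bias_offset` | 0.5 | reverse-strand probability shifted toward the opposite mode |
| `coverage_factor` | 3× | collapsed-duplication-like pile-up |
| `corruption` | 0.5 | dark/variant reads flip template w.p. 0.5 (wrong-reference calls), pulling apparent rates toward 0.5 |

True rates are drawn **per unit** and shared by the unit's CpGs, matching
how joint callers report them. Artifact classes are assigned to disjoint
unit sets so each flag's sensitivity is identifiable; unlabelled units that
happen to fall inside an injected dark interval or variant window are
relabelled so truth labels stay consistent with the injected coordinates.
The LLR emission is a signed Gaussian — no published emission model exists,
and the Gaussian makes error rates analytic: with `llr_mu = 0` the expected
reliable-read fraction is exactly 2·Φ(−1.921/σ), which the acceptance suite
checks against simulation.

All randomness flows through `numpy.random.default_rng` (PCG64) with
explicit seeds, so drawn counts are reproducible across platforms.

What the generator does **not** emulate: sequence-dependent error and k-mer
effects, mapping and alignment, haplotype structure, correlated noise along
the genome, overdispersed coverage (Poisson by default; a negative-binomial
option exists), or the shift of extreme rates away from 0/1 seen in some
probability callers. Passing recovery tests therefore demonstrates the
correctness of the aggregation/QC/comparison machinery under the stated
noise model, not caller accuracy on real reads.

## Problem sizes and numerical choices

Recovery checks run at 15,000–20,000 CpG sites (≈ 14,000 units): per-unit
rate MAE at 100× artifact-free coverage (observed ≈ 0.02 against a 0.06
bound), truth-APC monotone over 5/10/20/40×, hq-versus-all APC at the 15%
artifact load, and per-flag sensitivity ≥ 0.9. The strand-bias filter's
false-positive rate on artifact-free 20× data is ≈ 0.11 against a 0.15
control bound — dominated by binomial sampling noise at ~10 reads per
strand, concentrated in intermediate-rate units. The closed-form FRR check
uses 10⁴ reads and a 3-standard-error band.

Ties and degenerate inputs: boundary LLR/probability values are ambiguous;
rates are undefined (not 0) without unambiguous reads; Pearson correlation
raises on zero variance or n < 3; MAD requires n ≥ 1; empty inputs raise
rather than return silent zeros, except where the contract says otherwise
(empty variant list → not near a variant; empty track → no dark regions).

## Known limitations

- Dark-region detection assumes the pileup track covers the region of
  interest contiguously; sparse tracks conservatively mark holes as dark.
- Unit CpG positions from the Nanopolish dialect rely on the context string
  containing the CG motifs; when absent, a unit degrades to its start
  position and site expansion undercounts.
- Aggregation is not haplotype-aware.
- The confusion matrix's |Δrate| error bins and the probability-caller
  cutoffs are package conventions, not published values.
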
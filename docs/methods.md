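# Methods

## Statistical model

### Permutation empirical-null differential expression

Per gene and two-group comparison we compute the classic pooled-variance
Student *t* (a `welch` option is available for unequal variances; the
default is the pooled form, read literally from "Student's t-test"). A
degenerate zero-pooled-variance case with unequal means yields the capped
sentinel ±1e6 rather than an infinity; with equal means, 0.

The null distribution of *t* is built empirically: the group labels of the
samples in the comparison (and only those samples) are shuffled, *t* is
recomputed per gene, and all permuted values — across **every gene and
every permutation** — are pooled into one sample. Pooling across genes is
the key smoothing device: with 3–4 replicates per arm a per-gene null has
only C(6,3)=20 or C(8,4)=70 support points, but 2000 genes × 70 exhaustive
assignments give a dense, stable null. The requested permutation count is
10,000; whenever the number of distinct label assignments C(n_a+n_b, n_a)
does not exceed it, all assignments are enumerated exactly (deterministic
and free of Monte-Carlo error), otherwise random shuffles are drawn without
deduplication.

The "Gaussian density estimator" applied to the pooled values is, by
default, a Gaussian-kernel KDE with Silverman's-rule bandwidth (statsmodels
FFT implementation, 4096 grid points, support extended 6 bandwidths past
the data range; the fitted density must integrate to 1 within 1e-3). An
alternative reading — a single normal fitted by moments
(`estimator="gaussian_fit"`) — is provided because the phrase is ambiguous;
KDE is the default since it preserves the heavy tails that few-replicate
*t* null distributions have. Two-tailed p-values are read from the fitted
CDF as p = min(1, 2·min(F(t), 1−F(t))), clipped strictly above 0 (the
estimator's support is unbounded). Genes with p < 0.05 and |log₂FC| > 0.58
(1.5-fold) are called differential; **no additional multiple-testing
correction is applied** — the empirical p is used raw, by design, and
downstream set sizes must be interpreted accordingly.

Numerical notes: the KDE CDF is a trapezoid integral of the FFT density,
interpolated linearly at observed *t*; because the estimator smooths a
discrete permutation distribution, at a tiny null (one gene, few
assignments) its p-value tracks the *mid-p* permutation fraction (ties at
|t| counted half) rather than the ≥-tie fraction; under the pooled null the
two coincide to well under 0.05.

### Selection cascade

* **SAG**: direction (UP/DOWN per thresholds) in old-DMSO vs young at ≥ 1
  of the three DPTs; per-DPT directions and log₂FCs are retained.
* **DAG(drug)**: a SAG that, at ≥ 1 DPT with non-NS senescence direction,
  is significant in drug-vs-DMSO with the *opposite* direction
  ("restoration"). A stricter optional mode (`restoration_mode="strict"`)
  additionally requires the residual treated-vs-young shift, estimated as
  (old−young) + (drug−DMSO) log₂FC, to be within the fold-change cutoff —
  i.e. the treated mean returned to the young level.
* **SynAG(dpt)**: a DAG(KU+Y) significant with the *same* direction in both
  KU+Y-vs-KU and KU+Y-vs-Y at that DPT (conjunction; an `"or"` mode accepts
  either comparison but still rejects conflicting significant directions).

Temporal groups label each SynAG by its (3, 8, 15)-DPT direction triple;
the seven single-direction patterns carry their conventional names (EML-UP,
ML-UP, M-UP, L-UP, E-DOWN, M-DOWN, L-DOWN) and any other non-null triple is
labelled by the triple itself, so the group count is data-driven rather
than fixed. "Major" groups must exceed `major_min` (default 10) **strictly**;
the threshold is configurable because the boundary convention at exactly 10
genes is ambiguous in practice.

### Enrichment

One-sided upper-tail hypergeometric Pr(X ≥ k), X ~ Hypergeom(N, K, n),
via the scipy survival function (log-space-stable); exactness is verified
against rational-arithmetic enumeration to 1e-10 relative for N ≤ 60. The
universe defaults to all genes on the platform (the rows of the gene-level
matrix), the testable background, not the genome. The pass rule is
p < 0.05 with overlap ≥ 3 for process collections and overlap ≥ 1 for
TF-target collections. Raw p-values are thresholded with no
multiple-testing correction, and the EASE-style modification used by some
web tools (subtracting one from the overlap) is deliberately **not**
replicated — the plain hypergeometric tail is slightly less conservative.

### Phenotype synergy (CDI)

Efficacy is the treated/control mean ratio of a positive phenotype
measurement; CDI = AB/(A·B). CDI is scale-invariant in the raw
measurements and exactly 1 under multiplicative independence. Calls:
activation (> 1), inhibition (< 1), independent (|CDI − 1| ≤ 1e-12). An
alternative efficacy mode using |log₂ fold changes| is available behind a
flag because published CDI displays are sometimes built from log-scale
summaries; the ratio mode is the default and the unlogged equivalent.

ΔΔCt: dCt = Ct_target − Ct_reference (housekeeping reference, e.g. RPS11),
ddCt subtracts the control condition, relative expression is 2^−ΔΔCt with
the control pinned at exactly 1. Ct values must lie in (0, 45).

Mitochondrial morphology: per cell, the percentage of mitochondria strictly
longer than 10 µm (count-based, not length-weighted — the rule counts
mitochondria); > 70% elongated, < 30% fragmented, boundaries inclusive to
intermediate.

### Probe summarization

Probe-level matrices collapse to gene level by keeping, per gene, the probe
with the largest interquartile range across all samples (linear-interpolation
quantiles, the common default). IQR ties break to the lexicographically
smallest probe id, making the result independent of input row order.
Unmapped probes are dropped (count logged), never guessed.

## Synthetic data generator

The generator emulates the five-arm design: `n_replicates` young samples
(dpt = 0 by convention; every young comparison pools all young replicates,
since low-passage cells are profiled once) and four senescent arms ×
{3, 8, 15} DPT. Values are baseline (uniform on [6, 12] log₂ intensity,
the typical normalized microarray range) plus planted effects plus i.i.d.
Gaussian noise (σ = 0.25 log₂ by default — a realistic replicate-level sd
for well-normalized arrays). Defaults: 2000 genes, 4 replicates, 20%
SAGs with ±2.0 log₂ senescence shift, 50% of SAGs restored at 75% of the
shift, 50% of combination-restored genes given an extra ±1.0 log₂ synergy
shift in the KU+Y arm at planted DPTs. Planted temporal patterns are drawn
from the seven major single-direction patterns with weights proportional to
the group sizes observed in the reference experiment (10 : 68 : 105 : 377 :
11 : 10 : 314), so late-timepoint patterns dominate as they do in real data.

One modeling choice matters for interpretability of the planted truth:
**restoration is a single program shared by KU, Y, and KU+Y** (the same
planted DAG set, restored by the same amount, in all three treated arms).
If each drug restored its own random gene set, the restoration
*differences* between the combination and a single drug would themselves be
significant combination-vs-single contrasts — indistinguishable from
synergy by construction — and "planted SynAG" would not be a well-defined
ground truth. With a shared program, the combination-vs-single contrasts
contain exactly the planted synergy shifts, and sensitivity/FDR against
truth are meaningful. The cost is realism: real single drugs restore
overlapping but unequal gene sets (the reference experiment's KU/Y
asymmetry), so the generator's truth-scored recovery quantifies the
statistical machinery, not the biological ambiguity of attributing a
combination-vs-single difference to "synergy" versus differential
restoration. The generator also omits array batch effects, probe-level
structure (an optional concern handled by the IQR collapse when present),
correlated noise, and secretory-phenotype panels.

A small deterministic identity links truth labels to effects: a planted
SynAG whose synergy direction coincides with its senescence direction at
*every* planted DPT partially cancels its own restoration in the KU+Y arm
(|−0.75·2.0 + 1.0| = 0.5 < 0.58 log₂), and such all-timepoint genes
(EML-pattern, ~1% of draws) can fail the DAG stage; this bounds attainable
sensitivity around 0.99, not 1.0, and is a property of the composed design,
not a bug.

## Pipeline and reproducibility

All 18 contrasts (old/young; KU, Y, KU+Y vs DMSO; KU+Y vs KU; KU+Y vs Y —
each at 3 DPTs) get their own permutation null (per-comparison nulls are
the conservative reading; a global null across arms would mix variance
structures), seeded as `seed + comparison_index`. Identical config and seed
give byte-identical outputs; the run manifest records the config echo,
seed, package versions, stage timings, the stage-count funnel, and a
SHA-256 checksum of every output file. Inputs are never mutated.

Problem sizes in the shipped analyses and validation runs (2000 genes, 4
replicates, 1000 requested permutations — exhaustively enumerated as 70
assignments for 4-vs-4 cells) were chosen so the full suite and the
validation script complete in seconds while keeping the pooled null dense;
the statistics are insensitive to raising the permutation count because
small cells are enumerated exactly.

## Known limitations

* The empirical p is pooled across genes: genes with atypical variance
  borrow the global null, which is the method's intent but can mis-rank
  individual outlier genes relative to per-gene permutation tests.
* No FDR control anywhere in the cascade — set sizes are threshold
  artifacts and should be read comparatively, not as discoveries.
* The restoration criterion is direction-based by default; the strict
  young-anchored mode composes two estimated fold changes and inherits both
  errors.
* CDI is a point-ratio synergy summary; no dose–response surface models
  (Bliss/Loewe beyond this ratio) are provided.
* The generator's shared-restoration simplification described above.
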
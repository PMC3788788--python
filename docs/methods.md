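# Methods

## Model

The package treats a patient's genome-wide normalized differential gene
expression y (genes × 1) as a linear superposition of miRNA influences:
y ≈ N β, where N is the signed target-indicator matrix (−1 where a miRNA
targets a gene, 0 otherwise) and β holds one unknown influence per miRNA.
The −1 encoding carries the biology's canonical direction — miRNAs repress
their targets — while deliberately assuming nothing about per-edge
strength: every retained interaction contributes the same unit weight.
Under this convention a *positive* fitted influence means the miRNA's
targets shifted the way they would if the miRNA itself had risen, so the
influence sign lives on the same axis as the miRNA's own differential
expression; that is what makes sign-concordance validation against
measured miRNA data meaningful.

Identifiability comes from sparsity: the elastic-net penalty
λ(α‖β‖₁ + (1−α)/2‖β‖₂²) selects a small set of miRNAs that jointly explain
the expression shift, while the quadratic term keeps groups of miRNAs with
heavily overlapping target sets from being arbitrarily thinned to a single
representative. The mixing weight defaults to α = 0.25; the method's
conclusions are insensitive to moderate changes (0.1–0.5), which is why a
single value is used everywhere.

## Normalization

Raw intensities must be strictly positive and linear-scale; the pipeline
takes log2 and standardizes per gene against the healthy cohort:

    Y[g,p] = (log2 E[g,p] − μ_H[g]) / (σ_H[g] + w·σ_C[g] + s0)

* μ_H, σ_H — mean/SD of log2 expression over healthy controls (n ≥ 2);
* σ_C — SD over the tumour cohort (m ≥ 2), weighted by w (default 1).
  Including it damps genes that vary wildly between patients for reasons
  unrelated to the contrast of interest;
* s0 — additive stabilizer (default 0.1, unitless on the log2 scale)
  guarding against near-zero denominators. A constant is used rather than
  a data-driven percentile procedure; the alternative exists in the
  literature on moderated t-like statistics but adds a data dependence the
  rest of the pipeline never needs.

SDs use the n−1 denominator. The log base is a pure convention: it cancels
in every sign and is absorbed by rescaling s0.

## Penalty selection

The regression's observations are genes, so cross-validation partitions
*genes* into K = 10 seeded random folds. The penalty path has 100
log-spaced values from λ_max = max_j |N_jᵀy|/(n·α) (the smallest penalty
with an all-zero solution) down to 10⁻³·λ_max. Per patient the selected λ
minimizes the fold-mean held-out squared error; ties break toward the
larger (sparser) penalty because the path is scanned in descending order.
A one-standard-error rule (`lambda_rule="1se"`) is available; in noise-free
simulations the two rules select nearly identical penalties because the
fold errors' standard errors collapse, and "min" is the default.

The cohort is then refit at the arithmetic mean of the per-patient
selections. A shared penalty makes per-patient sparsity patterns
comparable, which the consensus step implicitly assumes.

Objective scaling is 1/(2n)·RSS + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), so λ is
comparable across gene spaces of different size. No intercept is fitted
(the normalization already centres each gene on its healthy mean) and
predictor columns are not re-standardized (they are −1/0 indicators on a
shared scale; a `standardize` switch exists for users who want the
variance-rescaled convention some solvers apply by default). Fits are
solved by coordinate descent to a duality-gap tolerance of 1e-7; the
cross-validation loop performs plain cold-start fits per (fold, λ) through
the same routine used everywhere else — with the fold's Gram matrix
precomputed, which changes speed but not results — so its error curve is
exactly reproducible by an independent loop.

## Consensus, validation, permutation test

A miRNA is called active when its fitted influence is nonzero *with the
same sign* in more than `consensus_fraction` of all patients (default 0.7;
the threshold must exceed 0.5 so at most one sign can qualify, and the
comparison is strict). Patients with an exactly zero coefficient count
against the fraction. miRNAs excluded from the regression because none of
their targets appear in the measured gene space are reported separately as
not assessable — absence from the call list is not evidence of inactivity.

Validation compares each call's sign with the observed miRNA differential
expression: the fraction of measured patients with a strictly matching
sign must exceed `validation_fraction` (default 0.7). Zero measurements
count as discordant — the strict reading; it can only make validation
harder. miRNAs absent from the measurement platform are kept but flagged
unmeasured.

Set-level significance: each permutation draws |calls| measured miRNAs
without replacement, assigns independent fair-coin signs, and applies the
identical validation rule. The p-value is
(#{permutation rate > observed rate} + 1)/(n_permutations + 1); the +1
correction keeps the estimate away from exactly zero, and the uncorrected
proportion is available via `plus_one_correction=False`. Draws come from
the *measured* miRNA universe, matching what the observed calls are
validated against. 10,000 permutations by default.

## Simulation framework

The generator reproduces the statistical structure the model assumes:

* `n_active` miRNAs (default 30) drawn uniformly are planted with signed
  mean differential expression — magnitude Uniform(1, 3), sign by fair
  coin; all other miRNAs get mean 0;
* each of `n_patients` (default 100) receives miRNA DE ~
  Normal(mean, patient_sd = 0.5) independently per miRNA;
* gene DE = N × (miRNA DE vector), exactly.

The planted magnitude floor of 1 is twice the patient spread, encoding the
premise that truly active miRNAs are *consistently* differentially
expressed; it is configurable.

Four perturbations emulate real-data corruption. Edge addition/removal
(fractions of the edge count, floor-rounded; additions drawn uniformly
from absent pairs) applies to the network used for *generation* only —
inference always sees the original network, so added edges model
information missing at inference and removed edges model incorrect
information trusted at inference. Diffusion leaks signal along a symmetric
gene–gene graph: Y′ = Y + γÂY + γ²Â²Y with Â the row-normalized adjacency
(zero-degree rows stay zero); row normalization keeps the perturbation's
scale interpretable as a fraction γ of a neighbour average, since the raw
adjacency's spectral radius would make the series explode for any useful
γ. Expression noise adds Normal(0, ν·|y|) per entry (variance, not SD —
ν = 1 is Poisson-like); exact-zero entries use the cohort mean |Y| as the
variance anchor so silent genes stay noisy the way measurements do.

Synthetic networks are scale-free-like: heavy-tailed (Pareto) per-miRNA
target counts rescaled to a median of 4% of the gene universe and clipped
to [1%, 30%], with heavy-tailed gene popularity — mirroring curated target
networks, where the median miRNA targets a few percent of genes and hub
genes attract many miRNAs. The gene–gene graph for diffusion is a random
symmetric graph with mean degree 10, matching the edge density of curated
protein-interaction subsets at this gene count.

What the generator does *not* emulate: raw intensity scales (it produces
normalized DE directly), copy-number-driven expression shifts, batch
effects, or tumour purity gradients. Passing recovery tests therefore
demonstrates correctness of the estimator under its own model plus the
four noise channels, not performance on any particular platform's data.

## Experiment scales used in the test suite

The reference experiment (711 miRNAs, 16,799 genes, 30 active, 100
patients, 1,000 replicates) is scaled down so the full suite runs on one
CPU in minutes: the noise-free recovery experiment uses 20 cohorts of 50
miRNAs / ~2,000 genes / 5 active / 50 patients, and the robustness
comparisons use 40 miRNAs / 1,000 genes / 5 active / 20 patients with 20
seed-paired replicates per arm. Two statistical consequences of the
scale-down are worth knowing. First, with 50 patients the consensus rule
(> 0.7 of the cohort, i.e. ≥ 36/50 same-sign) lets an inactive miRNA
through with probability ≈ 2.6×10⁻³ (versus ≈ 1.6×10⁻⁵ at 100 patients),
so a cohort of 45 inactive miRNAs produces a spurious extra call roughly
once in nine cohorts — exact-recovery rates near 0.9 at this scale
correspond to near-perfect recovery at the reference scale. Second, at
planted magnitudes ≥ 1 the per-patient influence signs of active miRNAs
are extremely stable, so *sensitivity* barely degrades under moderate
noise (γ = 0.3, ν = 1.0) at any cohort size — degradation shows up first
in precision.

## Numerical and degenerate-input conventions

* λ = 0 is solved by least squares, not coordinate descent.
* A response exactly orthogonal to all columns (λ_max = 0) yields an
  all-zero path and an all-zero fit.
* "Nonzero" coefficients are exact floating-point nonzeros — coordinate
  descent produces exact zeros by soft thresholding, so no magnitude
  cutoff is imposed.
* Fold assignment, cohort sub-seeds, and permutation draws all derive from
  explicit integer seeds (`numpy` SeedSequence); identical inputs and
  seeds give bit-identical outputs, including written files.
* Expression input must be strictly positive and complete; missing values
  are rejected rather than imputed.

## Known limitations

Tumour purification is out of scope — matrices are consumed as given.
Gene/miRNA identifiers are matched as exact strings against the network's
vocabulary. The gene–gene interaction network appears only as a simulation
noise source, never in inference. The permutation test is set-level; no
per-miRNA multiple-testing correction is attempted. CNV and other
non-miRNA drivers of expression change are unmodelled, so on real data the
method attributes to miRNAs whatever portion of the expression shift their
target pattern can explain.
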
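# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic benchmarks emulate,
and the numerical conventions that matter for reproducing a run.

## Model

### Feature channels

Two complementary molecular representations are used. The binary channel is
a hashed path fingerprint (RDKit topological fingerprint, 1024 bits by
default); the continuous channel is the RDKit 2-D descriptor set. Both are
pluggable: any binary matrix and any real matrix with consistent row order
can be supplied directly, which is how the synthetic benchmarks exercise the
full pipeline without chemistry. Continuous descriptors are standardised
**per feature across the whole training ligand collection** (not per ligand
set): similarities must be comparable across targets, which per-set scaling
would destroy. Constant or non-finite descriptor columns are dropped and
recorded; the training moments are stored and reapplied verbatim to query
molecules.

### Enrichment weighting

For target *j* with ligand set *S<sub>j</sub>* and the full training library
*B* as background, each binary feature gets the one-sided Fisher exact
p-value of over-representation from the 2×2 table
(bit on/off) × (in *S<sub>j</sub>* / in *B* \ *S<sub>j</sub>*) — computed as
the hypergeometric upper tail, vectorised over bits. Each continuous feature
gets the two-sided Wilcoxon rank-sum p-value of *S<sub>j</sub>* against
*B* \ *S<sub>j</sub>* (exact null when both groups have ≤ 8 tie-free
samples, tie-corrected normal approximation otherwise). P-values are
adjusted with Benjamini–Hochberg; the weight map is

w(q) = −log₁₀ q  for q < 0.05,  0 otherwise.

It is zero at and above the significance threshold and strictly decreasing
in q below it, so feature influence tracks the strength of evidence. By
default every feature with positive weight is retained; `m_features` caps
the selection at the top-m (ties broken by ascending feature index), and
`optimize_feature_count` grid-searches m against a retrieval objective.

A bit absent from the entire library gets p = 1; an ensemble with **no**
significant feature on a channel carries no evidence there and its pairs
receive Z = 0 on that channel rather than a floored-σ artefact that would
vary with set size alone.

### Similarity, raw score, S_cut

Binary-channel similarity between two molecules is the weighted Tanimoto
coefficient on the selected bits; continuous-channel similarity is the
cosine of the weight-scaled descriptor vectors with negative values clipped
to zero, so both channels live on (0, 1) and share one cutoff domain. Where
the weights enter the cosine (w∘x rather than √w∘x) is a convention; the
elementwise form is used. The raw score of a query against an ensemble sums
every pairwise similarity ≥ *S*<sub>cut</sub>; scores below the cutoff are
discarded. *S*<sub>cut</sub> is global per channel, selected by scanning the
grid {0.01, …, 0.99} for the maximum ROC AUC of the resulting Z-scores over
the labeled training pairs (ties resolve to the smallest value). Training
scores used in this scan are *self-excluded*: a positive pair's query never
counts its own identity similarity, so the scan reflects held-out geometry.

### Null calibration and Z-scores

For each target, `n_random` = 50 ligands are drawn without replacement from
the full library (per-target deterministic seeds derived from the global
seed and a CRC of the target id, so results are independent of iteration
order). Their raw scores against the ensemble give a null mean and standard
deviation; ordinary least squares across targets of these moments against
ligand-set size yields μ(size) = α₁·size + β₁ and σ(size) = α₂·size + β₂
(fit diagnostics R² are stored). Z = (raw − μ)/max(σ, 10⁻⁶); the floor
guards the regression's possible non-positive predictions at small sizes.
The regression is fitted at the selected operating cutoff; the scan keeps
the full per-cutoff table internally. Set sizes must include at least two
distinct values or the design is singular (fatal).

### Bayesian fusion and thresholds

The hybrid model fits one Gaussian KDE with a full 2×2 bandwidth matrix
H = f²·Cov(points) per class over the pooled (z₁, z₂) scores (Scott's
factor n^(−1/6) by default; Silverman and fixed-H available; a singular
covariance falls back to a floored diagonal). The likelihood is the
posterior L = π₊f₊/(π₊f₊ + π₋f₋) with empirical class priors (uniform
optional); where both densities underflow, the prior is returned with a
warning. Decision thresholds — per-channel Z thresholds and the hybrid θ —
are all chosen by the same scan: maximise F1 over the observed score
values, calling a pair positive when score > threshold, ties resolved to
the smallest threshold.

### Leave-one-interaction-out protocol

LOOCV holds out one labeled *interaction* at a time. A held-out positive is
removed from its target's ensemble and everything downstream of membership
is refit exactly for that target: enrichment p-values, weights, feature
selection, the null moments (same random draw, reduced ensemble) and the
null regression with that target's point replaced. The global ligand
library — the enrichment background and the random-null pool — is a fixed
resource, and the cutoffs, thresholds and KDEs are selected once on the
pooled held-out scores, which is also how the training protocol defines
them. Negatives never enter ensembles, so their scores coincide with the
full model's. A target reduced below two ligands by exclusion is scored
anyway and flagged.

## Synthetic benchmarks

The generator plants the exact structure the method assumes, so every stage
has unambiguous ground truth. Each target receives a random signature of
`n_signature_bits` fingerprint bits, switched on in its ligands with
probability `p_on` against a global background rate `p_bg`, and
`n_signature_desc` descriptors shifted by `desc_effect` standard deviations.
Background molecules are pure background; negatives pair targets with
background molecules, one per positive. Ligand-set sizes vary uniformly
within ±50% of the nominal `ligands_per_protein` (minimum 5) so the
size-vs-null-moment regressions are identifiable, as they are on real
corpora. All randomness derives from a single seed through SeedSequence
spawning, one stream per generation stage.

Defaults — 50 targets, nominally 20 ligands each, 400 background molecules,
B = 1024 bits with 30 signature bits at p_on = 0.6 vs p_bg = 0.05, D = 128
descriptors with 10 shifted by 1.5 sd — define the standard desk-scale
benchmark: a strong but not saturated signal in both channels at a size the
full LOOCV completes in well under a minute. The no-signal control sets
p_on = p_bg and desc_effect = 0.

**What the generator does not emulate:** real chemistry (valence,
synthesizability), correlated fingerprint bits from shared substructures,
heavy-tailed affinity distributions, and protein families with overlapping
ligand sets. Passing tests therefore demonstrate the statistical machinery
— enrichment detection, size calibration, fusion, threshold selection —
under the model's own assumptions, not performance on any real corpus.

### Scaffold-hopping scenario

The contrast with the 1-nearest-neighbour baseline needs ligand sets where
ensemble evidence and nearest-neighbour evidence genuinely diverge. In the
scenario configuration each target's set is mostly one dense analog series
(140 signature bits at p_on = 0.95 on a 512-bit space), plus 15%
*scaffold-unique* members that carry only the small shared signature core
(4% of the signature) and their own private bits drawn outside it — held
out in LOOCV, nothing similar remains in their ensemble, so their best
single-molecule Tanimoto is low while the core bits and the
cluster-independent descriptor signature still mark them at the ensemble
level. A quarter of the background is "dense" material with an elevated bit
rate (0.30), the synthetic analogue of the promiscuous, substructure-rich
molecules that produce spurious high-Tc nearest neighbours in real
screening libraries; they pin the 1NN baseline's F1-optimal threshold above
the hop range. The multi-cluster generator mode (disjoint private signature
subsets per cluster with a shared core) remains available for constructing
explicit two-cluster sets.

## Numerical conventions and degenerate inputs

- Similarities with empty weighted OR-support or zero-norm weighted vectors
  are 0 by convention, with a warning.
- Tie-breaking is deterministic everywhere: ascending feature index in
  selections, smallest candidate in m and cutoff grids, smallest threshold
  in F1 scans.
- The Wilcoxon path warns (low power) for single-ligand sets; zero-variance
  features get p = 1.
- BH q-values are clipped to [0, 1]; q = 0 is floored at 10⁻³⁰⁰ before the
  logarithm.
- Fingerprint matrices are validated to be strictly {0, 1}; bit counts are
  promoted to signed integers before tail computations.
- Serialisation is a version-stamped JSON container (fingerprints packed as
  hex, weights stored sparsely); loading an unknown version is refused, and
  a reloaded model reproduces in-memory predictions bit-for-bit.

## Design choices where the design was open

- **Multiple-testing adjustment:** Benjamini–Hochberg, the standard
  q-value-producing procedure; pluggable.
- **Continuous-channel similarity:** weighted cosine with negative clip, so
  both channels share the (0, 1) cutoff domain the grid scan assumes.
- **Global vs per-target S_cut:** global per channel — the null regressions
  pool targets at a common cutoff, implying one shared operating point.
- **KDE scope:** one global KDE pair over pooled scores rather than one per
  target; per-target score counts would be far too small for 2-D density
  estimation.
- **Priors:** empirical class frequencies (the training design is balanced,
  so this is ≈ uniform); configurable.
- **θ vs Z threshold:** both are selected by the same highest-F1 criterion;
  they are not numerically tied to each other.
- **Default feature count:** all features with positive weight, rather than
  a per-target optimisation in every LOOCV fold; the optimisation operation
  is exposed separately for explicit use.

## Problem sizes

The shipped benchmarks are desk-scale by choice: the default corpus is ~960
positives + equal negatives over 50 targets (full LOOCV in ~30 s on one
CPU), the scaffold-hop corpus ~380 positives over 12 targets. The pipeline
itself is vectorised per target and ingests arbitrarily larger
BindingDB-style corpora through the same interfaces.

## Known limitations

- The hashed-path fingerprint and RDKit descriptor set stand in for other
  engines' feature definitions; channel semantics, not the exact feature
  list, are what the method requires. Engine name and parameters ride along
  in the model file.
- The null is a single random draw per target (seed-recorded); replicate
  draws would tighten the moment estimates at small set sizes.
- With very few significant features the weighted similarity becomes
  coarse-grained and Z-scores degenerate toward ties; the Z = 0 convention
  keeps this honest but such targets are effectively unpredictable.
- The incremental LOOCV refit treats the ligand library as fixed; removing
  a held-out ligand from the global background as well would change every
  target's enrichment tables at quadratic cost for a vanishing effect at
  realistic library sizes.
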
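# Methods

`bindstack` re-implements, as a self-contained offline toolkit, the
meta-prediction approach to protein DNA-binding residue identification:
structure-derived gold-standard labelling, stacking of six sequence-based
base predictors with an RBF-kernel support-vector machine, residue-level
cross-validated evaluation under heavy class imbalance, and a
structure-aware false-positive filter. The six original base predictors were
public web servers (DISIS, DNABindR, BindN, BindN-rf, DP-Bind, DBS-PRED),
several of which are no longer reachable; this package therefore replaces
live queries with a file-based track interface plus a statistical simulator,
and validates the surrounding machinery against closed forms, brute-force
oracles, and the published results table's internal arithmetic.

## Gold-standard annotation

**Distance criterion.** In a protein–DNA complex, a residue is a binding
site when the minimum Euclidean distance between any of its atoms and any
atom of the DNA is *strictly less than* a cutoff. The default cutoff is
3.5 Å; 3.5–6.0 Å are all in literature use, and labels are provably nested
in the cutoff (the mechanism behind the sensitivity trend when the
definition is widened). Distances are found with a k-d tree but are
required — and tested — to agree exactly with the all-pairs scan.

**Buried-surface criterion.** Residue solvent-accessible surface area
(SASA) is computed for the protein alone and for the protein in the
presence of the DNA atoms; a residue whose SASA drops by at least 1 Å²
(absolute mode) or at least 1% of its unbound area (relative mode) is a
binding site. The two published descriptions of this threshold conflict
(1 Å² vs 1%), so both modes exist and neither is claimed as the original
setting; absolute 1 Å² is the default.

**SASA engine.** Shrake–Rupley with a golden-spiral (Fibonacci) point
lattice: deterministic, no random state, bit-reproducible. Defaults: probe
1.4 Å, 960 points per atom, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 /
P 1.80 / H 1.20, fallback 1.80 Å. A lattice point is buried when strictly
inside a neighbour's solvent-expanded sphere. Because both states of the
ΔASA computation reuse the same lattice, ΔASA ≥ 0 holds exactly. Accuracy
is checked three ways: the isolated-sphere closed form 4π(r+probe)² (≤1%
at 960 points), an independent random-direction Monte-Carlo oracle at 100×
point density (≤2% of sphere area on random 20-atom clusters), and
Bio.PDB's implementation on identical radii. One geometric point worth
recording: two equal spheres at near-zero separation each retain about
*half* their area (the far hemisphere is outside the neighbour), not zero;
the tests assert the Monte-Carlo-verified half-area limit.

**Structure model.** PDB parsing is delegated to Bio.PDB behind a typed
model (atoms → residues → chains → complex). Policies: first model of
multi-model files (an explicit choice; `model_policy=None` turns it into an
error), alternate locations resolved to the highest-occupancy conformer
with ties broken by altloc identifier, HETATM excluded unless whitelisted
(waters and ligands must not create false contacts), hydrogens kept (the
any-atom definition makes no exclusion) with an optional strip flag.
Residue numbering follows the source file; prediction tracks use 0-based
indices, and the reader emits the chain map that ties the two together.

## Feature encoding

Each residue is a six-vector, one column per registered predictor in fixed
order: `disis, dnabindr, bindn, bindn_rf` (continuous scores) and
`dpbind, dbs_pred` (binary calls encoded +1/0). The four score scales are
heterogeneous and undocumented, and the downstream RBF kernel is
scale-sensitive, so scoring columns are min–max normalized to [0, 1] per
track by default (raw pass-through available); an all-constant column maps
to the neutral 0.5. A predictor with no output is imputed with the neutral
constant 0 and flagged in the availability mask, preserving the six-column
width — mirroring how the original serving pipeline simply dropped failed
servers.

## The stacker

A C-SVM with RBF kernel on the six features; labels +1/−1. The benchmark
imbalance (5342 positive vs 67396 negative residues, ~1:12.6) would drive
the margin towards the all-negative solution, so each *training* set is
rebalanced to 1:1 by uniformly discarding negatives; positives are never
dropped, and held-out folds are never resampled. Evaluation is 10-fold
cross-validation: per-fold confusion counts at natural imbalance, pooled by
summation before computing metrics. Fold units are residues by default, as
in the original protocol; protein-level folds (no protein spanning folds)
are available and recommended when leakage between residues of one protein
is a concern.

Hyperparameters (C, γ) are selected per training set by an internal
stratified cross-validated grid search maximizing strength. The grid spans
C ∈ 2⁻³…2⁷ and γ ∈ 2⁻⁷…2³ in log₂ steps of 3 (4×4 grid), selection uses
3-fold internal CV on at most 2000 stratified-sampled rows, and the chosen
setting is refit on the full undersampled training set. These selection
economies were chosen so that a fully grid-searched 10-fold CV of the
default simulation (20 000 residues) completes in well under a minute per
replicate on one core; on that simulation the selected models are
indistinguishable in pooled strength from a 6×6-grid, 5-fold-selection run.
Undersampling happens once per fold, not per grid point. The decision
threshold is the sign of the SVM decision value; no probability
calibration. All randomness (undersampling, folds, internal shuffles)
derives from one seed through `numpy.random.SeedSequence`, making every CV
bit-reproducible.

## Evaluation measures

accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
strength = (sensitivity+specificity)/2, MCC, and F-measure
(harmonic mean of precision and sensitivity). Metrics with a vanishing
denominator are reported as NaN and flagged, never coerced to 0. Counts are
reals so that a published table row can be inverted: TP = sens·P,
TN = spec·N with the published class totals P = 5342, N = 67396. Rounding
for table comparison is half-up to two decimals.

This reconstruction validates the adopted formulas against the published
seven-method comparison: strength and MCC reproduce all seven printed rows,
and accuracy six of seven. The remaining cell (DBS-PRED accuracy, printed
0.75) is internally inconsistent with its own printed rates — every
sensitivity/specificity pair rounding to 0.53/0.76 yields accuracy ≤ 0.748 —
plausibly a typo or a per-method evaluation subset; the corresponding check
is left failing rather than special-cased. Reconstructed F-measure drifts by
±0.01 on five of seven rows, consistent with the original values having
been computed from unrounded internal rates; only the meta-predictor row is
asserted.

## Spatial post-filter

Predicted binding residues are clustered by single linkage on their CA
coordinates (two sites link when ≤ `link_distance` apart; coincident CAs
link at 0), and components smaller than `min_cluster_size` are discarded as
presumed false positives. The original report gives no algorithm or
parameters ("tried several"); single linkage under a distance threshold is
the minimal parameterization consistent with the description, with defaults
8 Å / 3 residues exposed as configuration. Since the filter can only remove
predicted positives, specificity never decreases and sensitivity never
increases on any labelled set — a theorem, tested as such, and exactly the
trade-off reported for the original post-process. Components are tested
against a brute-force union-find oracle.

## The simulator

**Toy complexes.** DNA is a pseudo-atom helical trace (rise 3.4 Å, twist
36°, backbone radius 9 Å — not chemically complete nucleotides); each
protein residue is a CA plus a side-chain pseudo-atom placed on the outward
radial ray of one helix atom so that its minimum distance to the DNA equals
a scripted value (fidelity ≤ 0.05 Å, verified by brute force). This gives
exact, constructed ground truth for distance labels and for SASA occlusion,
which is all the annotation code observes; it does not emulate real
protein/DNA chemistry, side-chain packing, or sequence-structure coupling.

**Predictor tracks.** Class-conditional Gaussian scores with one shared
latent factor: s = μ(class) + σ(√ρ·z + √(1−ρ)·ε). The loading ρ sets the
between-predictor correlation — the realistic obstacle to stacking gains —
and defaults to 0.4, a moderate value reflecting that the real servers
share much of their input information (conservation profiles, predicted
secondary structure). Default class separations put the six single-predictor
strengths at 0.59–0.75, the band spanned by the six published base methods,
with four scoring and two binary (midpoint-thresholded) tracks; labels are
i.i.d. Bernoulli at the benchmark's positive fraction 5342/72738. What
passing stacking tests on this simulation shows is that the pipeline
extracts the available complementary signal under realistic imbalance and
correlation; it does not certify performance on real proteins, where errors
are sequence-structured rather than exchangeable and predictor failures are
not at random.

## Problem sizes and numerical choices

The stacking-dominance check runs the full pipeline at 20 000 residues per
replicate (positives ≈ 1470, matching the benchmark imbalance), ten
replicates in the test suite and three in the acceptance script; the
chance-calibration check pools ten 600-residue balanced null replicates,
where the pooled strength estimator has a standard error of ~0.006. Fold
sizes differ by at most one unit by construction. Ties in the
highest-occupancy altloc rule go to the lexicographically first identifier;
ties in the hyperparameter search go to the first grid point in cost-major
order. Degenerate inputs (no positives, single-class training sets,
all-zero confusion matrices, empty tracks) raise errors rather than
returning conventional values.

## Known limitations

- The original 316-complex structure benchmark and live base-predictor outputs are not
  reconstructable offline, so absolute published performance (e.g. the
  meta-predictor's 0.77 sensitivity) is validated only at the level of its
  internal confusion-matrix arithmetic, not re-measured.
- The simulator's exchangeable Gaussian scores are a deliberately minimal
  model; real per-server biases (e.g. one server failing on whole proteins)
  are representable only through the availability mask.
- Toy complexes use pseudo-atoms; SASA values on them are internally
  consistent but not comparable to real protein areas.
- mmCIF, assemblies, and resolution-based dataset filtering are out of
  scope.
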
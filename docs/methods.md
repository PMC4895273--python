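# Methods

## The learner

`GradientBoostedRSA` implements stagewise gradient boosting of regression
trees for a target in [0, 1]. The fit starts from the constant minimizer of
the loss over the training labels (mean for squared error, median for the
Huber loss — the Huber minimizer's small-δ limit, used because δ is not yet
defined before the first iteration). Each of the M stages then:

1. computes the residuals r_i = y_i − F_{m−1}(x_i) and, for the Huber loss,
   the transition point δ_m as the `huber_alpha` quantile (default 0.9,
   numpy's linear-interpolation convention) of |r|, floored at 1e−12 so a
   perfect fit keeps a valid loss;
2. forms the pseudo-residuals (negative loss gradient): r_i clipped to
   [−δ_m, δ_m] for Huber, r_i itself for squared error;
3. fits a CART regression tree to the pseudo-residuals by exhaustive
   least-squares split search;
4. replaces every leaf's value by the exact minimizer of that leaf's loss
   over a constant shift: the mean residual for squared error, and for the
   Huber loss the root of the piecewise-linear gradient
   g(u) = Σ_i clip(u − r_i, −δ_m, δ_m), found by scanning the breakpoints
   r_i ± δ_m (a flat zero plateau, possible when every residual is clipped,
   resolves to its midpoint). Because each leaf receives its own exact
   line-search constant, a separate global stage weight would be redundant —
   the per-leaf constants dominate any single scalar multiplying the tree;
5. updates F_m = F_{m−1} + ν · (leaf update), ν the shrinkage.

Per-stage total loss (measured at that stage's δ_m) is non-increasing: the
leaf updates minimize the loss leaf-wise at full step, and convexity of the
loss along the segment from no step to full step makes any ν ∈ (0, 1]
non-increasing as well. The test suite asserts this at 1e−9.

There is no stochastic subsampling; training is deterministic given the
data and hyper-parameters, and two identical fits serialize to identical
JSON documents.

### Trees

Splits are scanned exhaustively over every feature and every midpoint
between consecutive distinct sorted values; the split with the largest SSE
reduction wins, ties breaking to the lowest feature index and then the
lowest threshold, which fixes the tree uniquely. Leaves respect
`min_samples_leaf` (default 5) and the depth cap (default 4; the tree size
is deliberately a small fixed cap, as is conventional for boosting weak
learners). Each column's sort order is computed once per fit and
partitioned stably down the tree, so node split searches cost O(n·p)
rather than O(n log n · p).

Feature importance is the total SSE reduction of all splits using a
feature, summed over stages and normalized to 1 — the standard
impurity-reduction importance for boosted trees.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `n_stages` (M) | 800 | boosting iterations; the benchmark grid-search optimum |
| `learning_rate` (ν) | 0.1 | shrinkage per stage |
| `loss` | huber | robust to label noise from crystal-structure artefacts |
| `huber_alpha` | 0.9 | quantile of abs residuals setting δ each stage |
| `max_depth` | 4 | tree size cap |
| `min_samples_leaf` | 5 | minimum residues per leaf |
| `clip_predictions` | True | outputs clamped to the RSA range [0, 1] |

## Labels

RSA = ASA / maxASA, clamped to [0, 1] (real structures occasionally exceed
the tripeptide maximum). ASA comes from the fixed-column `ACC` field of
classic DSSP files; chain-break rows are skipped and lowercase
half-cystine codes map to C. The default maxASA table is the Rost & Sander
(1994) Gly-X-Gly lineage; published tables differ by a few percent per
residue type — which shifts MAE systematically — so every output records
the table's name and a custom `MaxAsaTable` can be supplied. Two-state
labels use *buried iff RSA < threshold*, strict at the boundary, with
exposed as the positive class for MCC (MCC magnitude is class-symmetric;
only the sign convention needed fixing). A confusion matrix with any zero
marginal yields MCC = 0 by the usual convention, and all reported MAE/RMSE
are percentages (fractions internally, ×100 only at the reporting
boundary).

## Features and encoding

Per-residue tracks are parsed from the standard text outputs: PSI-BLAST
ASCII PSSM (20 integer log-odds columns; the information-per-position
column doubles as the conservation signal), PSIPRED `.ss2` (C/H/E
probabilities), and a whitespace-delimited disorder track
(disordered/ordered probabilities; a single-column dialect is
complemented). Parsers validate lengths against the FASTA sequence and
report the offending file and line.

Design choices where the encoding was genuinely open:

* **Conservation score.** No explicit formula accompanies the feature's
  description beyond its PSI-BLAST origin; the PSSM information-content
  column is the natural per-position conservation measure, so it is used
  directly, min-max scaled with bounds learned on the training set (stored
  in the model bundle; test-time values clip to [0, 1], a constant column
  maps to 0.5). It is windowed over L positions like the other local
  features for consistency; a scalar variant is available
  (`windowed_conservation=False`).
* **Side-chain environment at prediction time.** The six-class definition
  needs RSA and the polar fraction F, both unknown for a query sequence.
  The encoder therefore estimates, from the labelled training proteins, an
  add-one-smoothed propensity table (amino-acid type × 6 classes, rows
  summing to 1) and encodes every residue by its type's row — a
  sequence-only proxy that re-estimates inside every CV fold. Residues with
  letters outside the 20 canonical types fall back to the uniform 1/6
  vector. The polar fraction for training labels comes from a sidecar TSV
  (id, index, F), since computing it from atomic coordinates is outside
  this package's scope.
* **Terminus padding.** Window slots beyond the chain take neutral values:
  0.5 for logistic-normalized PSSM (the image of a zero log-odds), 1/3 for
  the three-state secondary structure, 0.5 for disorder and conservation.

With all families enabled the design matrix has 26·L + 6 columns; every
encoded value lies in [0, 1].

## Cross-validation and model selection

Folds are formed over proteins, never residues: windowed features of
neighbouring residues share content, so residue-level splits would leak
held-out labels into training. Fold assignment is a seeded permutation of
the protein ids dealt round-robin. All training-set state (SCE
propensities, conservation bounds) is re-fitted inside each fold. The grid
search evaluates every M of the stage grid from a single fit per
(fold, L) by truncating the stage list — boosting is stagewise, so the
truncated model is bit-identical to one trained with that M (asserted in
the tests). Selection minimizes pooled CV MAE (PCC selection available),
ties breaking to smaller M then smaller L, i.e. the cheaper model.

A trained deliverable is a `ModelBundle`: boosted model, fitted encoder
state, maxASA table identity and report thresholds, serialized to a single
versioned JSON document that round-trips losslessly (Python float repr is
shortest-round-trip).

## Synthetic fixtures

The generator emulates the *shape* of the real inputs, not their
statistics: each residue carries a latent exposure code c_i ~ U(0, 1); the
true burial signal is the ±`window_span` (default 3) moving average of c,
stretched by 1.8 around 0.5; the label is that signal plus N(0, `noise_sd`)
clipped to [0, 1], with the default noise_sd 0.05 chosen as a plausible
label-noise scale for crystallographic RSA. PSSM column 0 encodes c
(quantized to integers like a real PSSM), helix/strand probabilities fall
and the disorder probability rises with c (disordered regions are highly
exposed), the information content falls with c (conserved residues are
buried), and the polar fraction is drawn anti-correlated with
Kyte–Doolittle hydropathy. DSSP-style files are written in a minimal
dialect carrying exactly the columns the parser reads, with integer
ACC = round(RSA·maxASA) — the only quantization between planted and
recovered labels. All values are rounded to the precision written to disk
so in-memory records equal their re-parsed files byte for byte, and one
seeded generator drives everything (identical specs ⇒ identical bytes).

Because the label depends on the neighbourhood of c while each residue's
tracks encode only its own c_i, a window of at least 2·span + 1 = 7 is
needed to see the whole signal — the grid search demonstrably prefers
L = 7 over L = 3 on these fixtures. What passing these tests shows is that
the pipeline recovers a planted monotone sequence-to-burial map through the
real file formats and protocol; it does not show benchmark-level accuracy
on real proteins, whose feature-label relationship is far noisier and not
monotone in any single channel.

## Problem sizes and numerical notes

The test suite and the acceptance script run desk-scale versions of the
protocol, chosen once as the package's study conditions: ~2000 residues
(20 proteins of 80–120 residues) with M = 300, ν = 0.1, depth 4 for signal
recovery and the null control; 10 proteins of 40–60 residues with small
(L, M) grids for protocol checks; and a noise ladder {0.02, 0.1, 0.3} at
~1200 residues, M = 60 for the degradation property. Tolerances: staged
predictions match a naive reference at 1e−10 (squared loss); Huber leaf
updates match 1e−4-step grid minimizers at 1e−3; per-stage loss decrease
is asserted at 1e−9; metric implementations match independent computations
at 1e−12.

## Known limitations

* Real benchmark accuracy requires real datasets plus PSI-BLAST profiles
  against nr; nothing here substitutes for that evaluation.
* The side-chain-environment proxy collapses to a per-type lookup; residues
  of the same amino acid are indistinguishable in that block.
* Huber boosting with exact leaf updates is O(n log n) per leaf in the leaf
  size for the breakpoint scan; for very large leaves the squared loss is
  faster.
* No missing-data handling inside tracks: a residue either has all enabled
  tracks or its protein fails validation (permissive loading skips whole
  proteins, not residues).
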
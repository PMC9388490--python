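# Methods

This note records what `protqa` computes, the choices made where the
design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Scores and superposition

GDT at cutoff j is the maximal fraction of corresponding residues that
some rigid superposition brings within j Å. Correspondence is
positional: the PDB residue number is read as the 1-based index into the
target sequence (the convention of CASP server models); no sequence
alignment is attempted, and residues carrying insertion codes are
rejected. GDT_TS averages cutoffs {1, 2, 4, 8} Å, GDT_HA {0.5, 1, 2, 4} Å.

**Denominator.** The fraction's denominator is the full target sequence
length by default, not the common-residue count: this makes coverage an
upper bound on GDT_TS against the native structure, which the feature
set relies on. `denominator="common"` restores the common-count
convention where both are wanted.

**Search.** Maximizing the within-cutoff count over superpositions is
combinatorial, so a deterministic seeded search is used (see
`protqa/_gdt.py`): Kabsch superpositions seeded from every contiguous
common-residue window of lengths 3, 5 and 7 plus the all-common fit,
refined per cutoff by up to 10 rounds of select-within-j /
re-superpose; a peel-off trajectory (drop the farthest residue,
re-superpose, repeat) covers balanced subsets that local refinement
misses. When the common set has ≤ 10 residues the windows are replaced
by every residue triple and quadruple, making the search
near-exhaustive at negligible cost. Every superposition examined is a
least-squares fit on some residue subset, so the search can never
exceed the exhaustive subset-superposition optimum; on 200 random
small pairs it matches that optimum in ≈ 99% of threshold checks
(tested). There is no randomness anywhere in the kernel; ties break by
residue order.

Public Kabsch superposition goes through
`scipy.spatial.transform.Rotation.align_vectors` (guaranteed proper
rotation); the kernel's inner Kabsch is a small compiled routine
cross-checked in tests against scipy and an independent quaternion
(Horn) solution.

## Features

Per model of a target pool T (|T| models):

- **Consensus (7).** Averages over all s ∈ T — the self term included,
  as the plain average of the pool — of gdt₁, gdt₂, gdt₄, gdt₈, GDT_TS,
  GDT_HA and RMSD over the common residues after whole-common
  superposition. Pairs sharing fewer than 3 CA residues contribute
  worst-case values (gdt 0, RMSD 999 Å) with a logged warning. Pair
  scores are computed once per unordered pair; with positional
  correspondence they are direction-symmetric.
- **Basic (5).** `contacts8` / `contacts14`: cross-residue carbon–carbon
  pairs within 8 / 14 Å divided by the number of carbon atoms
  (same-residue pairs excluded — both conventions are configurable
  choices of this package); `scCarbonN`: side-chain carbon count (CB
  counts, backbone C/CA do not); `coverage`: modeled-CA fraction of the
  target; `rg`: root-mean-square CA distance from the CA centroid.
- **Target conditioning.** Per-target z-scores (population standard
  deviation; zero when the within-target spread is zero, avoiding
  infinities) and per-target medians (mean-of-middle-two for even
  counts) of the basic and consensus features; amino-acid composition
  of the target sequence — 20 per-residue frequencies plus 6
  physicochemical classes (positive K/R/H, negative D/E, aromatic
  F/W/Y/H, polar, non-polar, and a glycine+proline "special" class,
  this package's sixth class); and one-hot target-identity columns
  `OH_<id>` over the training targets. At prediction time an unseen
  target's one-hot block is all zeros.

## Regressor

`BoostedQARegressor` wraps a LightGBM ensemble with learning rate 0.1
and 100 estimators, squared-error objective, everything else at library
defaults; `n_jobs=1` and `deterministic=True` make runs bit-reproducible
for a fixed `random_state` (default 17). Predictions are clipped to
[0, 1] — the label's range — as an explicit post-processing choice.
Labels outside [0, 1] are rejected; the label column is dropped by name
before fitting so it can never leak in as a feature. Linear (ridge) and
feed-forward baselines sit behind the same interface (`backend=`) for
method comparisons. Importance is GAIN, the summed information gain of
all splits using a feature; ranks break ties by column order.

## Evaluation

Per target: RMSE over its models; LOSS = best observed GDT_TS minus the
observed GDT_TS of the top-predicted model; 5-LOSS the minimum such gap
over the five top-predicted. Prediction ties break lexicographically by
model id; a single-model target has LOSS = 5-LOSS = 0 by definition.
Benchmark performance is the median (and mean) over leave-one-target-out
folds. Filter-listed targets are removed from every training fold only
— they are always evaluated — and fold compositions are logged so the
contract is checkable. Method comparison uses the one-sided Wilcoxon
signed-rank test on paired per-target values; zero differences are
discarded, and the all-ties case returns p = 0.5 by convention.

## Synthetic benchmark

`DecoyConfig` defaults define the package's desk-scale study: 30
targets of 30–60 residues, 60 models each, noise range 0.25–8 Å,
cluster fraction 0.4, partial-coverage fraction 0.25. References are
self-avoiding CA traces (consecutive spacing 3.8 ± 0.1 Å, nonconsecutive
pairs ≥ 3.5 Å) with a CB dummy carbon on non-glycine residues; decoys
add isotropic per-axis Gaussian noise (cluster models draw sigma from
the lowest 1 Å of the range, tail models from the rest) and optionally
truncate to a contiguous 50–95% window. Labels are GDT_TS against the
reference, computed by the same kernel the features use. Sizes were
chosen so a full study (generation, all-vs-all similarities, three LOTO
ablations) completes in minutes on one CPU. An "out-of-context" variant
clusters a pool around an unrelated structure, giving high consensus
with low labels — the situation the training-set filter exists for.

These decoys are not physically realistic: side chains stop at CB,
noise ignores bond geometry, and the accuracy distribution is simpler
than a real server pool's (no systematic method biases, no duplicate
models, no alignment errors). Passing tests therefore demonstrate that
the pipeline recovers quality when the consensus premise holds and that
its contracts (determinism, filtering, bounds) are honored — not that
real-benchmark error levels are achieved. On this generator the
consensus signal is stronger than on real CASP pools, which compresses
the gap between the consensus-only and all-features ablations.

## Numerical and degenerate-input choices

- Superposition requires ≥ 3 common CA residues; below that, pairwise
  scoring records worst-case values rather than failing the whole pool.
- GDT fractions are made monotone across cutoffs by a running maximum
  (a smaller-cutoff solution is also valid at any larger cutoff).
- Collinear point sets leave a rotation degree of freedom; any
  least-squares solution is accepted (counts are unaffected in the
  cases that matter, and determinism is preserved for fixed input).
- Feature tables are tab-separated text with full-precision floats;
  round trips are exact.

## Known limitations

- No sequence-alignment-based correspondence, no multi-chain complexes,
  no mmCIF input, no per-residue (local) accuracy estimates.
- The basic-feature set is the coordinate-only core (contacts,
  compactness, coverage, side-chain content); energy-like terms,
  secondary-structure or solvent-accessibility compatibility features
  are out of scope, though externally computed columns can be merged by
  `(target_id, model_id)`.
- Consensus features require a pool; the method is undefined for a
  single model in isolation (a one-model pool degenerates to
  self-similarity).
- Labels treat a single reference structure as gold standard; protein
  flexibility (alternative native conformations) is ignored.
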
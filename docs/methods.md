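# Methods

## Problem setting and assumptions

The package predicts the binding free energy ΔG (kcal/mol) of a two-protein
complex from sequence alone. A complex is an ordered pair of chain sets
(ligand, receptor); the representation deliberately ignores structure,
stoichiometry and post-translational state. The underlying assumptions are
(i) that the 20-letter amino-acid sequence carries a usable affinity signal,
and (ii) that chain-level information can be pooled into a complex-level
representation by simple averaging — within-side means for explicit
descriptors, cross-complex chain-pair means for kernels. Both assumptions
are approximations; the evaluation machinery (leave-one-complex-out CV with
RMSE, Pearson r and its p-value) exists precisely to measure how far they
carry.

ΔG and the dissociation constant are interconverted as K_d = exp(ΔG/(R·T))
with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default. The
standard-condition temperature is a convention, not a fitted quantity;
benchmark affinities are reported without per-complex temperatures, so a
single default is the only consistent choice.

## Sequence handling

Sequences are upper-cased and mapped onto the canonical alphabet: B→D, Z→E,
U→C, O→K, and any remaining non-canonical letter (including X) → A, each
replacement logged. Every featurizer and kernel requires the 20-letter
alphabet; alanine is the least-informative common residue, which makes it
the least-bad imputation for unknowns.

## Chain descriptors

* **aac** — raw residue counts (20-d). Counts versus frequencies is
  immaterial downstream because rows are unit-normed before regression.
* **blosum** — mean of BLOSUM62 columns of the chain's residues (20-d).
* **pssm** — columnwise mean of a PSI-BLAST ASCII profile (20-d), with
  column order normalized to the package's alphabetical convention. When no
  profile is supplied the featurizer can substitute the per-residue BLOSUM62
  column (then identical to **blosum**); the substitution is flagged in the
  transformer metadata and logged. This keeps the full pipeline runnable
  without a sequence database; real applications should supply profiles.
* **protparam** — molecular weight (Da), aromaticity (F/W/Y fraction),
  instability index (Guruprasad dipeptide weights), isoelectric point
  (Henderson–Hasselbalch charge balance), and helix {V,I,Y,F,W,L}, turn
  {N,P,G,S}, sheet {E,M,A,L} residue fractions (7-d), computed with
  Biopython's ProtParam implementation of those standard definitions.
* **propy** — a 1017-d composite: AAC frequencies (20); normalized
  Moreau-Broto, Moran and Geary autocorrelations over an 8-scale
  physicochemical panel with lags 1..30 (3 × 240); Dubchak three-class
  composition/transition/distribution descriptors over 7 attributes (147);
  sequence-order-coupling numbers, lags 1..30 (30); quasi-sequence-order
  descriptors with weight 0.1 (50); type-I pseudo-amino-acid composition
  with λ = 30, w = 0.05 (50). The property panel comprises Kyte–Doolittle
  hydropathy, Hopp–Woods hydrophilicity, Zamyatnin residue volume, average
  residue mass, Grantham polarity, free-residue isoelectric point, and the
  Chou–Fasman helix and sheet propensities, z-normalized over the alphabet.
  The residue distance used by the sequence-order families is the Euclidean
  distance in this z-scaled property space — a self-contained choice made
  because the classical distance tables could not be embedded verbatim with
  confidence; any fixed symmetric residue metric serves the same role.
  The registry reports the realized dimension rather than promising a magic
  number, since the total depends on the family configuration.

Chains shorter than lag + 1 residues have their lag range truncated to
|s| − 1 with the remaining entries zero-filled and a logged warning, so the
descriptor dimension is constant for a fixed configuration. Moran and Geary
autocorrelations of a constant-property trace are defined as 0 (their
numerator vanishes with their denominator).

## String kernels

All three kernels use BLOSUM62 with affine gaps: a gap of length L costs
open + (L−1)·extend, default 11/1 — the convention under which the published
gap parameters are usually quoted, and the one the enumeration oracle
implements.

* **Smith-Waterman kernel**: the optimal local-alignment score, evaluated by
  Biopython's affine-gap local aligner and floored at 0 (the empty
  alignment). It is verified against exhaustive enumeration of all
  order-preserving position matchings on short pairs.
* **Local-alignment kernel**: Σ_π exp(β·p(a,b,π)) over *all* local
  alignments, including the empty one (+1). Evaluated with the five-state
  recursion (aligned-pair state, two gap states with the gap-ordering
  convention that prevents double counting, two accumulator states),
  vectorized row-wise; the within-row gap recurrence is a first-order linear
  filter. Running rescaling with an accumulated log-scale handles
  arbitrarily large exponents: the rescale threshold is chosen per pair as
  1e280 divided by the largest single-step growth factor, so no intermediate
  overflows. The linear-space value raises a numeric error only when the
  kernel value itself exceeds the float range; `la_kernel_log` is always
  representable. β defaults to 0.1 (empirical-performance default); as β
  grows, (1/β)·ln k_LA approaches the SW score, which is tested at β = 20.
* **Mismatch kernel**: the (k,m) inner product Σ_u N_a(u)·N_b(u). The number
  of k-mers u simultaneously within Hamming distance m of two k-mers depends
  only on their Hamming distance d, and has a closed combinatorial form
  (agreeing positions contribute match-or-differ-from-both; disagreeing
  positions contribute match-x / match-y / match-neither multinomials). The
  kernel is therefore the sum of a precomputed per-distance statistic over
  all instance pairs — exact, never materializing the 20^k space, and
  verified against whole-space brute-force counting for small k. Defaults
  k = 5, m = 3.

Chain kernels are lifted to complexes by averaging over all cross-complex
chain pairs, with |c| counting ligand and receptor chains alike (a
ligand–ligand/receptor–receptor "matched" pairing is available as a
non-default option). Cosine normalization k/√(k_aa·k_bb) is available but
off by default.

**PSD correction.** Alignment-score Grams can be indefinite. When the
smallest eigenvalue λ_min of a training Gram is negative, the diagonal is
shifted by −λ_min; the shift and a corrected flag are recorded. Correction is
applied uniformly to any training Gram with λ_min < 0 (it is a no-op on PSD
matrices). It is computed on the training fold only; test cross-kernel rows
are used as-is, since the diagonal shift does not alter off-diagonal terms
and test diagonal entries are never consumed. Within a fold, inner-CV
submatrices of the corrected Gram are principal submatrices of a PSD matrix
and hence PSD.

## Regression and model selection

Feature rows are scaled to unit L2 norm and then columns standardized, in
that order, with statistics fitted on the training rows of each fold only
(all-zero rows skip the norm step; constant columns keep scale 1). Learners:
ordinary least squares (minimum-norm solution on rank-deficient designs,
which wide concatenated descriptors routinely produce), ε-SVR
(linear / RBF / precomputed kernel), and random-forest regression.
Hyperparameters are selected by exhaustive grid search with 5-fold inner CV
on the training fold (seeded, shuffled; fold count reduced with a warning on
tiny folds), minimizing mean inner RMSE with ties broken by grid order; a
singleton grid is applied directly. Default grids are standard log grids
(C ∈ 10⁻²..10³, ε ∈ 10⁻³..1, γ ∈ 10⁻⁴..1 plus the reciprocal-dimension
heuristic; forests 100–500 trees, split 2–10) — engineering defaults,
configurable everywhere they are used. Kernel representations are evaluated
with precomputed-kernel SVR only; tree and plain least-squares learners
consume explicit features.

The homology baseline predicts the ΔG of the training complex with the
largest chain-pair-averaged SW similarity, ties broken by training order.
Complex-to-complex similarity uses the same chain-pair averaging as the
kernels rather than concatenating chains into one super-sequence, which
would make the score depend on an arbitrary chain order.

## Evaluation

Leave-one-complex-out CV refits the scaler, the grid search and the model on
each fold of N−1 complexes and predicts the left-out complex once. Pairwise
kernel matrices are precomputed (they involve no fitted statistics); all
fold-dependent quantities are re-learned inside the fold. Aggregates are
RMSE and Pearson r with the two-sided p-value from the t statistic with N−2
degrees of freedom. Zero-variance inputs yield r = NaN, never a silent 0,
so degenerate runs cannot masquerade as "no correlation" in comparison
tables. A cumulative absolute-error histogram supports error-profile plots.

## Synthetic data: what it does and does not emulate

The generator produces uniform-random (optionally composition-biased)
chains, assembles complexes, and labels them under two scenarios with ΔG
clipped to [−19, −4] kcal/mol, the plausible experimental range.

* **linear_in_features**: y = w*·(ψ(c)/‖ψ(c)‖) + b* + ε, linear in the
  unit-normed descriptor — the representation the models consume. Chains are
  drawn from a small shared pool (default 4 distinct chains for 40
  complexes). Proteins do recur across benchmark complexes, but the pool
  size here is chosen for identifiability, not realism: it keeps the rank of
  the 40-d composition design well below the leave-one-out fold size, so
  every held-out feature vector lies in the training row-span and the
  minimum-norm least-squares fit recovers the truth exactly. A recovery test
  with an unidentifiable design would measure nothing. The default signal
  spread is 1.5 kcal/mol around an intercept of −11 kcal/mol; label noise is
  Gaussian with configurable σ.
* **similarity_smooth**: anchor complexes with affinities spread across the
  range; each complex is a point-mutated copy of an anchor (mutation
  fraction ρ ~ U(0, 0.3)) with y = y_anchor + 3.0·ρ + ε kcal/mol. Mutation
  weakens binding on average, and affinity is smooth in sequence similarity —
  the regime in which a nearest-homolog predictor is informative. Mutation
  draws are made for every position regardless of rate, so runs at different
  rates under one seed are nested, making noise-level comparisons exact
  rather than merely statistical.

Passing tests on these fixtures demonstrate that the machinery is correct:
features and kernels compute what they claim, no fold leaks statistics,
recovery is exact when the model family contains the truth, and the baseline
wins when its assumption holds. They deliberately do not demonstrate
predictive power on real complexes, where affinity is not linear in
composition and not smooth in homology; real-benchmark performance must be
established on real data.

## Numerical and interface choices

* Alignment parameters are validated (gap_open ≥ gap_extend > 0, β > 0);
  mismatch parameters accept 1 ≤ k ≤ 9, 0 ≤ m ≤ 5, m < k (k below 3 is
  degenerate but well-defined and useful for cross-checks).
* Gram symmetry is enforced within 1e−9 (relative to the largest entry);
  PSD is certified at λ_min ≥ −1e−8 after correction.
* Model files are pickles wrapped with a format/version tag; mismatched
  versions are refused rather than mis-loaded.
* The CLI (`simulate`, `featurize`, `gram`, `train`, `predict`, `loco`,
  `sweep`) is a thin orchestration layer: YAML config with unknown keys
  rejected by name, flags overriding config, all randomness derived from
  `--seed`, partial outputs removed on failure. All artefacts are plain
  text (FASTA, CSV/TSV, JSON) and byte-stable for fixed inputs and seed.
* Problem sizes in the test-suite and the acceptance script (40 complexes
  for recovery, 30 for baseline studies, 10 for the full sweep, length ≤ 8
  pairs for brute-force oracles) are chosen so each check runs in seconds
  while still exercising every code path; the statistics of interest
  (recovery error, noise concentration, oracle agreement) are insensitive to
  scaling these up.

## Known limitations

* PSI-BLAST profiles are consumed, not produced; without profiles the PSSM
  descriptor degrades to the BLOSUM62 average (flagged).
* The composite-descriptor property panel and residue metric are fixed,
  documented choices; other published panels would give numerically
  different (not necessarily worse) descriptors.
* Chain-pair averaging treats all chains as exchangeable within a complex;
  interface-region weighting and chain-pairing optimization are out of
  scope.
* The LA kernel on long, self-similar chains produces Grams dominated by
  their diagonal at moderate β; cosine normalization (available, off by
  default) mitigates this at the cost of departing from the raw definition.
* No uncertainty quantification beyond the Pearson p-value; bootstrap
  confidence intervals are out of scope.
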
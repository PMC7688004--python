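# seqaffinity

Sequence-only prediction of protein–protein binding affinity.

Experimental determination of the binding free energy ΔG (kcal/mol) — or
equivalently the dissociation constant K_d, related by ΔG = RT·ln K_d — is
slow and expensive, and most structure-based predictors cannot be applied to
the vast majority of complexes whose structures are unknown. `seqaffinity`
implements a purely sequence-based pipeline for researchers who want to
estimate absolute binding affinity from the ligand and receptor chain
sequences alone, and to benchmark how far such predictors actually
generalize.

## Method

A complex is a tuple *c* = ((*l*, *r*), *y*): a set of ligand chains *l*, a
set of receptor chains *r*, and an affinity label *y* = ΔG. Two families of
representations are lifted from chain level to complex level:

**Explicit descriptors** φ(s) per chain — amino-acid composition (20-d),
averaged BLOSUM62 columns φ_Blosum(s) = (1/|s|) Σᵢ B_i (20-d), averaged
PSI-BLAST PSSM columns φ_PSSM(s) = (1/|s|) Σᵢ F_iˢ (20-d), whole-chain
physicochemical summaries (7-d), and a 1017-d composite of
autocorrelation/CTD/sequence-order/pseudo-composition families — are averaged
within each side and stacked, ψ(c) = [ψ_Avg(l); ψ_Avg(r)]. Rows are
unit-normed and columns standardized (statistics fitted on training folds
only) before regression.

**String kernels** k(a, b) per chain pair —

* Smith-Waterman kernel: the optimal affine-gap local-alignment score
  k_SW(a,b) = max_{π∈Π(a,b)} p(a,b,π), BLOSUM62 with gap open/extend 11/1;
* local-alignment (LA) kernel: k_LAᵝ(a,b) = Σ_{π∈Π(a,b)} exp(β·p(a,b,π)),
  summing all local alignments (β = 0.1 by default; (1/β)·ln k_LA → k_SW as
  β → ∞);
* (k,m)-mismatch kernel: Σ_u N_a(u)·N_b(u) over the 20^k k-mer space, where
  N_x(u) counts k-mer instances of x within Hamming distance m of u (defaults
  k = 5, m = 3)

— are averaged over cross-complex chain pairs,
K(c,c′) = (1/(|c|·|c′|)) Σ_{q∈c, q′∈c′} k(q,q′). Alignment-score kernels can
be indefinite, so training Grams are made PSD by subtracting the most
negative eigenvalue from the diagonal.

Regressors f(c) = wᵀψ(c) + b (ordinary least squares; ε-insensitive support
vector regression, linear/RBF/precomputed-kernel) and random-forest
regression are fitted with hyperparameters chosen by inner grid-search
cross-validation. Evaluation is leave-one-complex-out (LOCO): each complex is
predicted by a model trained on the other N−1, scored by RMSE and Pearson r
with its two-sided p-value. A nearest-homolog baseline predicts the affinity
of the most Smith-Waterman-similar training complex.

A synthetic-data module generates chains, complexes and affinities with known
structure (exactly linear in a chosen descriptor, or a smooth function of
sequence similarity), so that every stage is testable without downloads.

## Worked example

```python
from seqaffinity import SyntheticSpec, generate, evaluate_loco

spec = SyntheticSpec(n_complexes=30, affinity_model="similarity_smooth", seed=7)
dataset, truth = generate(spec)

homology = evaluate_loco(dataset, representation="homology")
print(f"homology baseline: RMSE {homology.rmse:.2f} kcal/mol, r = {homology.pearson_r:.2f}")

svr = evaluate_loco(dataset, representation="sw",
                    param_grid={"C": [1.0, 10.0, 100.0], "epsilon": [0.1]})
print(f"SW-kernel SVR:     RMSE {svr.rmse:.2f} kcal/mol, r = {svr.pearson_r:.2f}")
```

prints

```
homology baseline: RMSE 0.40 kcal/mol, r = 1.00
SW-kernel SVR:     RMSE 0.93 kcal/mol, r = 0.99
```

On this dataset affinity is, by construction, a smooth function of sequence
similarity, so the nearest-homolog lookup is nearly perfect and the SW-kernel
SVR tracks it closely; both RMSEs are small relative to the ~4.3 kcal/mol
spread of the labels. On real benchmarks, where affinity is *not* a simple
function of sequence similarity, both numbers degrade sharply — quantifying
that gap is what the LOCO machinery is for.

The same pipeline is available from the shell:

```sh
seqaffinity simulate --n-complexes 30 --seed 7 --out run/
seqaffinity loco --fasta run/chains.fasta --complexes run/complexes.csv \
    --representation aac --model olsr --seed 1 --out run/eval/
seqaffinity sweep --fasta run/chains.fasta --complexes run/complexes.csv \
    --seed 1 --out run/sweep.csv
```

`seqaffinity predict` emits both ΔG and the implied K_d
(K_d = exp(ΔG/RT) at 298.15 K) per complex.

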
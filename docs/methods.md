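# Methods

## Molecular graphs and featurization

Molecules are heavy-atom 2D graphs parsed from SMILES with RDKit. The stored
form is the canonical SMILES, and graphs are built by re-parsing it, so atom
order is the canonical output order: any spelling of the same molecule
yields a byte-identical graph. This determinism is load-bearing — the GRU
readout consumes atoms as an ordered sequence.

Atom features (28 dims): element one-hot over {C, N, O, S, F, Cl, Br, I, P,
other}; degree one-hot (0–5); formal charge clipped to [−2, 2];
hybridization one-hot (sp/sp²/sp³/other); aromatic flag; total-H one-hot
(0–4); in-ring flag. Bond features (6 dims): order one-hot
(single/double/triple/aromatic), conjugation, in-ring. This is the standard
minimal molecular-GNN set; widths are module constants so alternates can be
swapped. Hydrogens are implicit; 3D conformers, chirality and tautomers are
out of scope.

Missing labels are NaN throughout and excluded from every loss sum.

## The three views

Views are node-aligned: all three share the base atom set and order, and
annotations occupy disjoint slices of a common input block (scaffold 1 dim,
functional groups 14, pharmacophore families 6, plus a membership flag and a
pre-training mask flag). Alignment is what makes feature-wise fusion
`[H_s ; H_f ; H_p]` well-defined; an alternative design contracting groups
into super-nodes was rejected because it breaks this concatenation.

* **Scaffold** — membership is the Murcko framework, computed as the 2-core
  of the bond graph (iterative pruning of terminal atoms), which equals
  rings plus ring–ring linkers; an independent networkx `k_core` computation
  is the test oracle. Only edges internal to the scaffold survive;
  substituent atoms stay as isolated nodes with zero annotation. Acyclic
  molecules legitimately have an empty scaffold.
* **Functional groups** — one-hot (plus "none") over a 13-group SMARTS
  vocabulary shipped as versioned YAML (`specmol/data/functional_groups.yaml`).
  Overlaps are resolved by vocabulary order, which is therefore written
  most-specific-first (carboxyl before carbonyl/hydroxyl, ester before
  ether, …) so that e.g. a carboxylic acid's O–H is labelled carboxyl
  rather than hydroxyl. Ties are thus deterministic and documented in the
  file itself.
* **Pharmacophore** — multi-hot over six interaction families (donor,
  acceptor, hydrophobe, aromatic, positive/negative ionizable) from a
  built-in SMARTS table (`specmol/data/pharmacophores.yaml`), avoiding any
  dependency on external feature-definition files. The hydrophobe
  definition requires ring/aromatic carbons, halogens on carbon, or sp³
  carbons inside a ≥3-carbon chain, so an isolated ethane carbon is not a
  hydrophobic center.

## Spectral operators

For an undirected graph with adjacency `A` and degrees `D`:
`L = D − A`, `P = D^{-1/2} A D^{-1/2}`, `L_norm = I − P` with spectrum in
[0, 2]. Isolated nodes get zero rows/columns in `P`, so both filters act as
the identity there — this convention avoids division by zero in the
`1/√(|N_i||N_j|)` edge weights and preserves the complementarity identity
`(I−P)x + (I+P)x = 2x` on every graph. No self-loops are added.

High-pass filtering is `(I − P) x` (spectral response `g(λ) = λ`), low-pass
is `(I + P) x` (`g(λ) = 2 − λ`); both are evaluated sparsely with no
eigendecomposition. A dense oracle `U g(Λ) Uᵀ x` (guarded to n ≤ 500) exists
only for verification; tests require agreement below 1e−8 and the
complementarity identity below 1e−10.

The k-hop operator in the attention modulation is `L_norm^k` by default
(k = 2): the source derivation mixes "standard Laplacian" language with
normalized quantities, and the normalized choice keeps the spectrum bounded;
a config switch (`laplacian: combinatorial`) selects `(D − A)^k` instead.

## The spectral attention block

Per block, with per-head projections realized as column slices of full-width
maps (filter-then-project: `(I∓P)X` then a learnable linear map — the
minimal realization consistent with adding the filtered terms to `W·X`):

* `Q = W_Q X + HF(X)`, `K = W_K X + LF(X)`, `V = W_V X`
* `S = softmax(Q Kᵀ/√d_k)` (row-stochastic; verified to 1e−6)
* message matrix: the default combination rule is
  `M = S + α (L^k ⊙ A) ⊘ (J + β A)` with elementwise division; for binary
  `A` this equals `S + (α/(1+β)) (L^k ⊙ A)` on edges. The printed form of
  this rule is ambiguous, so it is a pluggable strategy with two documented
  alternates, `(S + α L^k) ⊘ (J + β A)` (`sum_div`) and
  `S + α L^k ⊘ (J + β A)` (`scaled_lk`); the default is recorded in config.
* output `H′ = M V + HF(X) + LF(X)`, heads concatenated and projected.

`α` and `β` are learnable non-negative scalars via softplus
reparameterization, initialized at 0.1 and 1.0: they are described in the
source as tunable, and learnability subsumes tuning. Ablation flags zero the
HF path, the LF path, or the modulation; with all three off the block equals
plain scaled-dot-product attention to 1e−8 (tested against an independent
implementation).

Blocks are stacked with residual connections and feature normalization.
Molecules are processed one graph at a time (graphs have tens of atoms), so
no padding/masking machinery is needed; batching is by iteration with
gradient accumulation.

Because the first block's HF path is `(I−P)·embed(X)·W`, two molecules with
identical topology whose inputs differ at one atom produce HF activations
differing only inside that atom's closed 1-hop neighborhood — the testable
core of cliff sensitivity, asserted exactly in the suite.

## Fusion, readout, heads

Fused features are linearly projected to `d_model`, a learned global token
is appended at index n, and `transformer_layers` standard post-norm encoder
layers (self-attention + 2× FFN) run over the tokens; with zero layers the
stack is the identity, and atom-token permutation equivariance (global row
fixed) is tested. The graph embedding is
`Norm(mean-pool(BiGRU(atom tokens)) + Mish(W_r · mean-pool(atom tokens)))`
with layer-style feature normalization ("normalization" being otherwise
unspecified, layer-norm is the conventional choice). The global token skips
the GRU and is concatenated to the graph embedding before the heads — the
readout consumes atoms, the global token is already a summary. Heads are
per-task affine maps; classification heads emit probabilities through the
logistic function.

Architecture defaults (d_model 128, 2 blocks, 4 heads, 2 transformer
layers) are engineering choices; the canned studies in
`specmol.experiments` use a depth-1, 32-wide configuration that trains in
seconds per epoch on one CPU.

## Objectives

* **Pre-training**: per molecule, a seeded 15% atom subset (≥1) has its
  base-feature block zeroed and a mask flag raised in all three views; the
  loss is the summed squared error of reconstructing those atoms' original
  feature rows plus a global-descriptor term (normalized element histogram,
  ring count/5, heavy atoms/25) predicted at the global token. The ground
  truths of this reconstruction objective are not externally pinned down;
  this masked-feature reading is the package's documented choice.
  Pre-training uses no dynamic task weighting.
* **Dynamic task weighting**: `λ_i ← λ_i (1 + γ(L_i − L̄_i)/(L̄_i + ε))`,
  floored at 1e−4 (the update can otherwise drive weights negative), then
  normalized to sum to 1. `L̄_i` is an EMA (momentum 0.9) initialized to the
  first observed loss, giving bounded memory and a no-op first update.
  Updates happen once per epoch on epoch-mean task losses.
* **Class-balanced weights**: `w_c = (1−β_cb)/(1−β_cb^{N_c})`, normalized to
  sum to the number of observed classes; zero-count classes are excluded
  with a warning. This `β_cb` is unrelated to the attention `β`.
* **Weighted BCE** per classification task with `w̃_1, w̃_0`; probabilities
  clamped to [1e−7, 1−1e−7]; regression tasks contribute masked MSE in the
  same weighted sum (class balancing applies to classification only).
* **Supervised contrastive**: temperature-scaled cosine similarities over
  graph embeddings; self-pairs excluded from numerator and denominator,
  anchors without positives dropped and the average taken over the rest —
  the standard convention that keeps the loss finite and ≥ 0 (numerator set
  ⊆ denominator set). Labels come from the first classification task, or a
  batch-median split of the first regression task when none exists.
* **Total**: `L_classification + λ_c L_contrastive`, λ_c default 0.1.

Defaults γ = 0.1, ε = 1e−8, τ = 0.1, β_cb = 0.99 — all config-exposed; none
of these values is externally prescribed.

## Synthetic data

The fixture generator stands in for external benchmarks and defines exactly
what passing tests show:

* 56 hard-coded drug-like molecules covering every functional group and
  pharmacophore family (asserted by test).
* Regression labels = Σ (coefficient × group match count) + seeded Gaussian
  noise (σ = 0.1 by default); coefficients ship in
  `specmol/data/fixture_constants.yaml`, spread in sign and magnitude.
  Classification labels threshold the noiseless score at the quantile
  realizing a 1:9 positive:negative ratio.
* Activity-cliff pairs: 17 templates × single-heavy-atom substituent swaps
  (C/F → O/N/Cl) with a fixed +3.0 label offset. Swaps are single atoms so
  the two members share graph topology, which is what makes the per-atom
  locality assertions well-defined; the generator also returns the
  template-derived atom correspondence.
* Random Erdős–Rényi graphs for the spectral harness.

All randomness uses NumPy's PCG64 with explicit seeds (stable across
platforms). What these fixtures do **not** emulate: assay noise structure,
scaffold-split distribution shift, realistic label sparsity patterns, or any
specific public benchmark's distribution — a model passing here has learned
a clean substructure-counting signal, not SAR in the wild.

## Canned studies and problem sizes

`specmol.experiments` fixes the desk-scale conditions: the overfit study
trains on 32 noiseless fixture molecules (batch 8, Adam lr 3e−3, early stop
once train RMSE < 0.1× initial, cap 500 epochs — typically ~40); the
pre-training study runs 30 epochs on the same set; the cliff ablation trains
full vs. no-HF/LF variants on 100 pairs (200 molecules, whole pairs held
out 1-in-5) for 25 epochs at seeds {s, s+1, s+2} and reports median final
train/validation RMSE. The ablation comparison is stochastic and is
reported rather than hard-gated.

## Numerical choices

float64 everywhere. Softmax is max-shifted; softplus via `logaddexp`;
probabilities clamped before logs; attribution channels whose total energy
is at roundoff (e.g. the HF channel of benzene, which is exactly zero up to
floating point) are reported as zeros rather than normalized noise.
Eigendecomposition uses `numpy.linalg.eigh` with ascending eigenvalues; ties
are left in decomposition order since only reconstructed operators are
compared. Duplicate input edges collapse to a single bond; self-loops are
rejected.

## Known limitations

* No 3D/chirality awareness; heavy-atom graphs only.
* The autodiff engine is deliberately minimal (no broadcasting matmul over
  batch dims, no GPU); throughput is adequate for tens of atoms and
  hundreds of molecules, not for large-scale pre-training corpora.
* Attention is O(n²) per molecule; fine at drug-like sizes.
* SMARTS vocabularies are compact and prioritized for determinism, not
  exhaustive chemical coverage; users can override the YAML tables.
* The supervised contrastive term needs discrete labels; the regression
  fallback (batch-median split) is a heuristic.
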
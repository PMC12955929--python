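# specmol

Multi-view spectral graph learning for molecular property prediction, built
to stay sensitive to **activity cliffs** — pairs of near-identical molecules
with very different bioactivity, the classic failure mode of
structure–activity models that smooth over local structural detail.

`specmol` is a library (plus a thin CLI) for cheminformatics researchers who
want a fully inspectable, CPU-scale implementation of frequency-aware graph
attention: every operator is exposed, every loss has a brute-force oracle in
the test suite, and all experiments run on synthetic molecules generated by
the package itself — no external datasets, no GPU.

## The model

Each molecule `G = (V, E)` (heavy-atom graph from SMILES, RDKit-canonical
atom order) is refracted into three node-aligned chemical views: the
**scaffold** graph `G_s` (Murcko framework: rings plus linkers), the
**functional-group** graph `G_f` (prioritized SMARTS annotation), and the
**pharmacophore** graph `G_p` (H-bond donors/acceptors, hydrophobes,
aromatics, ionizable centers).

A shared-parameter encoder `f_θ` maps each view to node embeddings,
`H_s = f_θ(G_s)`, `H_f = f_θ(G_f)`, `H_p = f_θ(G_p)`. Its core block augments
attention with closed-form spectral filters built from the normalized
adjacency `P = D^{-1/2} A D^{-1/2}` (so `L_norm = I − P`, eigenvalues in
`[0, 2]`):

```
HF(X) = (I − P) X W_HF          high-pass,  g(λ) = λ
LF(X) = (I + P) X W_LF          low-pass,   g(λ) = 2 − λ

Q = W_Q X + HF(X),   K = W_K X + LF(X),   V = W_V X
S = softmax(Q Kᵀ / √d_k)
M = S + α (L^k ⊙ A) ⊘ (J + β A)          k-hop attenuated modulation
H′ = M V + HF(X) + LF(X)
```

`α, β` are learnable non-negative scalars; `J` is all-ones; `⊘` is
elementwise division. High-pass output reacts only within one hop of a
perturbed atom — the mechanism behind cliff sensitivity — while the low-pass
path carries scaffold-level context. The fused views
`H_fusion = [H_s ; H_f ; H_p]` pass through a transformer with a learned
global token and a bidirectional-GRU readout (with a Mish-activated residual
projection) into per-task heads.

Training combines, per task `i` with normalized dynamic weight `λ̃_i`:

```
λ_i ← λ_i (1 + γ (L_i − L̄_i) / (L̄_i + ε))       dynamic task weighting
w_c = (1 − β_cb) / (1 − β_cb^{N_c})              class-balanced weights
L_total = Σ_i λ̃_i L_i + λ_c · L_contrastive       SupCon, cosine/τ
```

plus a masked-atom reconstruction objective for pre-training. The network
runs on a small reverse-mode autodiff engine over NumPy (`specmol.autograd`)
— molecular graphs are tiny, so dense float64 tapes train in seconds.

## Worked example

```bash
python examples/03_train_on_fixtures.py
```

```
molecules          : 32
epochs run         : 37
initial train RMSE : 1.0520
final train RMSE   : 0.1007
ratio              : 0.096  (< 0.1 means the structure-label mapping was learned)

masked-atom pre-training: loss 28.26 -> 1.85 (93% reduction); ...
```

The 32 molecules carry noiseless labels that are a fixed linear function of
functional-group content, so the RMSE ratio of 0.096 demonstrates the
encoder genuinely reads substructure. `examples/04_activity_cliffs.py`
builds a matched pair differing by one substituent and shows the
high-frequency attribution channel peaking at the substituted atom;
`examples/01_views_and_graphs.py` and `examples/02_spectral_filters.py`
walk through the views and the filter algebra.

The CLI mirrors the library:

```bash
specmol fixtures export --out fixtures.csv
specmol pretrain --config cfg.yaml --seed 0 --out-dir runs/pre
specmol train   --config cfg.yaml --seed 0 --out-dir runs/ft \
                --checkpoint runs/pre/checkpoint.npz
specmol predict --checkpoint runs/ft/checkpoint.npz --out-dir runs/pred
specmol explain --checkpoint runs/ft/checkpoint.npz --smiles "Cc1ccccc1"
```

Ablations (`--ablate HF,LF,MA,DTW,CIH,CL,PT`) switch off the high/low
frequency paths, the attention modulation, dynamic task weighting, class
balancing, the contrastive term, or pre-trained initialization — each a pure
configuration change.

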
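"""The multi-view spectral graph network.

One shared-parameter encoder maps each of the three chemical views of a
molecule to node embeddings through stacked *spectral attention blocks*:

* per head, queries are augmented with the high-frequency component of the
  node features, ``Q = W_Q X + (I-P) X W_HF``, and keys with the
  low-frequency component, ``K = W_K X + (I+P) X W_LF``;
* attention scores ``S = softmax(Q K^T / sqrt(d_k))`` are modulated by a
  distance-attenuating topological term built from the k-hop Laplacian
  power: by default ``M = S + alpha (L^k o A) / (J + beta A)`` elementwise
  (two documented alternate combination rules are selectable);
* the block output is ``M V + HF + LF``, heads concatenated and projected.

The three view embeddings are concatenated feature-wise, projected, joined
by a learned global token, passed through a standard transformer encoder,
and read out by a bidirectional GRU over atoms in canonical order combined
with a Mish-activated projection through a residual and normalization.

``alpha`` and ``beta`` are learnable non-negative scalars (softplus
reparameterized).  Ablation switches zero the HF path, the LF path, or the
topological modulation, which reduces the block to plain scaled-dot-product
attention.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import spectral
from .autograd import Adam, Tensor, concat, stack
from .molgraph import ELEMENTS, MolecularGraph, N_ATOM_FEATURES
from .multiview import ViewBundle, ViewGraph, make_views

__all__ = ["EncoderConfig", "DenseOps", "Model", "spectral_attention_block",
           "plain_attention", "global_descriptor", "GLOBAL_DESCRIPTOR_DIM",
           "MESSAGE_RULES"]

# annotation widths of the three views, in fusion order
_VIEW_SLICES = {"scaffold": (0, 1), "functional_group": (1, 15),
                "pharmacophore": (15, 21)}
_ANNOT_DIM = 21
# features | annotation | member mask | is-masked flag (pre-training)
INPUT_DIM = N_ATOM_FEATURES + _ANNOT_DIM + 2

MESSAGE_RULES = ("modulated_div", "sum_div", "scaled_lk")

GLOBAL_DESCRIPTOR_DIM = len(ELEMENTS) + 1 + 2


def global_descriptor(graph: MolecularGraph) -> np.ndarray:
    """Graph-level target for pre-training: normalized element histogram,
    ring count and heavy-atom count (both scaled to ~unit range)."""
    hist = graph.atom_features[:, :len(ELEMENTS) + 1].sum(axis=0)
    n = max(graph.n_atoms, 1)
    n_rings = graph.rdkit_mol.GetRingInfo().NumRings()
    return np.concatenate([hist / n, [n_rings / 5.0, graph.n_atoms / 25.0]])


@dataclass
class EncoderConfig:
    """Architecture hyperparameters (the symbol-level knobs of the model)."""

    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 2               # spectral attention blocks per view
    k: int = 2                      # Laplacian hop order
    alpha_init: float = 0.1
    beta_init: float = 1.0
    transformer_layers: int = 2
    dropout: float = 0.0
    message_rule: str = "modulated_div"
    laplacian: str = "normalized"   # operator raised to the k-th power
    use_HF: bool = True
    use_LF: bool = True
    use_MA: bool = True
    use_PT: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.message_rule not in MESSAGE_RULES:
            raise ValueError(f"unknown message rule {self.message_rule!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class DenseOps:
    """Dense operator bundle for one (small) graph, network-side view of
    :class:`~specmol.spectral.SpectralOperators`."""

    n: int
    ImP: np.ndarray     # I - P  (high-pass)
    IpP: np.ndarray     # I + P  (low-pass)
    A: np.ndarray
    Lk: np.ndarray      # k-th Laplacian power
    LkA: np.ndarray     # L^k o A (elementwise)

    @classmethod
    def from_edges(cls, edges, n: int, k: int,
                   laplacian: str = "normalized") -> "DenseOps":
        ops = spectral.build_operators(edges, n, k=k, laplacian=laplacian)
        I = np.eye(n)
        P = ops.P_dense
        A = ops.A.toarray()
        Lk = ops.Lk.toarray()
        return cls(n=n, ImP=I - P, IpP=I + P, A=A, Lk=Lk, LkA=Lk * A)


def _softplus_inverse(y: float) -> float:
    return math.log(math.expm1(y))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = math.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, s, size=(fan_in, fan_out))


def spectral_attention_block(X: Tensor, ops: DenseOps, cfg: EncoderConfig,
                             params: dict[str, Tensor], prefix: str) -> Tensor:
    """One frequency-enhanced attention block (see module docstring)."""
    if X.shape[0] != ops.n:
        raise ValueError("feature rows != node count")
    d_k = cfg.d_k
    HF = (ops.ImP @ X) @ params[f"{prefix}.W_HF"] if cfg.use_HF else None
    LF = (ops.IpP @ X) @ params[f"{prefix}.W_LF"] if cfg.use_LF else None
    Q = X @ params[f"{prefix}.W_Q"]
    if HF is not None:
        Q = Q + HF
    K = X @ params[f"{prefix}.W_K"]
    if LF is not None:
        K = K + LF
    V = X @ params[f"{prefix}.W_V"]

    mod = None
    if cfg.use_MA:
        alpha = params[f"{prefix}.alpha_raw"].softplus()
        beta = params[f"{prefix}.beta_raw"].softplus()
        if cfg.message_rule == "modulated_div":
            # default: S + alpha (L^k o A) / (J + beta A)
            mod = (alpha * ops.LkA) / (1.0 + beta * ops.A)
        elif cfg.message_rule == "scaled_lk":
            # alternate: S + alpha L^k / (J + beta A)
            mod = (alpha * ops.Lk) / (1.0 + beta * ops.A)
        # "sum_div" divides (S + alpha L^k) as a whole; handled per head

    head_outs = []
    collect = params.get("__collect__")
    for h in range(cfg.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
        S = ((Qh @ Kh.T) * (1.0 / math.sqrt(d_k))).softmax(axis=-1)
        if cfg.use_MA:
            if cfg.message_rule == "sum_div":
                M = (S + alpha * ops.Lk) / (1.0 + beta * ops.A)
            else:
                M = S + mod
        else:
            M = S
        out = M @ Vh
        if HF is not None:
            out = out + HF[:, sl]
        if LF is not None:
            out = out + LF[:, sl]
        head_outs.append(out)
        if collect is not None:
            collect.setdefault("S", []).append(S.data.copy())
    H = concat(head_outs, axis=1)
    if collect is not None:
        if HF is not None:
            collect.setdefault("HF", []).append(HF.data.copy())
        if LF is not None:
            collect.setdefault("LF", []).append(LF.data.copy())
    return H @ params[f"{prefix}.W_O"] + params[f"{prefix}.b_O"]


def plain_attention(X: Tensor, cfg: EncoderConfig, params: dict[str, Tensor],
                    prefix: str) -> Tensor:
    """Reference multi-head scaled-dot-product attention with the same
    parameters (used to verify the ablated block; no spectral terms)."""
    d_k = cfg.d_k
    Q = X @ params[f"{prefix}.W_Q"]
    K = X @ params[f"{prefix}.W_K"]
    V = X @ params[f"{prefix}.W_V"]
    outs = []
    for h in range(cfg.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        S = ((Q[:, sl] @ K[:, sl].T) * (1.0 / math.sqrt(d_k))).softmax(axis=-1)
        outs.append(S @ V[:, sl])
    return concat(outs, axis=1) @ params[f"{prefix}.W_O"] + params[f"{prefix}.b_O"]


def view_input_features(view: ViewGraph, base: MolecularGraph) -> np.ndarray:
    """[base atom features | annotation (view-specific slice) | member mask]."""
    n = base.n_atoms
    annot = np.zeros((n, _ANNOT_DIM))
    lo, hi = _VIEW_SLICES[view.kind]
    width = min(hi - lo, view.annotation.shape[1])
    annot[:, lo:lo + width] = view.annotation[:, :width]
    return np.concatenate(
        [base.atom_features, annot, view.member_mask[:, None].astype(float),
         np.zeros((n, 1))],   # is-masked flag, set during pre-training
        axis=1)


class Model:
    """Full property-prediction model over one shared parameter store."""

    def __init__(self, cfg: EncoderConfig, n_tasks: int,
                 task_types: list[str], seed: int = 0):
        if n_tasks != len(task_types):
            raise ValueError("n_tasks != len(task_types)")
        self.cfg = cfg
        self.n_tasks = n_tasks
        self.task_types = list(task_types)
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.Generator(np.random.PCG64(seed)))

    # -- parameters -----------------------------------------------------------
    def _p(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        d = cfg.d_model
        self._p("embed.W", _glorot(rng, INPUT_DIM, d))
        self._p("embed.b", np.zeros(d))
        for l in range(cfg.n_layers):
            pre = f"enc{l}"
            for w in ("W_Q", "W_K", "W_V", "W_HF", "W_LF", "W_O"):
                self._p(f"{pre}.{w}", _glorot(rng, d, d))
            self._p(f"{pre}.b_O", np.zeros(d))
            self._p(f"{pre}.alpha_raw",
                    np.array(_softplus_inverse(cfg.alpha_init)))
            self._p(f"{pre}.beta_raw",
                    np.array(_softplus_inverse(cfg.beta_init)))
        self._p("fuse.W", _glorot(rng, 3 * d, d))
        self._p("fuse.b", np.zeros(d))
        self._p("global_token", rng.normal(0.0, 0.1, size=(1, d)))
        for l in range(cfg.transformer_layers):
            pre = f"tr{l}"
            for w in ("W_Q", "W_K", "W_V", "W_O"):
                self._p(f"{pre}.{w}", _glorot(rng, d, d))
            self._p(f"{pre}.b_O", np.zeros(d))
            self._p(f"{pre}.ff.W1", _glorot(rng, d, 2 * d))
            self._p(f"{pre}.ff.b1", np.zeros(2 * d))
            self._p(f"{pre}.ff.W2", _glorot(rng, 2 * d, d))
            self._p(f"{pre}.ff.b2", np.zeros(d))
        dh = d // 2
        for direction in ("fwd", "bwd"):
            self._p(f"gru.{direction}.Wx", _glorot(rng, d, 3 * dh))
            self._p(f"gru.{direction}.Uh", _glorot(rng, dh, 3 * dh))
            self._p(f"gru.{direction}.b", np.zeros(3 * dh))
        self._p("readout.W", _glorot(rng, d, d))
        self._p("readout.b", np.zeros(d))
        for t in range(self.n_tasks):
            self._p(f"head{t}.W", _glorot(rng, 2 * d, 1))
            self._p(f"head{t}.b", np.zeros(1))
        self._p("pre.node.W", _glorot(rng, d, N_ATOM_FEATURES))
        self._p("pre.node.b", np.zeros(N_ATOM_FEATURES))
        self._p("pre.glob.W", _glorot(rng, d, GLOBAL_DESCRIPTOR_DIM))
        self._p("pre.glob.b", np.zeros(GLOBAL_DESCRIPTOR_DIM))

    # -- encoding -------------------------------------------------------------
    def view_operators(self, view: ViewGraph) -> DenseOps:
        return DenseOps.from_edges(view.edge_list, view.n_atoms,
                                   k=self.cfg.k, laplacian=self.cfg.laplacian)

    def encode_view(self, view: ViewGraph, base: MolecularGraph,
                    ops: DenseOps | None = None,
                    X0: np.ndarray | None = None,
                    collect: dict | None = None) -> Tensor:
        """Shared-encoder pass over one view: input projection then stacked
        spectral attention blocks with residual + feature normalization."""
        if ops is None:
            ops = self.view_operators(view)
        if X0 is None:
            X0 = view_input_features(view, base)
        H = Tensor(X0) @ self.params["embed.W"] + self.params["embed.b"]
        if collect is not None:
            self.params["__collect__"] = collect
        try:
            for l in range(self.cfg.n_layers):
                out = spectral_attention_block(H, ops, self.cfg, self.params,
                                               f"enc{l}")
                H = (H + out).layer_norm()
                if collect is not None and l == 0:
                    collect.setdefault("n_first_layer",
                                       len(collect.get("S", [])))
        finally:
            self.params.pop("__collect__", None)
        return H

    def _mha(self, X: Tensor, prefix: str) -> Tensor:
        d_k = self.cfg.d_k
        Q = X @ self.params[f"{prefix}.W_Q"]
        K = X @ self.params[f"{prefix}.W_K"]
        V = X @ self.params[f"{prefix}.W_V"]
        outs = []
        for h in range(self.cfg.n_heads):
            sl = slice(h * d_k, (h + 1) * d_k)
            S = ((Q[:, sl] @ K[:, sl].T)
                 * (1.0 / math.sqrt(d_k))).softmax(axis=-1)
            outs.append(S @ V[:, sl])
        return concat(outs, axis=1) @ self.params[f"{prefix}.W_O"] \
            + self.params[f"{prefix}.b_O"]

    def fuse_and_transform(self, H_s: Tensor, H_f: Tensor,
                           H_p: Tensor) -> Tensor:
        """Feature-wise fusion, global token, transformer stack -> H_out."""
        if not (H_s.shape[0] == H_f.shape[0] == H_p.shape[0]):
            raise ValueError("view embeddings misaligned")
        H_fusion = concat([H_s, H_f, H_p], axis=1)
        H = H_fusion @ self.params["fuse.W"] + self.params["fuse.b"]
        H = concat([H, self.params["global_token"]], axis=0)
        for l in range(self.cfg.transformer_layers):
            H = (H + self._mha(H, f"tr{l}")).layer_norm()
            ff = ((H @ self.params[f"tr{l}.ff.W1"]
                   + self.params[f"tr{l}.ff.b1"]).relu()
                  @ self.params[f"tr{l}.ff.W2"] + self.params[f"tr{l}.ff.b2"])
            H = (H + ff).layer_norm()
        return H

    def _gru_direction(self, X: Tensor, direction: str) -> list[Tensor]:
        dh = self.cfg.d_model // 2
        Wx = self.params[f"gru.{direction}.Wx"]
        Uh = self.params[f"gru.{direction}.Uh"]
        b = self.params[f"gru.{direction}.b"]
        n = X.shape[0]
        XW = X @ Wx + b                      # [n, 3*dh], precomputed
        order = range(n) if direction == "fwd" else range(n - 1, -1, -1)
        h = Tensor(np.zeros((1, dh)))
        outs: dict[int, Tensor] = {}
        for t in order:
            xw = XW[t:t + 1]
            hU = h @ Uh
            z = (xw[:, :dh] + hU[:, :dh]).sigmoid()
            r = (xw[:, dh:2 * dh] + hU[:, dh:2 * dh]).sigmoid()
            cand = (xw[:, 2 * dh:] + (r * h) @ Uh[:, 2 * dh:]).tanh()
            h = (1.0 - z) * h + z * cand
            outs[t] = h
        return [outs[t] for t in range(n)]

    def gru_readout(self, H_out: Tensor, n_atoms: int) -> Tensor:
        """Bidirectional GRU over atom tokens in canonical order, combined
        with a Mish-projected mean through a residual and normalization."""
        if n_atoms < 1:
            raise ValueError("empty molecule has no readout")
        atoms = H_out[:n_atoms]
        fwd = self._gru_direction(atoms, "fwd")
        bwd = self._gru_direction(atoms, "bwd")
        steps = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
        gru_mean = concat(steps, axis=0).mean(axis=0, keepdims=True)
        pooled = atoms.mean(axis=0, keepdims=True)
        mish = (pooled @ self.params["readout.W"]
                + self.params["readout.b"]).mish()
        return (gru_mean + mish).layer_norm().reshape(-1)

    # -- full passes ----------------------------------------------------------
    def prepare(self, graph: MolecularGraph) -> dict:
        """Precompute everything reusable across training steps."""
        bundle = make_views(graph)
        views = [bundle.scaffold, bundle.functional_group, bundle.pharmacophore]
        return {
            "graph": graph,
            "bundle": bundle,
            "ops": [self.view_operators(v) for v in views],
            "X0": [view_input_features(v, graph) for v in views],
            "descriptor": global_descriptor(graph),
        }

    def forward(self, rec: dict, mask_atoms: np.ndarray | None = None,
                collect: dict | None = None) -> dict:
        """Full forward pass for one prepared molecule.

        ``mask_atoms`` (bool per atom) zeroes the base-feature block of the
        masked atoms in every view's input and raises their is-masked flag
        (the pre-training corruption); annotation and membership columns are
        kept.  ``collect`` gathers attention and frequency-path activations
        per view for attribution.
        """
        bundle: ViewBundle = rec["bundle"]
        graph: MolecularGraph = rec["graph"]
        H_views = []
        views = [bundle.scaffold, bundle.functional_group, bundle.pharmacophore]
        for v, ops, X0 in zip(views, rec["ops"], rec["X0"]):
            if mask_atoms is not None and mask_atoms.any():
                X0 = X0.copy()
                X0[mask_atoms, :N_ATOM_FEATURES] = 0.0
                X0[mask_atoms, -1] = 1.0
            sub = None
            if collect is not None:
                sub = collect.setdefault(v.kind, {})
            H_views.append(self.encode_view(v, graph, ops=ops, X0=X0,
                                            collect=sub))
        H_out = self.fuse_and_transform(*H_views)
        graph_emb = self.gru_readout(H_out, graph.n_atoms)
        rep = concat([graph_emb, H_out[graph.n_atoms]], axis=0)
        return {"H_views": H_views, "H_out": H_out,
                "graph_embedding": graph_emb, "representation": rep}

    def predict(self, representation: Tensor) -> list[Tensor]:
        """Per-task outputs: probabilities for classification heads (via the
        logistic map), raw reals for regression heads."""
        outs = []
        rep = representation.reshape(1, -1)
        for t, kind in enumerate(self.task_types):
            z = rep @ self.params[f"head{t}.W"] + self.params[f"head{t}.b"]
            outs.append(z.sigmoid() if kind == "classification" else z)
        return outs

    def predict_logit(self, representation: Tensor, task: int) -> Tensor:
        rep = representation.reshape(1, -1)
        return rep @ self.params[f"head{task}.W"] + self.params[f"head{task}.b"]

    def pretrain_heads(self, H_out: Tensor, n_atoms: int) -> tuple[Tensor, Tensor]:
        """Node-feature reconstruction and global-descriptor predictions."""
        node_pred = H_out[:n_atoms] @ self.params["pre.node.W"] \
            + self.params["pre.node.b"]
        glob_pred = H_out[n_atoms:n_atoms + 1] @ self.params["pre.glob.W"] \
            + self.params["pre.glob.b"]
        return node_pred, glob_pred.reshape(-1)

    # -- persistence ----------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        meta = {"cfg": asdict(self.cfg), "n_tasks": self.n_tasks,
                "task_types": self.task_types, "seed": self.seed,
                "extra": extra or {}}
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load_meta(cls, path) -> dict:
        try:
            with np.load(path) as z:
                return json.loads(bytes(z["__meta__"]).decode())
        except Exception as exc:
            raise IOError(f"cannot read checkpoint {path}: {exc}") from exc

    @classmethod
    def load(cls, path) -> "Model":
        try:
            with np.load(path) as z:
                meta = json.loads(bytes(z["__meta__"]).decode())
                arrays = {k[len("param::"):]: z[k] for k in z.files
                          if k.startswith("param::")}
        except Exception as exc:
            raise IOError(f"cannot read checkpoint {path}: {exc}") from exc
        model = cls(EncoderConfig(**meta["cfg"]), meta["n_tasks"],
                    meta["task_types"], seed=meta["seed"])
        for k, v in arrays.items():
            if k not in model.params:
                raise IOError(f"checkpoint parameter {k!r} does not match "
                              "the configured architecture")
            model.params[k].data = v.astype(np.float64)
        return model

    def optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, lr=lr)
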
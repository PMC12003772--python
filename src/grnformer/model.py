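"""The bidirectional transformer with inspectable attention, and its decoders.

The encoder is a BERT-style pre-norm transformer: every gene and cell token
attends to every other token (no mask), residual blocks apply LayerNorm before
attention / MLP, the feed-forward block widens by 4x with a GELU activation,
and stochastic depth drops residual branches with a probability growing by
0.02 per layer during training only.  Attention is the exact
softmax(Q K^T / sqrt(d_k)) V computation; per-layer per-head Q and K tensors
can be cached on demand for gene-network extraction without changing the
outputs numerically.

Two decoders sit on top:

* the expression decoder maps each gene's output embedding through a
  [d, d, 3] MLP to the parameters of a zero-inflated negative binomial
  (ZINB): mean mu = exp(raw_a), inverse-dispersion theta = exp(raw_b) (both
  clamped to [-15, 15] before exponentiation to prevent overflow), and the
  zero-inflation logit rho = raw_c, so the dropout probability is
  pi = sigmoid(rho);
* one class decoder per annotated class maps the class's placeholder output
  embedding through a [d, d, d_A] MLP to logits over the d_A leaf labels of
  that class's ontology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import erf

from .encoding import TokenBatch, build_token_batch, init_scalar_mlp
from .vocab import GeneVocabulary, OntologyDAG, positional_encode

__all__ = ["ModelConfig", "ZINBParams", "ClassPrediction", "Model"]


@dataclass
class ModelConfig:
    n_layers: int = 2
    n_heads: int = 2
    d: int = 64
    context_size: int = 2200
    classes: tuple[str, ...] = ("cell_type",)
    mlp_ratio: int = 4
    dropout: float = 0.1
    stochastic_depth_increment: float = 0.02
    loss_mode: str = "zinb"  # zinb | nb | mse
    contrastive_sign: str = "as-printed"  # minimize (1-cos) | "repel": (1+cos)
    trainable_gene_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        self.classes = tuple(self.classes)

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    @property
    def placeholder_ids(self) -> tuple[str, ...]:
        return ("total_count", "default") + self.classes


@dataclass
class ZINBParams:
    """Per-cell per-gene ZINB parameters; pi of the mixture is sigmoid(rho)."""

    mu: np.ndarray
    theta: np.ndarray
    rho: np.ndarray

    def validate(self) -> "ZINBParams":
        for name in ("mu", "theta", "rho"):
            a = getattr(self, name)
            arr = a._value if hasattr(a, "_value") else a
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite values in ZINB parameter {name!r} "
                    "(expression decoder output)"
                )
        return self

    @property
    def pi(self) -> np.ndarray:
        rho = self.rho._value if hasattr(self.rho, "_value") else self.rho
        return 1.0 / (1.0 + np.exp(-np.clip(rho, -50, 50)))

    @property
    def expected(self) -> np.ndarray:
        """Expected count (1 - pi) * mu."""
        mu = self.mu._value if hasattr(self.mu, "_value") else self.mu
        return (1.0 - self.pi) * mu


@dataclass
class ClassPrediction:
    """Leaf logits and output embeddings for every decoded class."""

    logits: dict[str, np.ndarray]       # class -> (batch, d_A), pre-sigmoid
    embeddings: dict[str, np.ndarray]   # class -> (batch, d)
    ontologies: dict[str, OntologyDAG]

    def sigmoid(self, cls: str) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits[cls]))

    def probabilities(self, cls: str) -> np.ndarray:
        z = self.logits[cls]
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, cls: str, level: str | None = None):
        """Argmax leaf label; with ``level`` set, probabilities are first
        lifted to the children of that ontology node by summing descendant
        leaf probabilities."""
        onto = self.ontologies[cls]
        probs = self.probabilities(cls)
        if level is None:
            return np.array([onto.leaves[i] for i in probs.argmax(axis=-1)])
        groups = onto.children(level) or [level]
        lifted = np.stack(
            [probs[:, onto.leaf_descendant_indices(g)].sum(axis=-1) for g in groups],
            axis=-1,
        )
        return np.array([groups[i] for i in lifted.argmax(axis=-1)])

    def lift(self, cls: str, nodes: list[str]) -> np.ndarray:
        """Probability mass of each ontology node = sum of its leaves'."""
        onto = self.ontologies[cls]
        probs = self.probabilities(cls)
        return np.stack(
            [probs[:, onto.leaf_descendant_indices(n)].sum(axis=-1) for n in nodes],
            axis=-1,
        )


def logit_embedding(prediction: ClassPrediction, cls: str) -> np.ndarray:
    """Pre-sigmoid class logits reused as a cell embedding."""
    return np.asarray(prediction.logits[cls])


# ---------------------------------------------------------------------------
# functional forward pieces
# ---------------------------------------------------------------------------

def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _layer_norm(x, g, b, eps=1e-5):
    m = anp.mean(x, axis=-1, keepdims=True)
    v = anp.var(x, axis=-1, keepdims=True)
    return g * (x - m) / anp.sqrt(v + eps) + b


def _attention(x, lp, n_heads, qk_sink=None):
    """Exact multi-head self-attention; optionally records Q/K per head."""
    B, L, d = np.shape(x)[0], np.shape(x)[1], np.shape(x)[2]
    dk = d // n_heads
    qkv = anp.dot(x, lp["w_qkv"]) + lp["b_qkv"]
    q = anp.reshape(qkv[..., :d], (B, L, n_heads, dk))
    k = anp.reshape(qkv[..., d : 2 * d], (B, L, n_heads, dk))
    v = anp.reshape(qkv[..., 2 * d :], (B, L, n_heads, dk))
    if qk_sink is not None:
        qk_sink.append((q, k))
    scores = anp.einsum("blhd,bmhd->bhlm", q, k) / np.sqrt(dk)
    scores = scores - anp.max(scores, axis=-1, keepdims=True)
    w = anp.exp(scores)
    att = w / anp.sum(w, axis=-1, keepdims=True)
    out = anp.einsum("bhlm,bmhd->blhd", att, v)
    return anp.dot(anp.reshape(out, (B, L, d)), lp["w_o"]) + lp["b_o"]


def transformer_forward(
    params: dict,
    cfg: ModelConfig,
    tokens,
    train: bool = False,
    rng: np.random.Generator | None = None,
    collect_qk: bool = False,
):
    """Run the token matrix through the residual stack; returns the final
    LayerNorm-ed token outputs and, optionally, per-layer (Q, K) tensors."""
    x = tokens
    B = np.shape(tokens)[0]
    qk_cache: list | None = [] if collect_qk else None
    for li, lp in enumerate(params["layers"]):
        p_drop = cfg.stochastic_depth_increment * (li + 1) if train else 0.0
        h = _attention(
            _layer_norm(x, lp["ln1_g"], lp["ln1_b"]), lp, cfg.n_heads,
            qk_sink=qk_cache,
        )
        x = x + _residual_drop(h, p_drop, B, rng)
        h = _layer_norm(x, lp["ln2_g"], lp["ln2_b"])
        h = anp.dot(_gelu(anp.dot(h, lp["w_mlp1"]) + lp["b_mlp1"]), lp["w_mlp2"]) + lp["b_mlp2"]
        x = x + _residual_drop(h, p_drop, B, rng)
    x = _layer_norm(x, params["final_ln_g"], params["final_ln_b"])
    return x, qk_cache


def _residual_drop(h, p: float, batch: int, rng):
    if p <= 0.0:
        return h
    if rng is None:
        raise ValueError("stochastic depth in training mode needs an rng")
    keep = (rng.random(batch) >= p).astype(float) / (1.0 - p)
    return h * keep[:, None, None]


def _mlp3(lp, x):
    return anp.dot(_gelu(anp.dot(x, lp["w1"]) + lp["b1"]), lp["w2"]) + lp["b2"]


# ---------------------------------------------------------------------------
# the model object: config + parameters + vocabulary + ontologies
# ---------------------------------------------------------------------------

@dataclass
class ForwardOutput:
    tokens: np.ndarray                      # (B, C+P, d)
    gene_embeddings: np.ndarray             # (B, C, d)
    placeholder_embeddings: dict[str, np.ndarray]
    qk: list | None = None                  # [(Q, K)] per layer if requested


class Model:
    """Bundles parameters, frozen tables, vocabulary and label ontologies."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: GeneVocabulary,
        ontologies: dict[str, OntologyDAG],
        seed: int = 0,
    ):
        if vocab.d != config.d:
            raise ValueError(
                f"vocabulary embedding dim {vocab.d} != model dim {config.d}"
            )
        for cls in config.classes:
            if cls not in ontologies:
                raise KeyError(f"class {cls!r} has no ontology (use OntologyDAG.flat)")
        self.config = config
        self.vocab = vocab
        self.ontologies = {c: ontologies[c] for c in config.classes}
        rng = np.random.default_rng(seed)
        self.params = self._init_params(rng)
        self.frozen = {
            "gene_emb": np.array(vocab.id_embeddings),
            "pe": positional_encode(
                np.arange(int(vocab.location_index.max()) + 1), config.d
            ),
        }
        if config.trainable_gene_embeddings:
            self.params["gene_emb"] = self.frozen.pop("gene_emb")

    # -- initialization -----------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        d, dm = cfg.d, cfg.d * cfg.mlp_ratio
        s = 1.0 / np.sqrt(d)
        layers = []
        for _ in range(cfg.n_layers):
            layers.append(
                {
                    "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
                    "w_qkv": rng.normal(scale=s, size=(d, 3 * d)),
                    "b_qkv": np.zeros(3 * d),
                    "w_o": rng.normal(scale=s, size=(d, d)),
                    "b_o": np.zeros(d),
                    "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
                    "w_mlp1": rng.normal(scale=s, size=(d, dm)),
                    "b_mlp1": np.zeros(dm),
                    "w_mlp2": rng.normal(scale=1.0 / np.sqrt(dm), size=(dm, d)),
                    "b_mlp2": np.zeros(d),
                }
            )
        params = {
            "layers": layers,
            "final_ln_g": np.ones(d), "final_ln_b": np.zeros(d),
            "expr_enc": init_scalar_mlp(d, rng),
            "count_enc": init_scalar_mlp(d, rng),
            # learned placeholders: default + one per class (total_count is
            # carried by the encoded total instead of a learned vector)
            "placeholders": rng.normal(scale=s, size=(1 + len(cfg.classes), d)),
            "expr_dec": {
                "w1": rng.normal(scale=s, size=(d, d)), "b1": np.zeros(d),
                "w2": rng.normal(scale=s, size=(d, 3)), "b2": np.zeros(3),
            },
        }
        for cls in cfg.classes:
            d_a = self.ontologies[cls].n_leaves
            params[f"cls_dec_{cls}"] = {
                "w1": rng.normal(scale=s, size=(d, d)), "b1": np.zeros(d),
                # final classifier layer: weights ~ N(1, 0.02), bias -0.12
                "w2": rng.normal(loc=1.0, scale=0.02, size=(d, d_a)),
                "b2": np.full(d_a, -0.12),
            }
        return params

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        batch: TokenBatch,
        params: dict | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        collect_qk: bool = False,
        include_expression: bool = True,
        placeholder_override: dict | None = None,
        total_override=None,
    ) -> ForwardOutput:
        cfg = self.config
        params = self.params if params is None else params
        gene_emb = params.get("gene_emb", self.frozen.get("gene_emb"))
        tokens = build_token_batch(
            batch,
            gene_embeddings=gene_emb,
            pe_table=self.frozen["pe"],
            location_index=self.vocab.location_index,
            expr_params=params["expr_enc"],
            count_params=params["count_enc"],
            placeholders=params["placeholders"],
            include_expression=include_expression,
            placeholder_override=placeholder_override,
            total_override=total_override,
            train=train,
            rng=rng,
        )
        out, qk = transformer_forward(
            params, cfg, tokens, train=train, rng=rng, collect_qk=collect_qk
        )
        C = batch.context_size
        placeholder_out = {
            name: out[:, C + i, :] for i, name in enumerate(batch.placeholder_ids)
        }
        return ForwardOutput(
            tokens=out,
            gene_embeddings=out[:, :C, :],
            placeholder_embeddings=placeholder_out,
            qk=qk,
        )

    # -- decoders -----------------------------------------------------------

    def decode_expression(self, gene_embeddings, params: dict | None = None,
                          validate: bool = True) -> ZINBParams:
        params = self.params if params is None else params
        raw = _mlp3(params["expr_dec"], gene_embeddings)
        mu = anp.exp(anp.clip(raw[..., 0], -15.0, 15.0))
        theta = anp.exp(anp.clip(raw[..., 1], -15.0, 15.0))
        zp = ZINBParams(mu=mu, theta=theta, rho=raw[..., 2])
        return zp.validate() if validate else zp

    def decode_classes(
        self, placeholder_embeddings: dict, params: dict | None = None
    ) -> ClassPrediction:
        params = self.params if params is None else params
        logits = {}
        embeddings = {}
        for cls in self.config.classes:
            if cls not in placeholder_embeddings:
                continue
            e = placeholder_embeddings[cls]
            logits[cls] = _mlp3(params[f"cls_dec_{cls}"], e)
            embeddings[cls] = e
        return ClassPrediction(
            logits={k: np.asarray(v._value if hasattr(v, "_value") else v)
                    for k, v in logits.items()},
            embeddings={k: np.asarray(v._value if hasattr(v, "_value") else v)
                        for k, v in embeddings.items()},
            ontologies=self.ontologies,
        )

    def class_logits(self, placeholder_embeddings: dict, params: dict):
        """Autograd-traced class logits (used inside the training loss)."""
        return {
            cls: _mlp3(params[f"cls_dec_{cls}"], placeholder_embeddings[cls])
            for cls in self.config.classes
        }

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        flat = {}
        _flatten("p", self.params, flat)
        _flatten("f", self.frozen, flat)
        np.savez_compressed(path / "weights.npz", **flat)
        meta = {
            "config": asdict(self.config),
            "gene_ids": self.vocab.gene_ids,
            "chromosome": self.vocab.chromosome,
            "start": np.asarray(self.vocab.start).tolist(),
            "placeholder_ids": list(self.config.placeholder_ids),
            "ontologies": {
                c: {"nodes": o.nodes, "parent_edges": o.parent_edges}
                for c, o in self.ontologies.items()
            },
        }
        (path / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        config = ModelConfig(**{
            k: (tuple(v) if k == "classes" else v) for k, v in meta["config"].items()
        })
        ontologies = {
            c: OntologyDAG(
                nodes=o["nodes"],
                parent_edges=[tuple(e) for e in o["parent_edges"]],
            )
            for c, o in meta["ontologies"].items()
        }
        with np.load(path / "weights.npz") as zf:
            flat = dict(zf)
        params = _unflatten("p", flat)
        frozen = _unflatten("f", flat)
        vocab = GeneVocabulary(
            gene_ids=meta["gene_ids"],
            id_embeddings=frozen.get("gene_emb", params.get("gene_emb")),
            chromosome=meta["chromosome"],
            start=np.array(meta["start"]),
            location_index=_recover_location(meta),
        )
        model = cls.__new__(cls)
        model.config = config
        model.vocab = vocab
        model.ontologies = ontologies
        model.params = params
        model.frozen = frozen
        return model


def _recover_location(meta) -> np.ndarray:
    from .vocab import assign_location_indices
    import pandas as pd

    table = pd.DataFrame(
        {
            "gene_id": meta["gene_ids"],
            "chromosome": meta["chromosome"],
            "start": meta["start"],
        }
    )
    loc = assign_location_indices(table)
    return np.array([loc[g] for g in meta["gene_ids"]])


def _flatten(prefix: str, tree, out: dict) -> None:
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten(f"{prefix}.{k}", v, out)
    elif isinstance(tree, list):
        for i, v in enumerate(tree):
            _flatten(f"{prefix}#{i}", v, out)
    else:
        out[prefix] = np.asarray(tree)


def _unflatten(prefix: str, flat: dict):
    keys = [k for k in flat if k == prefix or k.startswith(prefix + ".") or k.startswith(prefix + "#")]
    if keys == [prefix]:
        return flat[prefix]
    heads = {}
    is_list = any(k.startswith(prefix + "#") for k in keys)
    sep = "#" if is_list else "."
    for k in keys:
        rest = k[len(prefix) + 1 :]
        head = rest.split(".")[0].split("#")[0]
        heads.setdefault(head, None)
    if is_list:
        n = len(heads)
        return [_unflatten(f"{prefix}#{i}", flat) for i in range(n)]
    return {h: _unflatten(f"{prefix}.{h}", flat) for h in heads}
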
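"""Transformer input construction.

A cell enters the model as a sequence of per-gene tokens followed by a small
block of cell-level tokens.  Each gene token is the elementwise sum of three
streams: the gene identity embedding g_j, an MLP encoding of the
log2-transformed count e_ij, and a sinusoidal positional encoding of the
gene's genome-location index l_j.  The cell-level block holds one token
carrying the encoded total transcript count e_t,i and one learned placeholder
vector p_A per requested class (default embedding, cell type, ...), identical
across cells, which the transformer fills in during the forward pass.

All functions here are written against ``autograd.numpy`` so gradients flow
through token construction during pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

__all__ = [
    "init_scalar_mlp",
    "scalar_mlp",
    "encode_expression",
    "encode_total_count",
    "sample_context",
    "TokenBatch",
    "build_token_batch",
]

DROPOUT_RATE = 0.1


# ---------------------------------------------------------------------------
# the scalar-input expression MLP: two layers of
# Dropout(ReLU(LayerNorm(Linear(.)))) with dims 1 -> d -> d
# ---------------------------------------------------------------------------

def init_scalar_mlp(d: int, rng: np.random.Generator) -> dict:
    # uniform fan-in init with nonzero biases: with zero biases, LayerNorm of
    # x*w1 is invariant to the scale of x and every positive count would map
    # to the same token
    s = 1.0 / np.sqrt(d)
    return {
        "w1": rng.uniform(-1.0, 1.0, size=(1, d)),
        "b1": rng.uniform(-1.0, 1.0, size=d),
        "ln1_g": np.ones(d),
        "ln1_b": np.zeros(d),
        "w2": rng.uniform(-s, s, size=(d, d)),
        "b2": rng.uniform(-s, s, size=d),
        "ln2_g": np.ones(d),
        "ln2_b": np.zeros(d),
    }


def _layer_norm(x, g, b, eps: float = 1e-5):
    m = anp.mean(x, axis=-1, keepdims=True)
    v = anp.var(x, axis=-1, keepdims=True)
    return g * (x - m) / anp.sqrt(v + eps) + b


def _dropout(x, rate: float, train: bool, rng: np.random.Generator | None):
    if not train or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = rng.random(np.shape(x)) >= rate
    return x * mask / (1.0 - rate)


def scalar_mlp(
    params: dict,
    x,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Apply the two-layer scalar-input MLP to an array of scalars.

    ``x`` has any shape; the output appends a trailing model dimension.
    Deterministic when ``train`` is False (dropout off).
    """
    h = x[..., None] * params["w1"][0] + params["b1"]
    h = _dropout(
        anp.maximum(0.0, _layer_norm(h, params["ln1_g"], params["ln1_b"])),
        DROPOUT_RATE, train, rng,
    )
    h = anp.dot(h, params["w2"]) + params["b2"]
    h = _dropout(
        anp.maximum(0.0, _layer_norm(h, params["ln2_g"], params["ln2_b"])),
        DROPOUT_RATE, train, rng,
    )
    return h


def encode_expression(params, x, train=False, rng=None):
    """Expression token: MLP applied to log2(x + 1); x is a raw count."""
    xv = anp.asarray(x, dtype=float) if not hasattr(x, "_value") else x
    arr = np.asarray(xv) if isinstance(xv, np.ndarray) or np.isscalar(xv) else None
    if arr is not None:
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression counts must be finite")
        if np.any(arr < 0):
            raise ValueError("expression counts must be nonnegative")
    return scalar_mlp(params, anp.log2(xv + 1.0), train=train, rng=rng)


def encode_total_count(params, t, train=False, rng=None):
    """Total-count token: a separate MLP of the same structure on log2(1+t)."""
    tv = np.asarray(t, dtype=float) if not hasattr(t, "_value") else t
    if isinstance(tv, np.ndarray) and np.any(tv < 0):
        raise ValueError("total counts must be nonnegative")
    return scalar_mlp(params, anp.log2(1.0 + tv), train=train, rng=rng)


# ---------------------------------------------------------------------------
# context-gene sampling
# ---------------------------------------------------------------------------

def sample_context(
    cell: np.ndarray,
    context_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the gene positions fed to the model for one cell.

    A uniform random subset of the expressed genes when there are enough;
    otherwise all expressed genes padded with uniformly sampled unexpressed
    genes carrying value 0.  Never returns duplicates.
    """
    cell = np.asarray(cell)
    if context_size > cell.shape[0]:
        raise ValueError(
            f"context_size {context_size} exceeds vocabulary size {cell.shape[0]}"
        )
    expressed = np.nonzero(cell > 0)[0]
    if len(expressed) >= context_size:
        idx = rng.choice(expressed, size=context_size, replace=False)
    else:
        unexpressed = np.nonzero(cell == 0)[0]
        pad = rng.choice(
            unexpressed, size=context_size - len(expressed), replace=False
        )
        idx = np.concatenate([expressed, pad])
    return idx, cell[idx]


# ---------------------------------------------------------------------------
# token batch
# ---------------------------------------------------------------------------

@dataclass
class TokenBatch:
    """A minibatch of sampled contexts ready for the transformer.

    ``placeholder_ids`` fixes the order of the cell-level token block; it is
    serialized with the model because decoders index outputs positionally.
    """

    gene_indices: np.ndarray  # (batch, context) int
    values: np.ndarray        # (batch, context) raw counts at those positions
    totals: np.ndarray        # (batch,) per-cell total transcript count
    placeholder_ids: tuple[str, ...] = ("total_count", "default")
    target_values: np.ndarray | None = None  # denoising target at same positions

    def __post_init__(self) -> None:
        if self.gene_indices.shape != np.shape(self.values):
            raise ValueError("gene_indices/values shape mismatch")
        if self.gene_indices.shape[0] != len(self.totals):
            raise ValueError("totals length mismatch")

    @property
    def n_cells(self) -> int:
        return self.gene_indices.shape[0]

    @property
    def context_size(self) -> int:
        return self.gene_indices.shape[1]


def build_token_batch(
    batch: TokenBatch,
    gene_embeddings,
    pe_table,
    location_index: np.ndarray,
    expr_params: dict,
    count_params: dict,
    placeholders,
    include_expression: bool = True,
    placeholder_override: dict | None = None,
    total_override=None,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Assemble the (batch, context + n_placeholders, d) input token matrix.

    Gene tokens are g_j + e_ij + l_j; with ``include_expression=False`` (the
    bottleneck decoding pass) the expression stream is omitted entirely.
    ``placeholder_override`` maps placeholder names to (batch, d) arrays that
    replace the learned placeholder vectors (again for bottleneck decoding);
    ``total_override`` substitutes the totals fed to the total-count encoder.
    """
    B, C = batch.gene_indices.shape
    idtok = gene_embeddings[batch.gene_indices]          # (B, C, d)
    loctok = pe_table[location_index[batch.gene_indices]]
    if include_expression:
        exptok = encode_expression(expr_params, batch.values, train=train, rng=rng)
        gene_tokens = idtok + exptok + loctok
    else:
        gene_tokens = idtok + loctok

    totals = batch.totals if total_override is None else total_override
    learned_order = [n for n in batch.placeholder_ids if n != "total_count"]
    rows = []
    for name in batch.placeholder_ids:
        if placeholder_override is not None and name in placeholder_override:
            rows.append(placeholder_override[name])
        elif name == "total_count":
            rows.append(encode_total_count(count_params, totals, train=train, rng=rng))
        else:
            # learned placeholder, identical across cells in the batch
            rows.append(anp.tile(placeholders[learned_order.index(name)][None, :], (B, 1)))
    cell_tokens = anp.stack(rows, axis=1)                # (B, P, d)
    return anp.concatenate([gene_tokens, cell_tokens], axis=1)
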
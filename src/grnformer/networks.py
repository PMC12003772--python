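"""Gene networks from attention heads.

Each attention head of the transformer is a candidate gene-gene connection
matrix.  For a set of cells U sharing a gene ordering, the meta-cell attention
of a head is softmax(mean_U(Q) mean_U(K)^T / sqrt(d_k)): queries of an average
cell looking across the keys of the whole set.  Heads can be averaged
uniformly ("all-heads-mean") or selected against a ground-truth network with a
nonnegative ridge classifier, then averaged without weighting.

Orientation convention: in the as-computed matrix, rows are targets and
columns are regulators (the softmax normalizes over each target's incoming
mass).  ``orient`` transposes for comparisons against ground truths built the
other way around.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import Ridge

from .encoding import TokenBatch, sample_context
from .model import Model

__all__ = [
    "HeadAttention",
    "NetworkMatrix",
    "HeadSelection",
    "metacell_attention",
    "attention_heads",
    "mean_network",
    "select_heads",
    "genome_wide_network",
    "orient",
    "subset_to_tf",
]


@dataclass
class HeadAttention:
    """Meta-cell attention matrix of one (layer, head) pair; row-stochastic."""

    layer: int
    head: int
    matrix: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        rs = self.matrix.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1 within 1e-5")


@dataclass
class NetworkMatrix:
    """Gene-by-gene nonnegative score matrix with an orientation convention.

    ``row_genes`` index the target axis and ``col_genes`` the regulator axis
    in the as-computed orientation; NaN entries mark gene pairs that were
    never co-sampled (absent, not zero).
    """

    scores: np.ndarray
    row_genes: list[str]
    col_genes: list[str]
    orientation: str = "as-computed"  # or "transposed"
    provenance: str = "all-heads-mean"

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.row_genes), len(self.col_genes)):
            raise ValueError("scores shape does not match gene axes")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and finite.min() < 0:
            raise ValueError("scores must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        if self.row_genes != self.col_genes:
            raise ValueError("network is not square over a single gene set")
        return self.row_genes

    def edge_score(self, source: str, target: str) -> float:
        """Score of the directed edge source -> target under the current
        axis layout (targets on rows, regulators on columns)."""
        return float(
            self.scores[self.row_genes.index(target), self.col_genes.index(source)]
        )

    def to_edge_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(np.isfinite(self.scores))
        return pd.DataFrame(
            {
                "regulator": [self.col_genes[c] for c in cols],
                "target": [self.row_genes[r] for r in rows],
                "score": self.scores[rows, cols],
            }
        )

    def save(self, path: str | Path) -> None:
        """Gzip TSV edge list plus a JSON sidecar with the metadata."""
        path = Path(path)
        with gzip.open(path, "wt") as fh:
            self.to_edge_frame().to_csv(fh, sep="\t", index=False)
        sidecar = {
            "orientation": self.orientation,
            "provenance": self.provenance,
            "row_genes": self.row_genes,
            "col_genes": self.col_genes,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkMatrix":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        with gzip.open(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t")
        rows = {g: i for i, g in enumerate(meta["row_genes"])}
        cols = {g: i for i, g in enumerate(meta["col_genes"])}
        scores = np.full((len(rows), len(cols)), np.nan)
        scores[
            [rows[t] for t in df["target"]], [cols[r] for r in df["regulator"]]
        ] = df["score"].to_numpy()
        return cls(
            scores=scores,
            row_genes=meta["row_genes"],
            col_genes=meta["col_genes"],
            orientation=meta["orientation"],
            provenance=meta["provenance"],
        )


@dataclass
class HeadSelection:
    selected: list[tuple[int, int]]
    coefficients: np.ndarray = field(default=None)  # diagnostic only

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("head selection must be nonempty")
        if self.coefficients is not None and (self.coefficients < 0).any():
            raise ValueError("coefficients must be nonnegative")


# ---------------------------------------------------------------------------
# attention extraction
# ---------------------------------------------------------------------------

def metacell_attention(
    Q: np.ndarray, K: np.ndarray, d_k: int | None = None,
    layer: int = 0, head: int = 0, gene_ids: list[str] | None = None,
) -> HeadAttention:
    """softmax(mean_U(Q) mean_U(K)^T / sqrt(d_k)) over a cell set U.

    ``Q`` and ``K`` have shape (n_cells, n_genes, d_k) — or (n_genes, d_k)
    for a single cell, in which case the result equals single-cell attention.
    """
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    if Q.ndim == 2:
        Q, K = Q[None], K[None]
    if Q.shape != K.shape:
        raise ValueError("Q and K must share the (cells, genes, d_k) shape")
    d_k = Q.shape[-1] if d_k is None else d_k
    q = Q.mean(axis=0)
    k = K.mean(axis=0)
    att = softmax(q @ k.T / np.sqrt(d_k), axis=1)
    return HeadAttention(
        layer=layer, head=head, matrix=att,
        gene_ids=gene_ids if gene_ids is not None else
        [f"g{i}" for i in range(att.shape[0])],
    )


def attention_heads(
    model: Model,
    counts: np.ndarray,
    gene_ids: list[str],
    max_cells: int | None = None,
) -> list[HeadAttention]:
    """Meta-cell attention for every (layer, head) of the model.

    All cells are passed with the same fixed gene ordering (the provided
    ``gene_ids``); placeholder rows/columns are dropped before assembly.
    """
    gi = model.vocab.index_of(gene_ids)
    n_cells = counts.shape[0] if max_cells is None else min(max_cells, counts.shape[0])
    batch = TokenBatch(
        gene_indices=np.tile(gi, (n_cells, 1)),
        values=np.asarray(counts[:n_cells], dtype=float),
        totals=np.asarray(counts[:n_cells]).sum(axis=1).astype(float),
        placeholder_ids=model.config.placeholder_ids,
    )
    out = model.forward(batch, collect_qk=True)
    n_genes = len(gene_ids)
    heads: list[HeadAttention] = []
    for layer, (q, k) in enumerate(out.qk):
        # (B, L, h, dk) -> per head, genes only
        for h in range(model.config.n_heads):
            heads.append(
                metacell_attention(
                    q[:, :n_genes, h, :], k[:, :n_genes, h, :],
                    layer=layer, head=h, gene_ids=list(gene_ids),
                )
            )
    return heads


def mean_network(heads: list[HeadAttention]) -> NetworkMatrix:
    """Unweighted elementwise mean of attention heads."""
    genes = heads[0].gene_ids
    for h in heads:
        if h.gene_ids != genes or h.matrix.shape != heads[0].matrix.shape:
            raise ValueError("heads must share the gene set")
    return NetworkMatrix(
        scores=np.mean([h.matrix for h in heads], axis=0),
        row_genes=list(genes),
        col_genes=list(genes),
        provenance="all-heads-mean",
    )


# ---------------------------------------------------------------------------
# head selection against a ground truth
# ---------------------------------------------------------------------------

def select_heads(
    heads: list[HeadAttention],
    truth,
    train_fraction: float = 0.5,
    seed: int = 0,
    max_negative_ratio: int = 10,
) -> tuple[HeadSelection, NetworkMatrix]:
    """Pick the heads whose attention predicts a ground-truth network.

    Gene pairs present in the truth's universe are featurized by their
    per-head attention scores; a ridge regressor (L2 penalty 1, nonnegative
    coefficients, no intercept) is fit on a train split of edges/non-edges
    against targets {-1, +1}.  Heads with a strictly positive coefficient are
    selected and averaged without weighting.  Non-edges are subsampled to at
    most ``max_negative_ratio`` times the positives.
    """
    rng = np.random.default_rng(seed)
    genes = heads[0].gene_ids
    gidx = {g: i for i, g in enumerate(genes)}
    universe = [g for g in truth.universe if g in gidx]
    pos_pairs = [
        (s, t) for (s, t) in truth.edges if s in gidx and t in gidx and s != t
    ]
    if not pos_pairs:
        raise ValueError("no ground-truth edges map onto the network's genes")
    pos_set = set(pos_pairs)
    neg_pairs = [
        (s, t)
        for s in universe for t in universe
        if s != t and (s, t) not in pos_set
    ]
    if not neg_pairs:
        raise ValueError("degenerate truth: no negative pairs")
    if len(neg_pairs) > max_negative_ratio * len(pos_pairs):
        pick = rng.choice(
            len(neg_pairs), size=max_negative_ratio * len(pos_pairs), replace=False
        )
        neg_pairs = [neg_pairs[i] for i in pick]

    pairs = pos_pairs + neg_pairs
    y = np.concatenate([np.ones(len(pos_pairs)), -np.ones(len(neg_pairs))])
    # attention entry for edge s -> t is [target row, regulator column]
    rows = np.array([gidx[t] for _, t in pairs])
    cols = np.array([gidx[s] for s, _ in pairs])
    X = np.stack([h.matrix[rows, cols] for h in heads], axis=1)

    order = rng.permutation(len(pairs))
    n_train = max(2, int(round(train_fraction * len(pairs))))
    tr = order[:n_train]
    if len(set(y[tr])) < 2:
        raise ValueError("train split lacks both positive and negative pairs")

    reg = Ridge(alpha=1.0, positive=True, fit_intercept=False)
    reg.fit(X[tr], y[tr])
    coefs = np.maximum(reg.coef_, 0.0)
    chosen = [i for i, c in enumerate(coefs) if c > 0]
    if not chosen:
        raise ValueError("no head received a positive coefficient")
    selection = HeadSelection(
        selected=[(heads[i].layer, heads[i].head) for i in chosen],
        coefficients=coefs,
    )
    net = mean_network([heads[i] for i in chosen])
    net.provenance = "selected-heads:" + ",".join(
        f"L{l}H{h}" for l, h in selection.selected
    )
    return selection, net


# ---------------------------------------------------------------------------
# genome-wide assembly
# ---------------------------------------------------------------------------

def genome_wide_network(
    model: Model,
    counts: np.ndarray,
    block_size: int,
    rng: np.random.Generator,
    n_rounds: int = 8,
    max_absent_fraction: float = 0.5,
) -> NetworkMatrix:
    """Vocabulary-wide network from repeated forward passes on gene blocks.

    Each round permutes the vocabulary into blocks of ``block_size`` genes,
    computes the all-heads-mean meta-cell attention per block, and scatters it
    into a vocabulary-sized accumulator.  Entries are averaged over the number
    of times each ordered pair co-occurred; never co-sampled pairs stay NaN
    (absent, not zero) and their fraction is reported if excessive.
    """
    n_vocab = len(model.vocab)
    if block_size > n_vocab:
        raise ValueError("block_size exceeds the vocabulary")
    acc = np.zeros((n_vocab, n_vocab))
    cnt = np.zeros((n_vocab, n_vocab))
    all_ids = np.array(model.vocab.gene_ids)
    for _ in range(n_rounds):
        perm = rng.permutation(n_vocab)
        for start in range(0, n_vocab, block_size):
            blk = np.sort(perm[start : start + block_size])
            if len(blk) < 2:
                continue
            heads = attention_heads(
                model, counts[:, blk], [all_ids[i] for i in blk]
            )
            sub = mean_network(heads).scores
            acc[np.ix_(blk, blk)] += sub
            cnt[np.ix_(blk, blk)] += 1.0
    with np.errstate(invalid="ignore"):
        scores = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    absent = float(np.mean(cnt == 0))
    net = NetworkMatrix(
        scores=scores,
        row_genes=list(all_ids),
        col_genes=list(all_ids),
        provenance=f"genome-wide:block={block_size},rounds={n_rounds},"
        f"absent={absent:.3f}",
    )
    if absent > max_absent_fraction:
        import warnings

        warnings.warn(
            f"{absent:.1%} of gene pairs were never co-sampled; "
            "increase n_rounds or block_size",
            stacklevel=2,
        )
    return net


# ---------------------------------------------------------------------------
# orientation and TF subsetting
# ---------------------------------------------------------------------------

def orient(network: NetworkMatrix) -> NetworkMatrix:
    """Transpose the score matrix and flip the orientation flag (involutive)."""
    return NetworkMatrix(
        scores=network.scores.T.copy(),
        row_genes=list(network.col_genes),
        col_genes=list(network.row_genes),
        orientation=(
            "transposed" if network.orientation == "as-computed" else "as-computed"
        ),
        provenance=network.provenance,
    )


def subset_to_tf(network: NetworkMatrix, tf_ids: list[str]) -> NetworkMatrix:
    """Restrict the regulator (column) axis to transcription factors."""
    keep = [g for g in network.col_genes if g in set(tf_ids)]
    if not keep:
        raise ValueError("no TF intersects the network's regulator axis")
    cols = [network.col_genes.index(g) for g in keep]
    return NetworkMatrix(
        scores=network.scores[:, cols],
        row_genes=list(network.row_genes),
        col_genes=keep,
        orientation=network.orientation,
        provenance=network.provenance + "+tf-subset",
    )
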
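"""Zero-shot task protocols on a trained model.

Denoising treats upsampling as asking the model for the expected ZINB profile
at a requested sequencing depth: the total-count token carries the target
depth, and the denoised value of a gene is its expected count
(1 - pi) * mu.  Scoring follows the downsample-and-recover protocol: the
Spearman correlation with the true profile, computed only over the genes
initially expressed in the cell, compared before and after denoising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoding import TokenBatch
from .model import ClassPrediction, Model, ZINBParams, logit_embedding
from .synthetic import CountMatrix

__all__ = [
    "DenoisingReport",
    "denoise",
    "evaluate_denoising",
    "predict_labels",
    "embed",
    "select_variable_genes",
]


@dataclass
class DenoisingReport:
    spearman_noisy: np.ndarray
    spearman_denoised: np.ndarray
    delta: np.ndarray
    mean_delta: float
    n_skipped: int
    subpopulation_mask: np.ndarray | None = None


def _forward_cells(
    model: Model,
    counts: np.ndarray,
    gene_ids: list[str] | None = None,
    totals: np.ndarray | None = None,
    batch_size: int = 16,
):
    """Evaluation-mode forward over full (or given) gene contexts, batched."""
    gene_ids = model.vocab.gene_ids if gene_ids is None else gene_ids
    gi = model.vocab.index_of(gene_ids)
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1) if totals is None else np.asarray(totals, float)
    outs = []
    for start in range(0, counts.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        batch = TokenBatch(
            gene_indices=np.tile(gi, (counts[sl].shape[0], 1)),
            values=counts[sl],
            totals=totals[sl],
            placeholder_ids=model.config.placeholder_ids,
        )
        outs.append(model.forward(batch))
    return outs, gi


def denoise(
    model: Model,
    counts: np.ndarray,
    gene_ids: list[str] | None = None,
    target_depth: float | np.ndarray | None = None,
) -> tuple[np.ndarray, ZINBParams]:
    """Expected expression profile at the requested sequencing depth.

    Returns ``(expected, params)`` where expected = (1 - pi) * mu per gene
    and ``params`` are the full decoded ZINB parameters.  ``target_depth``
    overrides the total-count token (scalar or per-cell); by default the
    cells' own totals are used.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if target_depth is not None:
        td = np.broadcast_to(
            np.asarray(target_depth, dtype=float), (counts.shape[0],)
        ).copy()
        if (td <= 0).any():
            raise ValueError("target_depth must be positive")
    else:
        td = None
    outs, _ = _forward_cells(model, counts, gene_ids, totals=td)
    mus, thetas, rhos = [], [], []
    for out in outs:
        zp = model.decode_expression(out.gene_embeddings)
        mus.append(np.asarray(zp.mu))
        thetas.append(np.asarray(zp.theta))
        rhos.append(np.asarray(zp.rho))
    params = ZINBParams(
        mu=np.concatenate(mus), theta=np.concatenate(thetas),
        rho=np.concatenate(rhos),
    )
    return params.expected, params


def evaluate_denoising(
    true: np.ndarray,
    noisy: np.ndarray,
    denoised: np.ndarray,
    subpopulation_mask: np.ndarray | None = None,
    min_expressed: int = 3,
) -> DenoisingReport:
    """Per-cell Spearman improvement of denoised over noisy profiles.

    Correlations are computed only over genes with true count > 0 in that
    cell (average-rank tie handling); cells with fewer than ``min_expressed``
    expressed genes are skipped and counted.  ``subpopulation_mask`` narrows
    only the averaging set, never the per-cell values.
    """
    true = np.atleast_2d(true)
    noisy = np.atleast_2d(noisy)
    denoised = np.atleast_2d(denoised)
    if not (true.shape == noisy.shape == denoised.shape):
        raise ValueError("true/noisy/denoised shapes must match")
    n = true.shape[0]
    sn = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        expressed = true[i] > 0
        if expressed.sum() < min_expressed:
            skipped += 1
            continue
        sn[i] = stats.spearmanr(noisy[i, expressed], true[i, expressed]).statistic
        sd[i] = stats.spearmanr(denoised[i, expressed], true[i, expressed]).statistic
    delta = sd - sn
    mask = (
        np.ones(n, dtype=bool) if subpopulation_mask is None
        else np.asarray(subpopulation_mask, dtype=bool)
    )
    valid = mask & np.isfinite(delta)
    return DenoisingReport(
        spearman_noisy=sn,
        spearman_denoised=sd,
        delta=delta,
        mean_delta=float(np.mean(delta[valid])) if valid.any() else np.nan,
        n_skipped=skipped,
        subpopulation_mask=subpopulation_mask,
    )


def select_variable_genes(counts: np.ndarray, n_top: int = 5000) -> np.ndarray:
    """Indices of the most variable genes on log-normalized counts."""
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    logn = np.log1p(counts / depth * np.median(depth))
    var = logn.var(axis=0)
    return np.sort(np.argsort(-var)[:n_top])


def predict_labels(
    model: Model,
    counts: np.ndarray,
    classes: list[str] | None = None,
    level: str | None = None,
    top_k: int = 1,
):
    """Per-class leaf probabilities and top labels for a batch of cells.

    With ``level`` set, probabilities are lifted to the children of that
    ontology node before the argmax.  Returns ``(labels, probabilities)``
    dicts keyed by class.
    """
    classes = list(model.config.classes) if classes is None else classes
    for cls in classes:
        if cls not in model.config.classes:
            raise KeyError(f"model has no class {cls!r}")
    outs, _ = _forward_cells(model, counts)
    labels: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    for cls in classes:
        emb = np.concatenate(
            [o.placeholder_embeddings[cls] for o in outs], axis=0
        )
        pred = model.decode_classes({cls: emb})
        probs[cls] = pred.probabilities(cls)
        labels[cls] = pred.predict(cls, level=level)
        if top_k > 1:
            order = np.argsort(-probs[cls], axis=1)[:, :top_k]
            labels[cls + "_topk"] = np.array(
                [[model.ontologies[cls].leaves[j] for j in row] for row in order]
            )
    return labels, probs


def embed(model: Model, counts: np.ndarray, source: str = "default-token"):
    """Cell embedding matrix from the requested stream.

    ``default-token``: the default placeholder output (width d);
    ``class-token:<cls>``: a class placeholder output (width d);
    ``class-logits:<cls>``: the classifier logits (width d_A).
    """
    outs, _ = _forward_cells(model, counts)
    if source == "default-token":
        return np.concatenate(
            [o.placeholder_embeddings["default"] for o in outs], axis=0
        )
    if source.startswith("class-token:"):
        cls = source.split(":", 1)[1]
        if cls not in model.config.classes:
            raise ValueError(f"unknown class {cls!r}")
        return np.concatenate(
            [o.placeholder_embeddings[cls] for o in outs], axis=0
        )
    if source.startswith("class-logits:"):
        cls = source.split(":", 1)[1]
        if cls not in model.config.classes:
            raise ValueError(f"unknown class {cls!r}")
        emb = np.concatenate(
            [o.placeholder_embeddings[cls] for o in outs], axis=0
        )
        return logit_embedding(model.decode_classes({cls: emb}), cls)
    raise ValueError(f"invalid embedding source {source!r}")
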
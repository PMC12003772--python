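"""Gene-network benchmarking: EPR, prevalence-floored AUPRC, prerank
hub-enrichment, and ground-truth construction.

The early precision ratio (EPR) used here is the diagnostic odds ratio
(TP * TN) / (FP * FN) at the score cutoff producing exactly K positive
predictions, K being the number of true edges among the candidate pairs:
1 is a random prediction, +inf a perfect one, and values below 1 mean the
inverted predictor would do better.

The AUPRC variant floors the area at the prevalence of the positive class
rather than at precision 0 — the precision-minus-prevalence excess, clipped
below at zero, is integrated over achieved recall with the composite
trapezoidal rule and never extrapolated past the last achieved recall — so a
perfect ranking scores 1 - prevalence and a random one about 0.

Candidate pairs are all ordered non-self gene pairs over the common gene
universe of prediction and truth; both metrics are invariant to strictly
monotone transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import NetworkMatrix

__all__ = [
    "GroundTruthNetwork",
    "MetricReport",
    "EnrichmentResult",
    "epr",
    "auprc",
    "prerank_enrichment",
    "truth_from_pvalues",
    "load_truth_edgelist",
]


@dataclass
class GroundTruthNetwork:
    """Binary directed edge set over named genes."""

    edges: set[tuple[str, str]]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for s, t in self.edges:
            if s not in uni or t not in uni:
                raise ValueError(f"edge ({s}, {t}) endpoint outside the universe")
        self.edges = set(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class MetricReport:
    epr: float
    auprc: float
    n_positives: int
    universe_size: int
    orientation: str


@dataclass
class EnrichmentResult:
    term: str
    es: float
    nes: float
    p: float
    q: float
    mode: str
    n_hits: int


# ---------------------------------------------------------------------------
# candidate-pair extraction
# ---------------------------------------------------------------------------

def _candidate_scores(pred: NetworkMatrix, truth: GroundTruthNetwork):
    """Scores and binary labels for all ordered non-self pairs over the
    common universe; NaN (never co-sampled) pairs are excluded."""
    common = [g for g in pred.gene_ids if g in set(truth.universe)]
    if not common:
        raise ValueError("prediction and truth share no genes")
    ridx = {g: i for i, g in enumerate(pred.row_genes)}
    cidx = {g: i for i, g in enumerate(pred.col_genes)}
    n = len(common)
    src = np.repeat(np.arange(n), n)
    tgt = np.tile(np.arange(n), n)
    keep = src != tgt
    src, tgt = src[keep], tgt[keep]
    rows = np.array([ridx[common[t]] for t in tgt])
    cols = np.array([cidx[common[s]] for s in src])
    scores = pred.scores[rows, cols]
    edge_set = truth.edges
    labels = np.array(
        [(common[s], common[t]) in edge_set for s, t in zip(src, tgt)], dtype=bool
    )
    finite = np.isfinite(scores)
    return scores[finite], labels[finite], len(common)


# ---------------------------------------------------------------------------
# EPR
# ---------------------------------------------------------------------------

def epr(
    pred: NetworkMatrix,
    truth: GroundTruthNetwork,
    seed: int = 0,
    mode: str = "odds-ratio",
) -> float:
    """Early precision ratio at the top-K cutoff (K = number of true edges).

    Tied scores at the K-th rank are broken by a seeded deterministic shuffle
    so exactly K predictions are made.  ``mode="precision-ratio"`` gives the
    conventional precision@K / prevalence instead of the odds ratio.
    """
    scores, labels, _ = _candidate_scores(pred, truth)
    K = int(labels.sum())
    if K < 1:
        raise ValueError("the ground truth has no edges among the candidates")
    return epr_from_scores(scores, labels, K, seed=seed, mode=mode)


def epr_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    K: int | None = None,
    seed: int = 0,
    mode: str = "odds-ratio",
) -> float:
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    K = int(labels.sum()) if K is None else K
    shuffle = rng.permutation(len(scores))  # seeded tie-break
    order = shuffle[np.argsort(-np.asarray(scores)[shuffle], kind="stable")]
    top = order[:K]
    predicted = np.zeros(len(scores), dtype=bool)
    predicted[top] = True
    tp = int(np.sum(predicted & labels))
    fp = int(np.sum(predicted & ~labels))
    fn = int(np.sum(~predicted & labels))
    tn = int(np.sum(~predicted & ~labels))
    if mode == "precision-ratio":
        prevalence = labels.mean()
        return float((tp / K) / prevalence)
    if fp == 0 or fn == 0:
        return float("inf")
    return float((tp * tn) / (fp * fn))


# ---------------------------------------------------------------------------
# AUPRC
# ---------------------------------------------------------------------------

def auprc(
    pred: NetworkMatrix,
    truth: GroundTruthNetwork,
    floor: str = "prevalence",
) -> float:
    scores, labels, _ = _candidate_scores(pred, truth)
    return auprc_from_scores(scores, labels, floor=floor)


def auprc_from_scores(
    scores: np.ndarray, labels: np.ndarray, floor: str = "prevalence"
) -> float:
    """Trapezoidal area of (precision - prevalence), clipped at 0, over
    achieved recall; thresholds sweep from 0 predictions to all, with tied
    scores entering together.  ``floor="none"`` integrates raw precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    P = labels.sum()
    if P == 0:
        raise ValueError("no positives among the candidate pairs")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp_cum = np.cumsum(l_sorted)
    k = np.arange(1, len(scores) + 1)
    # only cutoffs at distinct-score boundaries are achievable
    boundary = np.ones(len(scores), dtype=bool)
    boundary[:-1] = s_sorted[:-1] != s_sorted[1:]
    precision = tp_cum[boundary] / k[boundary]
    recall = tp_cum[boundary] / P
    prevalence = P / len(scores)
    # open the curve at recall 0 with the first achievable precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    excess = precision - prevalence if floor == "prevalence" else precision
    excess = np.clip(excess, 0.0, None)
    return float(np.trapezoid(excess, recall))


def metric_report(
    pred: NetworkMatrix, truth: GroundTruthNetwork, seed: int = 0
) -> MetricReport:
    scores, labels, n_common = _candidate_scores(pred, truth)
    K = int(labels.sum())
    return MetricReport(
        epr=epr_from_scores(scores, labels, K, seed=seed),
        auprc=auprc_from_scores(scores, labels),
        n_positives=K,
        universe_size=n_common,
        orientation=pred.orientation,
    )


# ---------------------------------------------------------------------------
# prerank enrichment
# ---------------------------------------------------------------------------

def _node_ranking(network: NetworkMatrix, mode: str) -> pd.Series:
    scores = np.nan_to_num(network.scores, nan=0.0)
    if mode == "target-hub":
        vals = scores.sum(axis=1)
        genes = network.row_genes
    elif mode == "regulator-hub":
        vals = scores.sum(axis=0)
        genes = network.col_genes
    elif mode == "eigenvector":
        G = nx.from_numpy_array(scores, create_using=nx.DiGraph)
        cent = nx.eigenvector_centrality_numpy(G, weight="weight")
        genes = network.gene_ids
        vals = np.array([cent[i] for i in range(len(genes))])
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    return pd.Series(vals, index=list(genes)).sort_values(ascending=False)


def _es_stat(ranked_scores: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum statistic, weight exponent 1."""
    w = np.abs(ranked_scores) * hit_mask
    total_w = w.sum()
    n_miss = len(hit_mask) - hit_mask.sum()
    if total_w == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(w / total_w - (~hit_mask.astype(bool)) / n_miss)
    i = np.argmax(np.abs(running))
    return float(running[i])


def prerank_enrichment(
    network: NetworkMatrix,
    gene_sets: dict[str, list[str]],
    mode: str = "target-hub",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Rank genes by hub score and test each gene set with a weighted-KS
    prerank statistic against a gene-label permutation null.

    The background is all genes in the network; modes are row-sum
    (target hubs), column-sum (regulator hubs) and eigenvector centrality.
    Sets with an empty intersection are reported with NaN statistics rather
    than raising.  q-values are Benjamini-Hochberg adjusted permutation
    p-values.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    ranking = _node_ranking(network, mode)
    genes = np.array(ranking.index)
    rs = ranking.to_numpy()
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for term, members in gene_sets.items():
        hit = np.isin(genes, list(members))
        n_hits = int(hit.sum())
        if n_hits == 0 or n_hits == len(genes):
            results.append(
                EnrichmentResult(term, np.nan, np.nan, np.nan, np.nan, mode, n_hits)
            )
            pvals.append(np.nan)
            continue
        es = _es_stat(rs, hit)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _es_stat(rs, rng.permutation(hit))
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.inf * np.sign(es)
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (len(same_sign) + 1)
            denom = np.mean(np.abs(same_sign))
            nes = es / denom if denom > 0 else np.nan
        results.append(EnrichmentResult(term, es, float(nes), float(p), np.nan,
                                        mode, n_hits))
        pvals.append(float(p))

    # Benjamini-Hochberg over the permutation p-values
    valid = [i for i, p in enumerate(pvals) if np.isfinite(p)]
    if valid:
        ps = np.array([pvals[i] for i in valid])
        order = np.argsort(ps)
        m = len(ps)
        q = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * m / (rank_pos + 1))
            q[i] = prev
        for j, i in enumerate(valid):
            results[i].q = float(q[j])
    return results


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def truth_from_pvalues(
    pmatrix: pd.DataFrame, cutoff: float = 0.05
) -> GroundTruthNetwork:
    """Directed binary network from a perturbation p-value matrix.

    Rows are knocked-out source genes, columns readout genes; edge A -> B iff
    p[A, B] < cutoff.  Self-edges are removed.
    """
    vals = pmatrix.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    edges = set()
    for i, src in enumerate(pmatrix.index):
        for j, tgt in enumerate(pmatrix.columns):
            if src != tgt and vals[i, j] < cutoff:
                edges.add((str(src), str(tgt)))
    universe = tuple(dict.fromkeys([str(g) for g in pmatrix.index]
                                   + [str(g) for g in pmatrix.columns]))
    return GroundTruthNetwork(edges=edges, universe=universe)


def load_gene_sets_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def load_truth_edgelist(
    path: str | Path,
    universe: tuple[str, ...] | None = None,
) -> GroundTruthNetwork:
    """Read a (source, target) TSV into a deduplicated directed edge set.

    The universe defaults to the union of endpoint genes; malformed rows are
    counted and reported via a warning.  Filtering of entries without proper
    gene symbols is the caller's preprocessing.
    """
    import warnings

    edges = set()
    bad = 0
    genes: dict[str, None] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                bad += 1
                continue
            if line_no == 0 and parts[0].lower() in {"source", "regulator", "tf"}:
                continue
            s, t = parts[0], parts[1]
            edges.add((s, t))
            genes.setdefault(s)
            genes.setdefault(t)
    if bad:
        warnings.warn(f"{bad} malformed rows skipped in {path}", stacklevel=2)
    if not edges:
        warnings.warn(f"empty ground-truth network from {path}", stacklevel=2)
    uni = universe if universe is not None else tuple(genes)
    return GroundTruthNetwork(edges=edges, universe=uni)
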
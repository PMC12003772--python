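"""Synthetic single-cell count data with a planted gene regulatory network.

The generator emulates the statistical features a ZINB-based expression model
assumes: a directed gene network shaping gene-gene covariance, hierarchically
labeled cell groups of imbalanced sizes, log-normal library-size variation,
negative-binomial counting noise, per-gene technical dropout, and mild
multiplicative batch effects.  It is a one-step linear structural-equation
mechanism — group- and cell-level latent activities are propagated once
through the planted network, rectified with a softplus, and scaled to a
sampled library size — which is the minimal mechanism producing
network-structured zero-inflated counts.

Also provided here: the standard QC filter (cells with too few expressed
genes dropped, datasets rejected when too small or too depleted) and a random
rooted ontology generator for the hierarchical-classification fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.special import expit

from .vocab import OntologyDAG

__all__ = [
    "PlantedGRN",
    "SyntheticConfig",
    "CountMatrix",
    "QCRejection",
    "generate_dataset",
    "qc_filter",
    "make_ontology",
    "default_gene_table",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PlantedGRN:
    """A directed ground-truth gene network planted into the generator."""

    genes: list[str]
    edges: set[tuple[str, str]]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-loop {s}->{t} not allowed")
            if s not in gene_set or t not in gene_set:
                raise ValueError(f"edge ({s}, {t}) endpoint outside gene list")
        for e in self.edges:
            w = self.weights.setdefault(e, 1.0)
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge {e}")

    @classmethod
    def random(
        cls,
        genes: list[str],
        edge_prob: float = 0.05,
        weight_scale: float = 1.0,
        seed: int = 0,
    ) -> "PlantedGRN":
        rng = np.random.default_rng(seed)
        n = len(genes)
        mask = rng.random((n, n)) < edge_prob
        np.fill_diagonal(mask, False)
        edges = set()
        weights = {}
        for i, j in zip(*np.nonzero(mask)):
            e = (genes[i], genes[j])
            edges.add(e)
            weights[e] = float(weight_scale * rng.normal(loc=1.0, scale=0.25))
        return cls(genes=genes, edges=edges, weights=weights)

    def adjacency(self, gene_order: list[str] | None = None) -> np.ndarray:
        """Weighted adjacency W with W[source, target] = weight."""
        order = gene_order if gene_order is not None else self.genes
        idx = {g: i for i, g in enumerate(order)}
        W = np.zeros((len(order), len(order)))
        for (s, t), w in self.weights.items():
            if s in idx and t in idx:
                W[idx[s], idx[t]] = w
        return W


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    ``mean_depth`` is the expected transcripts per cell; ``dispersion`` is the
    NB inverse-dispersion theta (large theta approaches Poisson counting);
    ``dropout_logit`` sets the per-entry technical-dropout probability through
    a sigmoid; ``group_proportions`` default to an imbalanced geometric decay
    so that rare populations exist.
    """

    n_cells: int = 5000
    n_genes: int = 100
    n_groups: int = 8
    group_proportions: np.ndarray | None = None
    mean_depth: float = 2000.0
    dispersion: float = 3.0
    dropout_logit: float = -2.0
    batch_count: int = 2
    library_sigma: float = 0.3
    cell_noise: float = 0.3
    batch_sigma: float = 0.1
    coarse_label_frac: float = 0.1
    ontology_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_groups <= 0:
            raise ValueError("n_cells, n_genes, n_groups must be positive")
        if self.mean_depth < 0 or self.dispersion <= 0 or self.library_sigma < 0:
            raise ValueError("scale parameters must be positive")
        if self.batch_count < 0:
            raise ValueError("batch_count must be nonnegative")
        if self.group_proportions is None:
            p = 0.5 ** np.arange(self.n_groups)
            self.group_proportions = p / p.sum()
        else:
            self.group_proportions = np.asarray(self.group_proportions, dtype=float)
            if len(self.group_proportions) != self.n_groups:
                raise ValueError("group_proportions length must equal n_groups")
            if abs(self.group_proportions.sum() - 1.0) > 1e-8:
                raise ValueError("group_proportions must sum to 1")


@dataclass
class CountMatrix:
    """Raw integer counts (cells x genes) with per-cell labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("counts/gene_ids shape mismatch")
        for name, lab in self.cell_labels.items():
            if len(lab) != self.counts.shape[0]:
                raise ValueError(f"label array {name!r} length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-cell total transcript count t_i = sum_j x_ij."""
        return self.counts.sum(axis=1)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[index],
            gene_ids=list(self.gene_ids),
            cell_labels={k: np.asarray(v)[index] for k, v in self.cell_labels.items()},
        )


@dataclass
class QCRejection:
    """Typed rejection outcome of the QC filter (not an exception)."""

    reason: str
    n_cells_surviving: int
    removed_fraction: float


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: SyntheticConfig, grn: PlantedGRN, return_means: bool = False
) -> CountMatrix | tuple[CountMatrix, np.ndarray]:
    """Draw a ZINB-like count matrix shaped by the planted network.

    Per cell: a latent activity vector (group base + cell jitter) is pushed
    one step through the planted network, softplus-rectified into relative
    expression rates, scaled to a log-normal library size, NB-sampled with the
    configured inverse-dispersion, and finally zeroed entrywise with
    probability ``sigmoid(dropout_logit)``.  Deterministic given ``cfg.seed``.
    """
    if cfg.n_genes < len(grn.genes):
        raise ValueError(
            f"n_genes={cfg.n_genes} smaller than the planted network "
            f"({len(grn.genes)} genes)"
        )
    rng = np.random.default_rng(cfg.seed)
    gene_ids = list(grn.genes) + [
        f"G{j:05d}" for j in range(len(grn.genes), cfg.n_genes)
    ]
    W = np.zeros((cfg.n_genes, cfg.n_genes))
    W[: len(grn.genes), : len(grn.genes)] = grn.adjacency()

    group = rng.choice(cfg.n_groups, size=cfg.n_cells, p=cfg.group_proportions)
    counts_per_group = np.bincount(group, minlength=cfg.n_groups)
    if (counts_per_group == 0).any():
        empty = np.nonzero(counts_per_group == 0)[0]
        raise ValueError(f"empty groups {empty.tolist()}; increase n_cells")

    base = rng.normal(size=(cfg.n_groups, cfg.n_genes))  # group-level activities
    z = base[group] + cfg.cell_noise * rng.normal(size=(cfg.n_cells, cfg.n_genes))
    activity = z + z @ W  # one-step propagation through the planted network
    rate = np.logaddexp(0.0, activity)  # softplus keeps rates positive

    if cfg.batch_count > 0:
        batch = rng.integers(cfg.batch_count, size=cfg.n_cells)
        batch_factor = np.exp(
            cfg.batch_sigma * rng.normal(size=(cfg.batch_count, cfg.n_genes))
        )
        rate = rate * batch_factor[batch]
    else:
        batch = np.zeros(cfg.n_cells, dtype=int)

    prop = rate / rate.sum(axis=1, keepdims=True)
    # E[library] = mean_depth exactly, so analytic gene means are prop*mean_depth
    library = cfg.mean_depth * np.exp(
        cfg.library_sigma * rng.normal(size=cfg.n_cells)
        - 0.5 * cfg.library_sigma**2
    )
    mean = prop * library[:, None]

    if cfg.dispersion > 1e5:  # effectively Poisson counting
        counts = rng.poisson(mean)
    else:
        lam = rng.gamma(cfg.dispersion, mean / cfg.dispersion)
        counts = rng.poisson(lam)

    p_drop = expit(cfg.dropout_logit)
    if p_drop > 0:
        counts = counts * (rng.random(counts.shape) >= p_drop)

    onto = make_ontology(cfg.n_groups, cfg.ontology_depth, seed=cfg.seed)
    leaf_names = onto.leaves
    cell_type = np.array([leaf_names[g] for g in group], dtype=object)
    if cfg.coarse_label_frac > 0:
        parent_of = {c: p for c, p in onto.parent_edges}
        coarse = rng.random(cfg.n_cells) < cfg.coarse_label_frac
        for i in np.nonzero(coarse)[0]:
            cell_type[i] = parent_of[cell_type[i]]

    data = CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_labels={
            "cell_type": cell_type.astype(str),
            "batch": np.array([f"batch{b}" for b in batch]),
            "group": np.array([leaf_names[g] for g in group]),
        },
    )
    if return_means:
        # analytic per-entry expectation: NB mean thinned by dropout survival
        return data, mean * (1.0 - p_drop)
    return data


def make_ontology(n_leaves: int, depth: int, seed: int = 0) -> OntologyDAG:
    """Random rooted ontology with ``n_leaves`` leaves and the given depth.

    Built by recursive binary partition of the leaf set, so every internal
    node has at least one leaf descendant.  Deterministic given ``seed``.
    """
    if n_leaves < 2 or depth < 1:
        raise ValueError("need n_leaves >= 2 and depth >= 1")
    rng = np.random.default_rng(seed)
    leaves = [f"leaf{i}" for i in range(n_leaves)]
    nodes: list[str] = ["root"]
    edges: list[tuple[str, str]] = []
    counter = [0]

    def build(parent: str, members: list[str], remaining: int) -> None:
        if remaining <= 1 or len(members) == 1:
            for leaf in members:
                nodes.append(leaf)
                edges.append((leaf, parent))
            return
        cut = int(rng.integers(1, len(members)))
        order = rng.permutation(len(members))
        parts = [[members[i] for i in order[:cut]], [members[i] for i in order[cut:]]]
        for part in parts:
            if len(part) == 1:
                nodes.append(part[0])
                edges.append((part[0], parent))
            else:
                counter[0] += 1
                inner = f"node{counter[0]}"
                nodes.append(inner)
                edges.append((inner, parent))
                build(inner, part, remaining - 1)

    build("root", leaves, depth)
    return OntologyDAG(nodes=nodes, parent_edges=edges)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(
    data: CountMatrix,
    min_genes_per_cell: int = 200,
    min_cells: int = 100,
    min_genes_total: int = 10_000,
    max_removed_frac: float = 0.95,
) -> CountMatrix | QCRejection:
    """Drop shallow cells; reject datasets that end up too small or depleted.

    Cells expressing fewer than ``min_genes_per_cell`` genes are removed.  The
    dataset is rejected (a typed :class:`QCRejection`, not an exception) if
    fewer than ``min_cells`` cells survive, if the gene count is below
    ``min_genes_total``, or if more than ``max_removed_frac`` of the cells
    were removed.
    """
    if min(min_genes_per_cell, min_cells, min_genes_total) < 0:
        raise ValueError("thresholds must be nonnegative")
    expressed = (data.counts > 0).sum(axis=1)
    keep = expressed >= min_genes_per_cell
    n_keep = int(keep.sum())
    removed_frac = 1.0 - n_keep / data.n_cells
    if data.n_genes < min_genes_total:
        return QCRejection(
            reason=f"gene count {data.n_genes} < {min_genes_total}",
            n_cells_surviving=n_keep,
            removed_fraction=removed_frac,
        )
    if n_keep < min_cells:
        return QCRejection(
            reason=f"{n_keep} surviving cells < {min_cells}",
            n_cells_surviving=n_keep,
            removed_fraction=removed_frac,
        )
    if removed_frac > max_removed_frac:
        return QCRejection(
            reason=f"removed fraction {removed_frac:.3f} > {max_removed_frac}",
            n_cells_surviving=n_keep,
            removed_fraction=removed_frac,
        )
    return data.subset_cells(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def default_gene_table(gene_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """Plausible gene coordinates for synthetic gene IDs: a few chromosomes,
    sorted starts with a mix of sub-10kb and larger gaps."""
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    n_chrom = max(1, min(5, n // 10))
    chrom = np.sort(rng.integers(n_chrom, size=n))
    gaps = rng.choice([2_000, 5_000, 40_000, 200_000], size=n, p=[0.2, 0.2, 0.3, 0.3])
    start = np.zeros(n, dtype=int)
    pos = 0
    for i in range(n):
        if i > 0 and chrom[i] != chrom[i - 1]:
            pos = 0
        start[i] = pos
        pos += int(gaps[i])
    return pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": [f"chr{c + 1}" for c in chrom], "start": start}
    )


def write_dataset(data: CountMatrix, out_dir: str | Path) -> None:
    """Write counts as an MTX triplet (genes x cells) plus cell/gene TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(data.counts.T))
    pd.DataFrame(data.cell_labels).to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": data.gene_ids}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )


def read_dataset(in_dir: str | Path) -> CountMatrix:
    src = Path(in_dir)
    mat = spio.mmread(src / "matrix.mtx").tocsr().T.toarray()
    cells = pd.read_csv(src / "cells.tsv", sep="\t")
    genes = pd.read_csv(src / "genes.tsv", sep="\t")
    return CountMatrix(
        counts=np.asarray(mat),
        gene_ids=list(genes["gene_id"]),
        cell_labels={c: cells[c].to_numpy(dtype=str) for c in cells.columns},
    )


def to_anndata(data: CountMatrix):
    """Optional AnnData container view of the count matrix."""
    import anndata as ad

    return ad.AnnData(
        X=sparse.csr_matrix(data.counts),
        obs=pd.DataFrame(data.cell_labels),
        var=pd.DataFrame(index=data.gene_ids),
    )


def from_anndata(adata) -> CountMatrix:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    labels = {c: adata.obs[c].to_numpy(dtype=str) for c in adata.obs.columns}
    return CountMatrix(
        counts=np.asarray(X), gene_ids=list(adata.var_names), cell_labels=labels
    )
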
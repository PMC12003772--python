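"""Gene vocabulary: identity embeddings, genomic location binning, and label ontologies.

Each gene in the vocabulary carries three pieces of identity information used to
build transformer input tokens: a fixed-length embedding vector (typically a
protein-language-model embedding of the gene's main protein product, or a random
stand-in), its genomic coordinates, and a "location index" that bins genes lying
close together on the same chromosome into a shared positional-encoding slot.

Cell labels (cell type, disease, ...) follow a rooted ontology DAG; the
classifier is trained on leaf terms only, so the DAG exposes fast
leaf-descendant lookups.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

#: genes closer than this many bp on the same chromosome share a location index
LOCATION_BIN_BP = 10_000


# ---------------------------------------------------------------------------
# location binning and positional encoding
# ---------------------------------------------------------------------------

def assign_location_indices(gene_table: pd.DataFrame) -> dict[str, int]:
    """Assign a genome-location index to every gene.

    Within each chromosome, genes are sorted by start coordinate; consecutive
    genes share an index iff their gap is strictly less than
    :data:`LOCATION_BIN_BP`, otherwise the index increments by one.  The index
    also increments at every chromosome boundary (different chromosomes share
    no regulatory regions).  The first gene overall gets index 0.

    Parameters
    ----------
    gene_table:
        DataFrame with columns ``gene_id``, ``chromosome``, ``start``.

    Returns
    -------
    dict mapping gene_id -> nonnegative location index.
    """
    df = gene_table[["gene_id", "chromosome", "start"]].copy()
    if (df["start"] < 0).any():
        raise ValueError("start coordinates must be nonnegative")
    if df.duplicated(subset=["gene_id", "chromosome", "start"]).any():
        raise ValueError("duplicate (gene_id, chromosome, start) rows")
    # stable, order-independent sort: (chromosome, start, gene_id)
    df = df.sort_values(["chromosome", "start", "gene_id"], kind="stable")
    indices: dict[str, int] = {}
    idx = 0
    prev_chrom = None
    prev_start = None
    first = True
    for gid, chrom, start in df.itertuples(index=False):
        if first:
            first = False
        elif chrom != prev_chrom or (start - prev_start) >= LOCATION_BIN_BP:
            idx += 1
        indices[gid] = idx
        prev_chrom, prev_start = chrom, start
    return indices


def positional_encode(location_index: int | np.ndarray, d: int) -> np.ndarray:
    """Sinusoidal positional encoding of a location index.

    Component ``2k`` is ``sin(pos / 10000^(2k/d))`` and component ``2k+1`` is
    ``cos(pos / 10000^(2k/d))``.  ``d`` must be even.
    """
    if d % 2 != 0:
        raise ValueError("embedding dimension d must be even")
    pos = np.asarray(location_index, dtype=float)
    k = np.arange(d // 2)
    freq = 1.0 / (10000.0 ** (2.0 * k / d))
    angle = pos[..., None] * freq
    out = np.empty(pos.shape + (d,), dtype=float)
    out[..., 0::2] = np.sin(angle)
    out[..., 1::2] = np.cos(angle)
    return out


# ---------------------------------------------------------------------------
# gene identity embeddings
# ---------------------------------------------------------------------------

def load_or_randomize_embeddings(
    gene_ids: list[str],
    d: int,
    table: pd.DataFrame | None = None,
    path: str | Path | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-gene identity embedding vectors, loaded from a table or randomized.

    In table mode the table (or the TSV at ``path``, indexed by gene_id) must
    cover every requested gene and have exactly ``d`` value columns.  In random
    mode each gene gets a unit-scale Gaussian vector drawn deterministically
    from ``(gene_id, seed)``, so vectors are reproducible and independent of
    the order and composition of ``gene_ids``.
    """
    if path is not None:
        table = pd.read_csv(path, sep="\t", index_col=0)
    if table is not None:
        missing = [g for g in gene_ids if g not in table.index]
        if missing:
            raise KeyError(f"genes missing from embedding table: {missing}")
        if table.shape[1] != d:
            raise ValueError(
                f"embedding table has dimension {table.shape[1]}, expected {d}"
            )
        return table.loc[gene_ids].to_numpy(dtype=float)
    if seed is None:
        raise ValueError("either an embedding table or a seed is required")
    out = np.empty((len(gene_ids), d), dtype=float)
    for i, gid in enumerate(gene_ids):
        rng = np.random.default_rng([seed, zlib.crc32(gid.encode())])
        out[i] = rng.normal(scale=1.0 / np.sqrt(d), size=d)
    return out


@dataclass
class GeneVocabulary:
    """Ordered gene vocabulary with identity embeddings and genome locations."""

    gene_ids: list[str]
    id_embeddings: np.ndarray  # (n_genes, d)
    chromosome: list[str]
    start: np.ndarray
    location_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if self.id_embeddings.shape[0] != n:
            raise ValueError("one embedding vector per gene required")
        self.start = np.asarray(self.start)
        self.location_index = np.asarray(self.location_index, dtype=int)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def d(self) -> int:
        return self.id_embeddings.shape[1]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self._index[g] for g in gene_ids], dtype=int)

    @classmethod
    def from_gene_table(
        cls,
        gene_table: pd.DataFrame,
        d: int,
        embedding_table: pd.DataFrame | None = None,
        embedding_path: str | Path | None = None,
        seed: int | None = None,
    ) -> "GeneVocabulary":
        """Build a vocabulary from a (gene_id, chromosome, start) table."""
        loc = assign_location_indices(gene_table)
        gene_ids = list(gene_table["gene_id"])
        emb = load_or_randomize_embeddings(
            gene_ids, d, table=embedding_table, path=embedding_path, seed=seed
        )
        return cls(
            gene_ids=gene_ids,
            id_embeddings=emb,
            chromosome=list(gene_table["chromosome"]),
            start=gene_table["start"].to_numpy(),
            location_index=np.array([loc[g] for g in gene_ids]),
        )

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "chromosome": self.chromosome,
                "start": self.start,
            }
        )


# ---------------------------------------------------------------------------
# ontology DAG
# ---------------------------------------------------------------------------

@dataclass
class OntologyDAG:
    """Rooted label ontology as a parent-child DAG.

    ``leaves`` (the set T) are the nodes with no children, enumerated in a
    stable order; classifier logits are indexed by leaf position.
    """

    nodes: list[str]
    parent_edges: list[tuple[str, str]]  # (child, parent)
    _children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, parent in self.parent_edges:
            if child not in node_set or parent not in node_set:
                raise ValueError(f"edge ({child}, {parent}) references unknown node")
            children[parent].append(child)
        self._children = children
        self._check_acyclic()
        self.leaves = [n for n in self.nodes if not children[n]]
        self._leaf_set = frozenset(self.leaves)
        self._leaf_pos = {leaf: i for i, leaf in enumerate(self.leaves)}
        self._desc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(n: str, stack: list[str]) -> None:
            state[n] = 1
            for c in self._children[n]:
                if state.get(c) == 1:
                    raise ValueError(f"ontology contains a cycle through {c}")
                if c not in state:
                    visit(c, stack)
            state[n] = 2

        for n in self.nodes:
            if n not in state:
                visit(n, [])

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_leaf(self, node: str) -> bool:
        return node in self._leaf_set

    def leaf_position(self, leaf: str) -> int:
        return self._leaf_pos[leaf]

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def leaf_descendants(self, node: str) -> frozenset[str]:
        """Exact set of leaves reachable from ``node`` (cached)."""
        if node not in self._children:
            raise KeyError(f"unknown ontology node: {node}")
        cached = self._desc_cache.get(node)
        if cached is not None:
            return cached
        if not self._children[node]:
            result = frozenset([node])
        else:
            result = frozenset().union(
                *(self.leaf_descendants(c) for c in self._children[node])
            )
        self._desc_cache[node] = result
        return result

    def leaf_descendant_indices(self, node: str) -> np.ndarray:
        """Sorted leaf-logit positions of the leaves under ``node``."""
        return np.array(
            sorted(self._leaf_pos[x] for x in self.leaf_descendants(node)), dtype=int
        )

    @classmethod
    def flat(cls, labels: list[str]) -> "OntologyDAG":
        """Degenerate ontology for a class without hierarchy: root over a flat
        label list, so T equals the full label set."""
        root = "__root__"
        return cls(
            nodes=[root] + list(labels),
            parent_edges=[(lab, root) for lab in labels],
        )

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "OntologyDAG":
        """Read a two-column (child_id, parent_id) TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"])
        nodes: list[str] = []
        seen: set[str] = set()
        for col in ("parent", "child"):
            for n in df[col]:
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
        return cls(nodes=nodes, parent_edges=list(df.itertuples(index=False, name=None)))

    def to_edge_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.parent_edges).to_csv(
            path, sep="\t", header=False, index=False
        )


def leaf_descendants(onto: OntologyDAG, node: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyDAG.leaf_descendants`."""
    return onto.leaf_descendants(node)
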
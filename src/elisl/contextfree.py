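"""Context-free gene-pair features from sequence and PPI-network embeddings.

Two sources are produced, one from protein-sequence embeddings (default
1024-D) and one from node embeddings of the curated/experimental PPI graph
(default 64-D). The pair feature in both cases is the elementwise absolute
difference between the two genes' vectors, so it is symmetric under gene
swap and non-negative.

Any embedder satisfying the :class:`Embedder` protocol can supply sequence
vectors; precomputed embedding tables (e.g. from a protein language model)
can be imported as TSV and bypass the embedder entirely. The built-in
:class:`KmerHashEmbedder` is a deterministic k-mer hashing embedder: fast,
dependency-free, and sensitive to shared subsequences, which is what the
downstream framework actually relies on.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import FeatureBlock, GenePair

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYXBZU*")

ACCEPTED_EVIDENCE = frozenset({"curated", "experimental"})


class GeneEmbeddingTable:
    """gene -> fixed-dimension real vector, stored as a genes x d DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 1:
            raise ValueError("embedding table needs at least one dimension")
        if not np.isfinite(frame.to_numpy()).all():
            raise ValueError("embedding table contains non-finite values")
        self.frame = frame.astype(float)

    @property
    def dim(self) -> int:
        return self.frame.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def vector(self, gene: str) -> np.ndarray:
        return self.frame.loc[gene].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneEmbeddingTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


class Embedder(Protocol):
    """Maps an amino-acid sequence to a fixed-dimension vector,
    deterministically for a fixed input."""

    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class KmerHashEmbedder:
    """Deterministic signed k-mer hashing into ``dim`` buckets.

    Each overlapping k-mer is hashed (salted by ``seed``) to a bucket and a
    sign; bucket sums are L2-normalized. Sequences sharing subsequences get
    nearby vectors, so absolute-difference pair features carry signal for
    genes with a common motif.
    """

    def __init__(self, dim: int = 1024, k: int = 3, seed: int = 0):
        self.dim = dim
        self.k = k
        self.seed = seed
        self._salt = str(seed).encode()

    def embed(self, sequence: str) -> np.ndarray:
        seq = sequence.strip().upper()
        if not seq:
            raise ValueError("empty sequence")
        if not set(seq) <= AMINO_ACIDS:
            raise ValueError(f"non amino-acid characters in sequence: {set(seq) - AMINO_ACIDS}")
        vec = np.zeros(self.dim)
        k = min(self.k, len(seq))
        for i in range(len(seq) - k + 1):
            h = hashlib.blake2b(seq[i : i + k].encode(), salt=self._salt, digest_size=8)
            val = int.from_bytes(h.digest(), "big")
            vec[val % self.dim] += 1.0 if (val >> 32) & 1 else -1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def embed_sequences(sequences: dict[str, str], embedder: Embedder) -> GeneEmbeddingTable:
    """One embedding vector per gene; genes the embedder rejects are omitted
    (logged), not fatal."""
    vectors: dict[str, np.ndarray] = {}
    for gene, seq in sequences.items():
        try:
            vectors[gene] = np.asarray(embedder.embed(seq), dtype=float)
        except Exception as exc:
            logger.warning("embedder failed for gene %s: %s", gene, exc)
    frame = pd.DataFrame.from_dict(vectors, orient="index")
    if frame.empty:
        frame = pd.DataFrame(np.empty((0, embedder.dim)))
    frame.columns = [f"d{i}" for i in range(frame.shape[1])]
    return GeneEmbeddingTable(frame)


def build_ppi_graph(
    edges: pd.DataFrame, accepted: frozenset[str] = ACCEPTED_EVIDENCE
) -> nx.Graph:
    """Simple undirected graph keeping only edges whose ``evidence_class``
    is accepted (curated or experimentally validated by default).
    Self-loops are dropped and duplicate / reversed edges collapsed."""
    graph = nx.Graph()
    for row in edges.itertuples():
        if row.evidence_class not in accepted:
            continue
        a, b = str(row.gene1), str(row.gene2)
        if a == b:
            continue
        graph.add_edge(a, b)
    return graph


@dataclass(frozen=True)
class WalkParams:
    """node2vec-style walk/embedding parameters (canonical defaults)."""

    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    dim: int = 64


def _generate_walks(graph: nx.Graph, params: WalkParams, rng: np.random.Generator) -> list[list[int]]:
    nodes = sorted(graph.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    adj = [np.array(sorted(index[n] for n in graph.neighbors(g)), dtype=int) for g in nodes]
    neighbor_sets = [set(a.tolist()) for a in adj]
    walks = []
    for _ in range(params.num_walks):
        order = rng.permutation(len(nodes))
        for start in order:
            if len(adj[start]) == 0:
                continue
            walk = [int(start)]
            while len(walk) < params.walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if len(nbrs) == 0:
                    break
                if len(walk) == 1 or (params.p == 1.0 and params.q == 1.0):
                    nxt = int(nbrs[rng.integers(len(nbrs))])
                else:
                    prev = walk[-2]
                    # second-order bias: 1/p to return, 1 to stay in the
                    # triangle, 1/q to move outward
                    weights = np.where(
                        nbrs == prev,
                        1.0 / params.p,
                        np.array([1.0 if n in neighbor_sets[prev] else 1.0 / params.q for n in nbrs]),
                    )
                    weights = weights / weights.sum()
                    nxt = int(nbrs[rng.choice(len(nbrs), p=weights)])
                walk.append(nxt)
            walks.append(walk)
    return walks


def embed_ppi_nodes(
    graph: nx.Graph, params: WalkParams = WalkParams(), seed: int = 0
) -> GeneEmbeddingTable:
    """Walk-based node embeddings of the PPI graph.

    Biased random walks are generated per node2vec, then the window
    co-occurrence matrix is factorized: embeddings are the top singular
    directions of the positive PMI matrix (the closed-form counterpart of
    skip-gram training on the same walks). Fixed seed gives bit-identical
    output. Graphs with fewer nodes than ``dim`` are zero-padded so the
    dimension contract holds; isolated nodes receive zero vectors.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot embed an empty graph")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    rng = np.random.default_rng(seed)
    walks = _generate_walks(graph, params, rng)

    cooc = np.zeros((n, n))
    for walk in walks:
        arr = np.array(walk)
        for offset in range(1, params.window + 1):
            if offset >= len(arr):
                break
            left, right = arr[:-offset], arr[offset:]
            np.add.at(cooc, (left, right), 1.0)
            np.add.at(cooc, (right, left), 1.0)
    total = cooc.sum()
    if total == 0:
        emb = np.zeros((n, params.dim))
    else:
        row = cooc.sum(axis=1, keepdims=True)
        col = cooc.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log(cooc * total / (row @ col))
        pmi[~np.isfinite(pmi)] = 0.0
        pmi = np.maximum(pmi, 0.0)
        u, s, _ = np.linalg.svd(pmi, hermitian=True)
        d = min(params.dim, n)
        emb = np.zeros((n, params.dim))
        emb[:, :d] = u[:, :d] * np.sqrt(s[:d])
        # fix SVD sign ambiguity for bit-reproducibility
        signs = np.sign(emb[np.abs(emb).argmax(axis=0), np.arange(params.dim)])
        signs[signs == 0] = 1.0
        emb *= signs
    frame = pd.DataFrame(emb, index=nodes, columns=[f"d{i}" for i in range(params.dim)])
    return GeneEmbeddingTable(frame)


def pair_absdiff_features(pair: GenePair, table: GeneEmbeddingTable) -> np.ndarray:
    """|v(gene_a) - v(gene_b)| elementwise; all-NaN if either gene lacks a
    vector (imputed downstream, pairs are never dropped here)."""
    if pair.gene_a not in table or pair.gene_b not in table:
        logger.debug("pair %s has a gene without an embedding", pair)
        return np.full(table.dim, np.nan)
    return np.abs(table.vector(pair.gene_a) - table.vector(pair.gene_b))


def absdiff_feature_block(
    pairs: Sequence[GenePair], table: GeneEmbeddingTable, source: str
) -> FeatureBlock:
    values = np.vstack([pair_absdiff_features(p, table) for p in pairs]) if pairs else np.empty((0, table.dim))
    columns = [f"{source}_absdiff_{i}" for i in range(table.dim)]
    return FeatureBlock(list(pairs), values, columns, source)
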
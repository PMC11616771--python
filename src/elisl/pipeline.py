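"""End-to-end orchestration: from raw inputs to the five feature blocks.

Source order is fixed throughout the package:
``seq, ppi, crispr_mut, crispr_expr, tissue`` (k = 5), followed by the
concatenated early-integration block built at fit time.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .cellline import Thresholds, cellline_feature_blocks
from .contextfree import (
    Embedder,
    GeneEmbeddingTable,
    KmerHashEmbedder,
    WalkParams,
    absdiff_feature_block,
    build_ppi_graph,
    embed_ppi_nodes,
    embed_sequences,
)
from .data_io import FeatureBlock, GenePair, OmicsBundle

logger = logging.getLogger(__name__)

SOURCE_ORDER = ["seq", "ppi", "crispr_mut", "crispr_expr", "tissue"]


def contextfree_feature_blocks(
    pairs: Sequence[GenePair],
    sequences: dict[str, str] | None = None,
    ppi_edges: pd.DataFrame | None = None,
    embedder: Embedder | None = None,
    seq_table: GeneEmbeddingTable | None = None,
    walk_params: WalkParams | None = None,
    seed: int = 0,
) -> tuple[FeatureBlock, FeatureBlock]:
    """Sequence- and PPI-embedding absolute-difference blocks.

    A precomputed ``seq_table`` (e.g. imported protein-language-model
    embeddings) bypasses the embedder."""
    if seq_table is None:
        if sequences is None:
            raise ValueError("need sequences or a precomputed embedding table")
        seq_table = embed_sequences(sequences, embedder or KmerHashEmbedder(seed=seed))
    seq_block = absdiff_feature_block(pairs, seq_table, "seq")

    if ppi_edges is None:
        raise ValueError("need a PPI edge list")
    graph = build_ppi_graph(ppi_edges)
    ppi_table = embed_ppi_nodes(graph, walk_params or WalkParams(), seed=seed)
    ppi_block = absdiff_feature_block(pairs, ppi_table, "ppi")
    ppi_block = FeatureBlock(ppi_block.pairs, ppi_block.values, ppi_block.columns, "ppi")
    return seq_block, ppi_block


def featurize(
    pairs: Sequence[GenePair],
    sequences: dict[str, str],
    ppi_edges: pd.DataFrame,
    cell_lines: OmicsBundle,
    tissue_bundle: OmicsBundle,
    thresholds: Thresholds | None = None,
    embedder: Embedder | None = None,
    walk_params: WalkParams | None = None,
    seed: int = 0,
) -> list[FeatureBlock]:
    """All five per-source blocks for ``pairs``, in canonical source order."""
    from .tissue import tissue_feature_block

    seq_block, ppi_block = contextfree_feature_blocks(
        pairs,
        sequences=sequences,
        ppi_edges=ppi_edges,
        embedder=embedder,
        walk_params=walk_params,
        seed=seed,
    )
    crispr_mut, crispr_expr = cellline_feature_blocks(pairs, cell_lines, thresholds)
    tissue_blk = tissue_feature_block(pairs, tissue_bundle, thresholds)
    return [seq_block, ppi_block, crispr_mut, crispr_expr, tissue_blk]


def featurize_world(world, pairs: Sequence[GenePair] | None = None, seed: int | None = None) -> list[FeatureBlock]:
    """Feature blocks for a synthetic world's labelled pairs (or any pair
    list over its gene universe)."""
    if pairs is None:
        pairs = world.labels.pairs
    return featurize(
        pairs,
        world.sequences,
        world.ppi_edges,
        world.cell_lines,
        world.tissue,
        seed=world.config.seed if seed is None else seed,
    )
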
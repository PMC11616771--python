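"""Alteration calling and CRISPR-dependency gene-pair features (cell lines).

An *alteration* is any of: a non-silent mutation, an extreme expression
z-score (|z| > 1.96, strict), or a deep copy-number event (discrete score
exactly -2 or 2). The two cell-line feature sets, "CRISPR with mutation"
and "CRISPR with expression", each hold four features per pair: the average
dependency of one gene across cell lines where the partner is unaltered /
altered, for both orderings of the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import FeatureBlock, GenePair, OmicsBundle

logger = logging.getLogger(__name__)

#: variant classes counted as non-silent (configurable per call)
NONSILENT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "nonstop", "inframe_indel"}
)

CRISPR_FEATURE_NAMES = [
    "dep_a_partner_unaltered",
    "dep_a_partner_altered",
    "dep_b_partner_unaltered",
    "dep_b_partner_altered",
]


@dataclass
class Thresholds:
    """Alteration-calling thresholds. Comparisons are strict: a z-score of
    exactly 1.96 is *not* an alteration; only CNA scores of exactly +/-2
    count as deep events."""

    expr_z: float = 1.96
    cna_deep: frozenset = frozenset({-2, 2})
    nonsilent: frozenset = NONSILENT_CLASSES


@dataclass
class AlterationMatrix:
    """sample x gene binary matrix with the channel it was called from."""

    frame: pd.DataFrame
    channel: str

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("alteration matrix entries must be 0/1")


def call_alterations(
    bundle: OmicsBundle, channel: str, thresholds: Thresholds | None = None
) -> AlterationMatrix:
    """Binary alteration calls for one channel.

    ``mutation``: any non-silent variant call for (sample, gene).
    ``expression``: |z| > threshold (strict).
    ``cna``: discrete score in the deep set {-2, 2}.
    ``any``: elementwise OR over whichever of the three layers the bundle
    provides.
    """
    thr = thresholds or Thresholds()
    shape = pd.DataFrame(0, index=bundle.samples, columns=bundle.genes, dtype=int)

    if channel == "mutation":
        if bundle.mutations is None:
            raise ValueError("bundle has no mutation calls")
        calls = bundle.mutations[bundle.mutations["variant_class"].isin(thr.nonsilent)]
        mat = shape.copy()
        if len(calls):
            hit = calls[calls["sample"].isin(bundle.samples) & calls["gene"].isin(bundle.genes)]
            idx = pd.crosstab(hit["sample"], hit["gene"]).clip(upper=1)
            mat.loc[idx.index, idx.columns] = idx.astype(int)
        return AlterationMatrix(mat, "mutation")
    if channel == "expression":
        if bundle.expr_z is None:
            raise ValueError("bundle has no expression z-scores")
        return AlterationMatrix(
            (bundle.expr_z.abs() > thr.expr_z).astype(int), "expression"
        )
    if channel == "cna":
        if bundle.cna is None:
            raise ValueError("bundle has no copy-number scores")
        return AlterationMatrix(
            bundle.cna.isin(list(thr.cna_deep)).astype(int), "cna"
        )
    if channel == "any":
        available = []
        if bundle.mutations is not None:
            available.append(call_alterations(bundle, "mutation", thr).frame)
        if bundle.expr_z is not None:
            available.append(call_alterations(bundle, "expression", thr).frame)
        if bundle.cna is not None:
            available.append(call_alterations(bundle, "cna", thr).frame)
        if not available:
            raise ValueError("bundle has no alteration-callable layer")
        combined = available[0]
        for extra in available[1:]:
            combined = combined | extra
        return AlterationMatrix(combined.astype(int), "any")
    raise ValueError(f"unknown alteration channel {channel!r}")


def masked_pair_means(
    pair: GenePair, values: pd.DataFrame, alt: AlterationMatrix
) -> np.ndarray:
    """The four conditional means underlying both CRISPR and average-
    expression features, in the fixed order: value(gene_a) over samples
    where gene_b is unaltered / altered, then value(gene_b) over samples
    where gene_a is unaltered / altered. An empty selection yields NaN
    (zero is a meaningful score, so it must not stand in for 'no data')."""
    a, b = pair.gene_a, pair.gene_b
    if a not in values.columns or b not in values.columns or a not in alt.frame.columns or b not in alt.frame.columns:
        logger.debug("pair %s has unmeasured gene(s)", pair)
        return np.full(4, np.nan)
    va = values[a].to_numpy(dtype=float)
    vb = values[b].to_numpy(dtype=float)
    alt_a = alt.frame[a].to_numpy(dtype=bool)
    alt_b = alt.frame[b].to_numpy(dtype=bool)

    def _mean(vals: np.ndarray, mask: np.ndarray) -> float:
        sel = vals[mask]
        sel = sel[~np.isnan(sel)]
        return float(sel.mean()) if sel.size else np.nan

    return np.array(
        [_mean(va, ~alt_b), _mean(va, alt_b), _mean(vb, ~alt_a), _mean(vb, alt_a)]
    )


def crispr_pair_features(
    pair: GenePair, dependency: pd.DataFrame, alt: AlterationMatrix
) -> np.ndarray:
    """Average dependency of each gene conditioned on the partner's
    alteration status (4 features)."""
    return masked_pair_means(pair, dependency, alt)


def cellline_feature_blocks(
    pairs: Sequence[GenePair],
    bundle: OmicsBundle,
    thresholds: Thresholds | None = None,
) -> tuple[FeatureBlock, FeatureBlock]:
    """The "CRISPR with mutation" and "CRISPR with expression" blocks
    (each N x 4). The bundle should already be context-filtered to the
    target cancer type."""
    if bundle.dependency is None:
        raise ValueError("bundle has no dependency scores")
    blocks = []
    for channel, source in (("mutation", "crispr_mut"), ("expression", "crispr_expr")):
        alt = call_alterations(bundle, channel, thresholds)
        values = (
            np.vstack([crispr_pair_features(p, bundle.dependency, alt) for p in pairs])
            if pairs
            else np.empty((0, 4))
        )
        cols = [f"{source}_{name}" for name in CRISPR_FEATURE_NAMES]
        blocks.append(FeatureBlock(list(pairs), values, cols, source))
    return blocks[0], blocks[1]
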
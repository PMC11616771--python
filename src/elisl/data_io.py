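"""Core domain types and I/O for gene-pair synthetic-lethality data.

Gene pairs are unordered: every pair is stored in canonical form with the
lexicographically smaller symbol first, so order-dependent features
("first gene" vs "second gene") are well defined and invariant to how the
caller happened to write the pair.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, fields, replace
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "SLLabelTable",
    "OmicsBundle",
    "FeatureBlock",
    "harmonize_labels",
    "filter_context",
    "enumerate_candidate_pairs",
    "read_feature_block",
    "write_feature_block",
    "read_matrix",
    "write_matrix",
    "read_sequences",
    "write_sequences",
]


@dataclass(frozen=True, order=True)
class GenePair:
    """Canonical unordered pair of gene symbols (``gene_a < gene_b``)."""

    gene_a: str
    gene_b: str

    def __init__(self, gene_a: str, gene_b: str) -> None:
        if not isinstance(gene_a, str) or not isinstance(gene_b, str):
            raise TypeError("gene symbols must be strings")
        a, b = gene_a.strip(), gene_b.strip()
        if not a or not b:
            raise ValueError("gene symbols must be non-empty")
        if a == b:
            raise ValueError(f"a gene pair needs two distinct genes, got {a!r} twice")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.gene_a}|{self.gene_b}"


LABEL_COLUMNS = ["gene_a", "gene_b", "label", "source", "cancer"]


class SLLabelTable:
    """Labelled gene pairs with study-source and cancer-type provenance.

    Wraps a DataFrame with columns ``gene_a, gene_b, label, source, cancer``
    where ``label`` is 1 for synthetic lethal and 0 for non-SL.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"label table is missing columns {missing}")
        df = frame.loc[:, LABEL_COLUMNS].copy()
        df["label"] = df["label"].astype(int)
        if not df["label"].isin([0, 1]).all():
            raise ValueError("labels must be binary (1=SL, 0=non-SL)")
        # canonicalize pair order
        swap = df["gene_a"] > df["gene_b"]
        df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].values
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("self-pairs are not allowed")
        dup = df.duplicated(subset=["gene_a", "gene_b", "source", "cancer"])
        if dup.any():
            df = df[~dup]
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[GenePair, int]] | Iterable[tuple[GenePair, int, str, str]],
        source: str = "unspecified",
        cancer: str = "PANCAN",
    ) -> "SLLabelTable":
        rows = []
        for rec in records:
            if len(rec) == 2:
                pair, label = rec
                src, can = source, cancer
            else:
                pair, label, src, can = rec
            rows.append((pair.gene_a, pair.gene_b, int(label), src, can))
        return cls(pd.DataFrame(rows, columns=LABEL_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pairs(self) -> list[GenePair]:
        return [GenePair(a, b) for a, b in zip(self.frame["gene_a"], self.frame["gene_b"])]

    def labels_for(self, pairs: Sequence[GenePair]) -> np.ndarray:
        """Label vector aligned to ``pairs``; raises if any pair is unlabelled."""
        lut = {(r.gene_a, r.gene_b): r.label for r in self.frame.itertuples()}
        try:
            return np.array([lut[p.genes] for p in pairs], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"pair {exc.args[0]} has no label") from exc

    def subset_pairs(self, pairs: Sequence[GenePair]) -> "SLLabelTable":
        keys = {p.genes for p in pairs}
        keep = [
            (r.gene_a, r.gene_b) in keys for r in self.frame.itertuples()
        ]
        return SLLabelTable(self.frame[keep])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SLLabelTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str}))


@dataclass
class OmicsBundle:
    """Container for one omics cohort (cell lines or patient tissue).

    All matrices are samples x genes DataFrames sharing the declared sample
    and gene universes; layers a cohort does not provide are ``None``.

    dependency
        CRISPR gene-dependency scores (more negative = more essential).
    expr_z
        Expression z-scores relative to the cohort distribution; used only
        for alteration calling.
    expr_level
        Non-negative expression levels (e.g. RSEM/TPM); used for averaging
        and co-expression.
    mutations
        Long-format calls with columns ``sample, gene, variant_class``.
    cna
        Discrete copy-number scores in {-2, -1, 0, 1, 2}.
    clinical
        Per-sample table ``sample, time_months, event, age, sex, cancer``.
    sample_context
        Series mapping sample id -> cancer-type code.
    expr_level_normal / expr_level_healthy
        Matched normal-tissue and healthy-donor expression compartments
        (their sample universes are separate from the tumour cohort).
    """

    samples: list[str]
    genes: list[str]
    dependency: pd.DataFrame | None = None
    expr_z: pd.DataFrame | None = None
    expr_level: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    cna: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    sample_context: pd.Series | None = None
    expr_level_normal: pd.DataFrame | None = None
    expr_level_healthy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("dependency", "expr_z", "expr_level", "cna"):
            mat = getattr(self, name)
            if mat is not None:
                if list(mat.columns) != list(self.genes) or list(mat.index) != list(self.samples):
                    raise ValueError(
                        f"{name} matrix is not indexed by the declared sample/gene universes"
                    )
        if self.cna is not None:
            vals = self.cna.to_numpy()
            if not np.isin(vals, [-2, -1, 0, 1, 2]).all():
                raise ValueError("cna scores must lie in {-2,-1,0,1,2}")
        if self.clinical is not None and (self.clinical["time_months"] < 0).any():
            raise ValueError("clinical survival times must be non-negative")


def harmonize_labels(sources: Sequence[SLLabelTable]) -> SLLabelTable:
    """Merge label tables from several studies into one consistent table.

    A (pair, cancer) combination labelled SL by one study and non-SL by
    another is removed entirely; consistent labels are kept once, with the
    contributing study identifiers joined into the ``source`` field. The
    result is independent of the order the studies are given in.
    """
    if not sources:
        raise ValueError("harmonize_labels needs at least one label table")
    frames = [s.frame for s in sources]
    df = pd.concat(frames, ignore_index=True)

    bad = ~(
        df["gene_a"].astype(str).str.strip().astype(bool)
        & df["gene_b"].astype(str).str.strip().astype(bool)
    )
    if bad.any():
        logger.warning("rejecting %d records with malformed gene symbols", int(bad.sum()))
        df = df[~bad]

    grouped = df.groupby(["gene_a", "gene_b", "cancer"], sort=True)
    rows = []
    n_conflict = 0
    for (a, b, cancer), grp in grouped:
        labels = grp["label"].unique()
        if len(labels) > 1:
            n_conflict += 1
            continue
        srcs = ";".join(sorted(grp["source"].astype(str).unique()))
        rows.append((a, b, int(labels[0]), srcs, cancer))
    if n_conflict:
        logger.info("removed %d gene pairs with conflicting labels across studies", n_conflict)
    return SLLabelTable(pd.DataFrame(rows, columns=LABEL_COLUMNS))


def filter_context(bundle: OmicsBundle, cancer: str) -> OmicsBundle:
    """Restrict a cohort to samples of one cancer type; genes are untouched.

    An unknown cancer code yields an empty (but valid) bundle. The normal
    and healthy-donor expression compartments have their own sample
    universes and pass through unchanged.
    """
    if bundle.sample_context is None:
        raise ValueError("bundle has no sample_context to filter on")
    keep = [s for s in bundle.samples if bundle.sample_context.get(s) == cancer]
    if not keep:
        logger.warning("no samples match cancer type %r", cancer)

    def _rows(mat: pd.DataFrame | None) -> pd.DataFrame | None:
        return None if mat is None else mat.loc[keep]

    mutations = None
    if bundle.mutations is not None:
        mutations = bundle.mutations[bundle.mutations["sample"].isin(keep)].reset_index(drop=True)
    clinical = None
    if bundle.clinical is not None:
        clinical = bundle.clinical[bundle.clinical["sample"].isin(keep)].reset_index(drop=True)
    return replace(
        bundle,
        samples=keep,
        dependency=_rows(bundle.dependency),
        expr_z=_rows(bundle.expr_z),
        expr_level=_rows(bundle.expr_level),
        cna=_rows(bundle.cna),
        mutations=mutations,
        clinical=clinical,
        sample_context=None if bundle.sample_context is None else bundle.sample_context.loc[keep],
    )


def enumerate_candidate_pairs(
    genes: Iterable[str], exclude: Iterable[GenePair] = ()
) -> list[GenePair]:
    """All unordered pairs of distinct genes in canonical order, minus
    exclusions. The count equals C(n, 2) - |exclusions among the pairs|."""
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise ValueError("need at least 2 genes to enumerate pairs")
    excluded = {p.genes for p in exclude}
    return [
        GenePair(a, b)
        for a, b in itertools.combinations(uniq, 2)
        if (a, b) not in excluded
    ]


def candidate_pair_count(n_genes: int, n_excluded: int = 0) -> int:
    """Closed-form pair count C(n, 2) - excluded."""
    return comb(n_genes, 2) - n_excluded


# ---------------------------------------------------------------------------
# Feature blocks


@dataclass
class FeatureBlock:
    """N x f matrix of gene-pair features for one data source.

    Rows follow ``pairs`` order; missing values are NaN and imputed at model
    fit time, never here.
    """

    pairs: list[GenePair]
    values: np.ndarray
    columns: list[str]
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        if self.values.shape != (len(self.pairs), len(self.columns)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.columns)} columns"
            )
        if len(set(p.genes for p in self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in feature block")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "gene_a", [p.gene_a for p in self.pairs])
        df.insert(1, "gene_b", [p.gene_b for p in self.pairs])
        return df

    def subset(self, pairs: Sequence[GenePair]) -> "FeatureBlock":
        index = {p.genes: i for i, p in enumerate(self.pairs)}
        rows = [index[p.genes] for p in pairs]
        return FeatureBlock(list(pairs), self.values[rows], list(self.columns), self.source)


def write_feature_block(block: FeatureBlock, path: str | Path) -> None:
    block.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_block(path: str | Path, source: str | None = None) -> FeatureBlock:
    """Read a TSV feature block; write->read round-trips to full precision.

    Ragged rows and duplicated pair ids raise with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_a", "gene_b"]:
            raise ValueError(f"{path}: first two columns must be gene_a, gene_b")
        ncol = len(header)
        pairs: list[GenePair] = []
        seen: set[tuple[str, str]] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}"
                )
            key = (parts[0], parts[1])
            if key in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate pair {key}")
            seen.add(key)
            pairs.append(GenePair(parts[0], parts[1]))
            rows.append([float(x) if x not in ("", "nan") else np.nan for x in parts[2:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, ncol - 2))
    return FeatureBlock(pairs, values, header[2:], source or path.stem)


# ---------------------------------------------------------------------------
# Matrix / sequence plumbing


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    """Samples-in-rows TSV with the sample id as first column."""
    mat.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_sequences(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
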
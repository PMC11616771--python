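"""Evaluation protocols: splits, class balancing, metrics, model comparison.

Three split families are provided. Standard runs draw a single global
pair-disjoint 80/20 train/test split, then per run undersample the
majority class independently within train and within test. Double gene
holdout additionally forbids any *gene* from appearing on both sides,
probing robustness to gene selection bias. Cross-label-source runs train
on one label study and test on another, with pairs known to both removed
from the test side.

AUPRC is average precision (step interpolation); AUROC is the normalized
Mann-Whitney statistic. Paired model comparison uses the two-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import GenePair, SLLabelTable

logger = logging.getLogger(__name__)


@dataclass
class EvaluationRun:
    """One balanced train/test split with per-model metric results."""

    index: int
    seed: int
    train: SLLabelTable
    test: SLLabelTable
    protocol: str = "standard"
    metrics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        overlap = {p.genes for p in self.train.pairs} & {p.genes for p in self.test.pairs}
        if overlap:
            raise ValueError(f"train/test pair overlap: {sorted(overlap)[:3]}...")


def _undersample(frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Random undersampling of the majority class to balance labels."""
    counts = frame["label"].value_counts()
    if len(counts) < 2 or counts.iloc[0] == counts.iloc[-1]:
        return frame.reset_index(drop=True)
    n = int(counts.min())
    parts = []
    for label, grp in frame.groupby("label"):
        if len(grp) > n:
            take = rng.choice(len(grp), size=n, replace=False)
            grp = grp.iloc[np.sort(take)]
        parts.append(grp)
    return pd.concat(parts).reset_index(drop=True)


def _check_two_classes(frame: pd.DataFrame, where: str) -> None:
    if frame["label"].nunique() < 2:
        raise ValueError(f"{where} does not contain both classes")


def make_standard_runs(
    labels: SLLabelTable,
    n_runs: int = 10,
    seed: int = 0,
    test_frac: float = 0.2,
    balance: str = "both",
) -> list[EvaluationRun]:
    """One global pair-disjoint 80/20 split; per run, independent seeded
    undersampling of the majority class within train and (by default) test."""
    df = labels.frame
    _check_two_classes(df, "label table")
    rng = np.random.default_rng(seed)
    # stratified global split so both sides keep both classes
    test_parts, train_parts = [], []
    for _, grp in df.groupby("label"):
        perm = rng.permutation(len(grp))
        n_test = max(1, int(round(test_frac * len(grp))))
        test_parts.append(grp.iloc[perm[:n_test]])
        train_parts.append(grp.iloc[perm[n_test:]])
    train_df = pd.concat(train_parts)
    test_df = pd.concat(test_parts)
    _check_two_classes(train_df, "train split")
    _check_two_classes(test_df, "test split")

    runs = []
    for r in range(n_runs):
        run_rng = np.random.default_rng(seed * 100_003 + r + 1)
        tr = _undersample(train_df, run_rng)
        te = _undersample(test_df, run_rng) if balance == "both" else test_df.reset_index(drop=True)
        runs.append(
            EvaluationRun(r, seed * 100_003 + r + 1, SLLabelTable(tr), SLLabelTable(te), "standard")
        )
    return runs


def gene_test_fraction_for(target_test_frac: float) -> float:
    """Gene-side test fraction q so that among retained pairs the test share
    q^2/(p^2+q^2) hits the target (q/p = sqrt(t/(1-t)))."""
    s = sqrt(target_test_frac / (1.0 - target_test_frac))
    return s / (1.0 + s)


def make_double_holdout_runs(
    labels: SLLabelTable,
    n_runs: int = 10,
    seed: int = 0,
    target_test_frac: float = 0.2,
    gene_test_frac: float | None = None,
    max_retries: int = 50,
) -> list[EvaluationRun]:
    """Per run, partition the gene universe; keep only pairs whose two genes
    fall on the same side (cross pairs are dropped), so train and test share
    zero genes. Partitions leaving one side single-class are resampled up to
    ``max_retries`` times."""
    df = labels.frame
    _check_two_classes(df, "label table")
    genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    q = gene_test_frac if gene_test_frac is not None else gene_test_fraction_for(target_test_frac)
    n_test_genes = max(1, int(round(q * len(genes))))
    runs = []
    for r in range(n_runs):
        base = seed * 100_003 + r + 1
        for attempt in range(max_retries):
            rng = np.random.default_rng(base + 7919 * attempt)
            perm = rng.permutation(len(genes))
            test_genes = {genes[i] for i in perm[:n_test_genes]}
            train_genes = {genes[i] for i in perm[n_test_genes:]}
            in_test = df["gene_a"].isin(test_genes) & df["gene_b"].isin(test_genes)
            in_train = df["gene_a"].isin(train_genes) & df["gene_b"].isin(train_genes)
            tr, te = df[in_train], df[in_test]
            if len(tr) and len(te) and tr["label"].nunique() == 2 and te["label"].nunique() == 2:
                tr = _undersample(tr, rng)
                te = _undersample(te, rng)
                run = EvaluationRun(r, base, SLLabelTable(tr), SLLabelTable(te), "double_holdout")
                tg = {g for p in run.train.pairs for g in p.genes}
                sg = {g for p in run.test.pairs for g in p.genes}
                assert not (tg & sg), "gene overlap in double-holdout run"
                runs.append(run)
                break
        else:
            raise RuntimeError(
                f"could not find a two-class gene partition in {max_retries} tries (run {r})"
            )
    return runs


def make_cross_source_runs(
    train_labels: SLLabelTable,
    test_labels: SLLabelTable,
    n_runs: int = 10,
    seed: int = 0,
) -> list[EvaluationRun]:
    """Train on one label study, test on another; pairs labelled in both
    studies are removed from the test side to prevent leakage."""
    tr_df = train_labels.frame
    te_df = test_labels.frame
    _check_two_classes(tr_df, "train source")
    _check_two_classes(te_df, "test source")
    train_keys = set(zip(tr_df["gene_a"], tr_df["gene_b"]))
    te_df = te_df[~pd.Series(list(zip(te_df["gene_a"], te_df["gene_b"])), index=te_df.index).isin(train_keys)]
    if te_df.empty or te_df["label"].nunique() < 2:
        raise ValueError("test source has no usable two-class pairs after removing overlap")
    runs = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed * 100_003 + r + 1)
        runs.append(
            EvaluationRun(
                r,
                seed * 100_003 + r + 1,
                SLLabelTable(_undersample(tr_df, rng)),
                SLLabelTable(_undersample(te_df, rng)),
                "cross_source",
            )
        )
    return runs


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve as average precision."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC needs both classes")
    if len(y) != len(scores):
        raise ValueError("labels and scores must align")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUROC = Mann-Whitney U statistic / (n+ * n-)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes")
    if len(y) != len(scores):
        raise ValueError("labels and scores must align")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def compare_wilcoxon(metric_a: Sequence[float], metric_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-run metrics.

    Zero differences are dropped per the standard convention; if every
    difference is zero the comparison is vacuous and p = 1 is returned."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need paired vectors of equal length >= 5")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning p = 1")
        return 1.0
    nz = diffs[diffs != 0]
    if len(nz) <= 15:
        return _exact_signed_rank_p(nz)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    (average ranks for tied |differences|), valid with ties where the
    textbook exact tables are not."""
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = float(ranks[diffs > 0].sum())
    total = float(ranks.sum())
    w_all = np.zeros(1, dtype=float)
    for r in ranks:  # distribution of W+ over all sign assignments
        w_all = np.concatenate([w_all, w_all + r])
    eps = 1e-9
    p_ge = np.mean(w_all >= w_obs - eps)
    p_le = np.mean(w_all <= w_obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def run_experiment(
    runs: Sequence[EvaluationRun],
    fit_predict: Callable[[SLLabelTable, SLLabelTable], dict[str, np.ndarray]],
) -> pd.DataFrame:
    """Fit/score each run and tabulate metrics.

    ``fit_predict(train, test)`` returns {model name -> test scores aligned
    to test.pairs}; typically the ensemble plus its single-source submodels.
    Failures are isolated per run (logged, row skipped). Returns a tidy
    table (run, model, auprc, auroc)."""
    rows = []
    for run in runs:
        try:
            scores_by_model = fit_predict(run.train, run.test)
            y = run.test.frame["label"].to_numpy()
            for name, scores in scores_by_model.items():
                rows.append((run.index, name, auprc(y, scores), auroc(y, scores)))
        except Exception as exc:
            logger.error("run %d failed: %s", run.index, exc)
    return pd.DataFrame(rows, columns=["run", "model", "auprc", "auroc"])


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby("model")[["auprc", "auroc"]]
        .agg(["mean", "median", "std"])
        .sort_index()
    )
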
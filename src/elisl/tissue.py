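"""Tissue-cohort gene-pair features and co-mutation survival analysis.

Thirteen features per pair: one survival feature (Wald p-value of the
co-mutation group coefficient in a Cox proportional-hazards model with age,
sex and cancer-type covariates), four average-expression features, six
co-expression features (Pearson r and p in tumour, matched-normal and
healthy-donor compartments) and two copy-number correlation features
(Spearman rho and p in tumour).

Expression *levels* are log2(x+1)-transformed before averaging and
correlation; z-scores are used only for alteration calling. Co-mutation for
a pair means an alteration in both genes in the same sample, where an
alteration in any one omics layer suffices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cellline import AlterationMatrix, Thresholds, call_alterations, masked_pair_means
from .data_io import FeatureBlock, GenePair, OmicsBundle

logger = logging.getLogger(__name__)

TISSUE_FEATURE_NAMES = [
    "survival_p",
    "expr_a_partner_unaltered",
    "expr_a_partner_altered",
    "expr_b_partner_unaltered",
    "expr_b_partner_altered",
    "coexpr_tumour_r",
    "coexpr_tumour_p",
    "coexpr_normal_r",
    "coexpr_normal_p",
    "coexpr_healthy_r",
    "coexpr_healthy_p",
    "cna_spearman_rho",
    "cna_spearman_p",
]

GROUP_CO_ALTERED = "co-altered"
GROUP_NOT_CO_ALTERED = "not-co-altered"
SUBGROUP_ONE_ONLY = "one-family-only"
SUBGROUP_UNALTERED = "unaltered"


@dataclass
class ComutationGrouping:
    """Exhaustive, disjoint partition of cohort samples by co-alteration."""

    co_altered: pd.Series  # sample -> bool
    subgroup: pd.Series  # sample -> {co-altered, one-family-only, unaltered}

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.subgroup.value_counts().to_dict()


@dataclass
class SurvivalResult:
    hazard_ratio: float
    p_value: float
    covariate_estimates: dict[str, float]
    group_sizes: dict[str, int]
    median_survival: dict[str, float]


def _log2p1(frame: pd.DataFrame) -> pd.DataFrame:
    return np.log2(frame + 1.0)


def _family_alteration(alt: AlterationMatrix, family: Sequence[str]) -> pd.Series:
    present = [g for g in family if g in alt.frame.columns]
    if not present:
        return pd.Series(False, index=alt.frame.index)
    return alt.frame[present].any(axis=1)


def _grouping_from_hits(hit_a: pd.Series, hit_b: pd.Series) -> ComutationGrouping:
    co = hit_a & hit_b
    one_only = (hit_a | hit_b) & ~co
    subgroup = pd.Series(SUBGROUP_UNALTERED, index=co.index)
    subgroup[one_only] = SUBGROUP_ONE_ONLY
    subgroup[co] = GROUP_CO_ALTERED
    return ComutationGrouping(co_altered=co, subgroup=subgroup)


def comutation_grouping(
    pair: GenePair, bundle: OmicsBundle, thresholds: Thresholds | None = None
) -> ComutationGrouping:
    """Samples co-altered iff both genes carry an any-channel alteration."""
    alt = call_alterations(bundle, "any", thresholds)
    return _grouping_from_hits(
        _family_alteration(alt, [pair.gene_a]), _family_alteration(alt, [pair.gene_b])
    )


def _cox_fit(
    clinical: pd.DataFrame, co_altered: pd.Series
) -> tuple[float, float, dict[str, float]] | None:
    """CoxPH of survival on the co-mutation indicator with age/sex/cancer
    covariates (Efron ties). Returns (HR, Wald p, covariates) or None when
    the fit is degenerate or fails to converge."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = clinical.set_index("sample")
    df = df.loc[df.index.intersection(co_altered.index)]
    data = pd.DataFrame(
        {
            "time": df["time_months"].astype(float),
            "event": df["event"].astype(int),
            "group": co_altered.loc[df.index].astype(int),
            "age": df["age"].astype(float),
        }
    )
    if data["group"].nunique() < 2:
        return None
    # drop single-level categorical covariates (e.g. single-sex cohorts)
    if df["sex"].nunique() > 1:
        data["sex"] = (df["sex"] == sorted(df["sex"].unique())[0]).astype(int)
    if df["cancer"].nunique() > 1:
        dummies = pd.get_dummies(df["cancer"], prefix="cancer", drop_first=True)
        data = pd.concat([data, dummies.astype(int)], axis=1)
    # constant covariates make the information matrix singular
    keep = [c for c in data.columns if c in ("time", "event", "group") or data[c].nunique() > 1]
    data = data[keep]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(data, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        logger.debug("CoxPH fit failed: %s", exc)
        return None
    summary = cph.summary
    hr = float(summary.loc["group", "exp(coef)"])
    p = float(summary.loc["group", "p"])
    covs = {c: float(summary.loc[c, "coef"]) for c in summary.index if c != "group"}
    if not np.isfinite(p):
        return None
    return hr, p, covs


def survival_feature(
    pair: GenePair, bundle: OmicsBundle, thresholds: Thresholds | None = None
) -> float:
    """Wald p-value for the co-mutation group coefficient; NaN when the
    co-altered group is empty or the fit does not converge."""
    if bundle.clinical is None:
        return np.nan
    grouping = comutation_grouping(pair, bundle, thresholds)
    if not grouping.co_altered.any():
        logger.debug("pair %s has no co-altered samples", pair)
        return np.nan
    fit = _cox_fit(bundle.clinical, grouping.co_altered)
    return np.nan if fit is None else fit[1]


def avg_expression_features(
    pair: GenePair, bundle: OmicsBundle, thresholds: Thresholds | None = None
) -> np.ndarray:
    """Average log2(x+1) tumour expression of each gene conditioned on the
    partner's any-channel alteration status (4 features)."""
    if bundle.expr_level is None:
        return np.full(4, np.nan)
    alt = call_alterations(bundle, "any", thresholds)
    return masked_pair_means(pair, _log2p1(bundle.expr_level), alt)


def _pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def coexpression_features(pair: GenePair, bundle: OmicsBundle) -> np.ndarray:
    """Pearson (r, p) of the two genes' log-expression in tumour, matched
    normal and healthy-donor compartments, in that order (6 features)."""
    out = []
    for compartment in (bundle.expr_level, bundle.expr_level_normal, bundle.expr_level_healthy):
        if (
            compartment is None
            or pair.gene_a not in compartment.columns
            or pair.gene_b not in compartment.columns
        ):
            out.extend([np.nan, np.nan])
            continue
        logged = _log2p1(compartment[[pair.gene_a, pair.gene_b]])
        out.extend(_pearson_pair(logged[pair.gene_a].to_numpy(), logged[pair.gene_b].to_numpy()))
    return np.array(out)


def cna_correlation_features(pair: GenePair, bundle: OmicsBundle) -> np.ndarray:
    """Spearman (rho, p) of the genes' tumour copy-number scores."""
    if bundle.cna is None or pair.gene_a not in bundle.cna.columns or pair.gene_b not in bundle.cna.columns:
        return np.full(2, np.nan)
    x = bundle.cna[pair.gene_a].to_numpy(dtype=float)
    y = bundle.cna[pair.gene_b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.full(2, np.nan)
    rho, p = stats.spearmanr(x, y)
    return np.array([float(rho), float(p)])


def tissue_feature_block(
    pairs: Sequence[GenePair],
    bundle: OmicsBundle,
    thresholds: Thresholds | None = None,
) -> FeatureBlock:
    """N x 13 tissue feature block in the fixed column order
    [survival, avg-expression x4, co-expression x6, CNA correlation x2]."""
    alt = None
    expr_logged = None
    if bundle.expr_level is not None:
        expr_logged = _log2p1(bundle.expr_level)
    try:
        alt = call_alterations(bundle, "any", thresholds)
    except ValueError:
        alt = None

    rows = []
    for pair in pairs:
        surv = survival_feature(pair, bundle, thresholds)
        if alt is not None and expr_logged is not None:
            avg = masked_pair_means(pair, expr_logged, alt)
        else:
            avg = np.full(4, np.nan)
        coexpr = coexpression_features(pair, bundle)
        cna = cna_correlation_features(pair, bundle)
        rows.append(np.concatenate([[surv], avg, coexpr, cna]))
    values = np.vstack(rows) if rows else np.empty((0, 13))
    return FeatureBlock(list(pairs), values, list(TISSUE_FEATURE_NAMES), "tissue")


def family_comutation_survival(
    family_a: Sequence[str],
    family_b: Sequence[str],
    bundle: OmicsBundle,
    thresholds: Thresholds | None = None,
    min_group_size: int = 5,
) -> tuple[SurvivalResult, dict[str, pd.DataFrame]]:
    """Gene-family co-mutation survival analysis.

    Samples with an any-channel alteration in at least one member of each
    family form the co-altered group; the complement splits into
    one-family-only and unaltered subgroups. Returns the CoxPH result for
    the co-altered indicator (p-value NaN when the group is empty or
    smaller than ``min_group_size``) plus Kaplan-Meier step functions per
    group. With singleton families this reduces exactly to the pairwise
    grouping.
    """
    from lifelines import KaplanMeierFitter

    if not len(family_a) or not len(family_b):
        raise ValueError("gene families must be non-empty")
    alt = call_alterations(bundle, "any", thresholds)
    grouping = _grouping_from_hits(
        _family_alteration(alt, family_a), _family_alteration(alt, family_b)
    )
    sizes = {
        GROUP_CO_ALTERED: int(grouping.co_altered.sum()),
        GROUP_NOT_CO_ALTERED: int((~grouping.co_altered).sum()),
        SUBGROUP_ONE_ONLY: int((grouping.subgroup == SUBGROUP_ONE_ONLY).sum()),
        SUBGROUP_UNALTERED: int((grouping.subgroup == SUBGROUP_UNALTERED).sum()),
    }

    hr, p, covs = np.nan, np.nan, {}
    if bundle.clinical is not None and sizes[GROUP_CO_ALTERED] >= max(1, min_group_size):
        fit = _cox_fit(bundle.clinical, grouping.co_altered)
        if fit is not None:
            hr, p, covs = fit

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    if bundle.clinical is not None:
        clin = bundle.clinical.set_index("sample")
        groups = {
            GROUP_CO_ALTERED: grouping.co_altered,
            GROUP_NOT_CO_ALTERED: ~grouping.co_altered,
            SUBGROUP_ONE_ONLY: grouping.subgroup == SUBGROUP_ONE_ONLY,
            SUBGROUP_UNALTERED: grouping.subgroup == SUBGROUP_UNALTERED,
        }
        for name, mask in groups.items():
            members = mask[mask].index.intersection(clin.index)
            if len(members) == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(
                clin.loc[members, "time_months"].astype(float),
                clin.loc[members, "event"].astype(int),
            )
            sf = km.survival_function_
            curves[name] = pd.DataFrame(
                {"time_months": sf.index.to_numpy(), "survival_prob": sf.iloc[:, 0].to_numpy()}
            )
            medians[name] = float(km.median_survival_time_)
    result = SurvivalResult(
        hazard_ratio=hr,
        p_value=p,
        covariate_estimates=covs,
        group_sizes=sizes,
        median_survival=medians,
    )
    return result, curves
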
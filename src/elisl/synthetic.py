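"""Synthetic multi-omics world with plantable synthetic-lethality signal.

Generates everything the rest of the package consumes — protein sequences,
a PPI edge list with evidence classes, a cell-line omics bundle with CRISPR
dependency scores, and a patient tissue bundle with tumour/normal/healthy
expression, mutations, copy number and clinical follow-up — so the whole
pipeline is exercisable without external downloads.

Planted SL signal, per channel:

* sequence — both partners of an SL pair share a common inserted motif, so
  k-mer-hash embedding differences shrink for SL pairs;
* PPI — SL partners are wired to a set of common neighbours;
* dependency — knocking out one SL partner matters more when the other is
  genetically lost: dependency of gene_a drops by ``delta`` in cell lines
  carrying a non-silent mutation in gene_b (and vice versa), which makes
  the mutation-channel CRISPR source the deliberately dominant one;
* co-expression — tumour expression of SL partners is correlated at
  ``r_target`` on top of a weak shared-factor background present for all
  genes (mimicking global expression programs, and keeping the tissue
  source informative but not trivially separable);
* survival — the hazard of patients co-altered in at least one SL pair is
  multiplied by ``hazard_ratio``.

Planted SL pairs are gene-disjoint (a matching) so the pairwise correlation
targets never conflict; non-SL pairs are sampled from the remaining pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenePair, OmicsBundle, SLLabelTable, write_matrix, write_sequences

logger = logging.getLogger(__name__)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
CANCER = "SYNT"
VARIANT_CLASSES = ["missense", "nonsense", "frameshift", "splice_site", "silent"]
VARIANT_PROBS = [0.55, 0.15, 0.1, 0.1, 0.1]


@dataclass
class SyntheticWorldConfig:
    n_genes: int = 200
    n_cell_lines: int = 300
    n_patients: int = 600
    n_normals: int = 120
    n_healthy: int = 120
    n_sl_pairs: int = 80
    n_nonsl_pairs: int = 80
    delta: float = 1.0  # dependency shift under partner mutation
    r_target: float = 0.6  # tumour co-expression of SL partners
    hazard_ratio: float = 0.5  # hazard multiplier for co-altered patients
    effect_penetrance: float = 1.0  # fraction of SL pairs that manifest the effects
    mutation_rate: float = 0.15  # per (cell line, gene)
    patient_mutation_rate: float = 0.08
    cna_deep_rate: float = 0.02  # per (sample, gene), each of +2/-2
    dependency_noise: float = 0.3
    seq_length: int = 240
    motif_length: int = 60  # shared-domain scale, so k-mer hashes see it
    communality_max: float = 0.7  # spread of background co-expression
    background_ppi_prob: float = 0.02
    n_shared_neighbors: int = 3
    d_seq: int = 1024
    d_ppi: int = 64
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_patients", "n_sl_pairs", "n_nonsl_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mutation_rate", "patient_mutation_rate", "cna_deep_rate"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        total = self.n_sl_pairs + self.n_nonsl_pairs
        if total > comb(self.n_genes, 2):
            raise ValueError(
                f"{total} planted pairs exceed C({self.n_genes},2) possible pairs"
            )
        if 2 * self.n_sl_pairs > self.n_genes:
            raise ValueError(
                "gene-disjoint SL pairs require n_genes >= 2 * n_sl_pairs"
            )
        if not 0 < self.effect_penetrance <= 1:
            raise ValueError("effect_penetrance must lie in (0, 1]")


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    genes: list[str]
    sequences: dict[str, str]
    ppi_edges: pd.DataFrame
    cell_lines: OmicsBundle
    tissue: OmicsBundle
    labels: SLLabelTable
    sl_pairs: list[GenePair]
    nonsl_pairs: list[GenePair]
    manifest_pairs: list[GenePair] = None  # SL pairs actually carrying effects

    def __post_init__(self) -> None:
        if self.manifest_pairs is None:
            self.manifest_pairs = list(self.sl_pairs)


def _random_sequences(genes, cfg, rng) -> dict[str, str]:
    return {
        g: "".join(AA[rng.integers(0, len(AA), size=cfg.seq_length)]) for g in genes
    }


def _plant_motifs(sequences, sl_pairs, cfg, rng) -> None:
    for pair in sl_pairs:
        motif = "".join(AA[rng.integers(0, len(AA), size=cfg.motif_length)])
        for g in pair.genes:
            seq = sequences[g]
            pos = int(rng.integers(0, len(seq) - cfg.motif_length + 1))
            sequences[g] = seq[:pos] + motif + seq[pos + cfg.motif_length :]


def _ppi_edges(genes, sl_pairs, cfg, rng) -> pd.DataFrame:
    evidence_pool = np.array(["experimental", "curated", "textmining"])
    rows = []
    n = len(genes)
    # sparse background
    n_bg = int(cfg.background_ppi_prob * comb(n, 2))
    idx_a = rng.integers(0, n, size=n_bg)
    idx_b = rng.integers(0, n, size=n_bg)
    for a, b in zip(idx_a, idx_b):
        if a == b:
            continue
        rows.append((genes[a], genes[b], str(evidence_pool[rng.integers(0, 3)])))
    # common neighbourhoods for SL partners
    for pair in sl_pairs:
        hubs = rng.choice(n, size=cfg.n_shared_neighbors, replace=False)
        for h in hubs:
            hub = genes[int(h)]
            for g in pair.genes:
                if hub != g:
                    rows.append((g, hub, "experimental"))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "evidence_class"])


def _mutation_table(samples, genes, rate, rng) -> pd.DataFrame:
    mask = rng.random((len(samples), len(genes))) < rate
    si, gi = np.nonzero(mask)
    classes = rng.choice(VARIANT_CLASSES, size=len(si), p=VARIANT_PROBS)
    return pd.DataFrame(
        {
            "sample": [samples[i] for i in si],
            "gene": [genes[i] for i in gi],
            "variant_class": classes,
        }
    )


def _cna_matrix(samples, genes, deep_rate, rng) -> pd.DataFrame:
    u = rng.random((len(samples), len(genes)))
    vals = np.zeros(u.shape, dtype=int)
    vals[u < deep_rate] = 2
    vals[(u >= deep_rate) & (u < 2 * deep_rate)] = -2
    vals[(u >= 2 * deep_rate) & (u < 2 * deep_rate + 0.05)] = 1
    vals[(u >= 2 * deep_rate + 0.05) & (u < 2 * deep_rate + 0.10)] = -1
    return pd.DataFrame(vals, index=samples, columns=genes)


def _nonsilent_mask(mutations: pd.DataFrame, samples, genes) -> np.ndarray:
    from .cellline import NONSILENT_CLASSES

    mat = np.zeros((len(samples), len(genes)), dtype=bool)
    s_idx = {s: i for i, s in enumerate(samples)}
    g_idx = {g: i for i, g in enumerate(genes)}
    hits = mutations[mutations["variant_class"].isin(NONSILENT_CLASSES)]
    for s, g in zip(hits["sample"], hits["gene"]):
        mat[s_idx[s], g_idx[g]] = True
    return mat


def _expression_levels(samples, genes, sl_pairs, cfg, rng, correlate_sl: bool) -> pd.DataFrame:
    """Factor-model expression: latent_g = sqrt(c_g) F + sqrt(1-c_g) e_g,
    with SL-partner idiosyncratic noise correlated so the pair's total
    latent correlation hits r_target (tumour compartment only)."""
    n_s, n_g = len(samples), len(genes)
    communality = rng.uniform(0.0, cfg.communality_max, size=n_g)
    factor = rng.standard_normal(n_s)
    eps = rng.standard_normal((n_s, n_g))
    # r_target == 0 means "no planted correlation": SL pairs keep the same
    # background structure as every other pair, rather than being forced to
    # exactly zero correlation (which would itself be a detectable signal)
    if correlate_sl and cfg.r_target != 0.0:
        g_idx = {g: i for i, g in enumerate(genes)}
        for pair in sl_pairs:
            ia, ib = g_idx[pair.gene_a], g_idx[pair.gene_b]
            ca, cb = communality[ia], communality[ib]
            rho = (cfg.r_target - np.sqrt(ca * cb)) / np.sqrt((1 - ca) * (1 - cb))
            rho = float(np.clip(rho, -0.999, 0.999))
            eps[:, ib] = rho * eps[:, ia] + np.sqrt(1 - rho**2) * eps[:, ib]
    latent = np.sqrt(communality) * factor[:, None] + np.sqrt(1 - communality) * eps
    level = np.power(2.0, 6.0 + latent)
    return pd.DataFrame(level, index=samples, columns=genes)


def generate_world(
    config: SyntheticWorldConfig | None = None, seed: int | None = None
) -> SyntheticWorld:
    """Deterministically generate the full synthetic world (same seed, same
    world, bitwise)."""
    cfg = config or SyntheticWorldConfig()
    if seed is not None:
        cfg = SyntheticWorldConfig(**{**cfg.__dict__, "seed": seed})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # planted pairs: SL pairs form a gene-disjoint matching
    perm = rng.permutation(cfg.n_genes)
    sl_pairs = [
        GenePair(genes[perm[2 * i]], genes[perm[2 * i + 1]])
        for i in range(cfg.n_sl_pairs)
    ]
    if cfg.effect_penetrance < 1.0:
        manifest_mask = rng.random(cfg.n_sl_pairs) < cfg.effect_penetrance
        manifest_pairs = [p for p, m in zip(sl_pairs, manifest_mask) if m]
    else:
        manifest_pairs = list(sl_pairs)
    sl_keys = {p.genes for p in sl_pairs}
    nonsl_pairs: list[GenePair] = []
    seen = set(sl_keys)
    while len(nonsl_pairs) < cfg.n_nonsl_pairs:
        i, j = rng.integers(0, cfg.n_genes, size=2)
        if i == j:
            continue
        pair = GenePair(genes[int(i)], genes[int(j)])
        if pair.genes in seen:
            continue
        seen.add(pair.genes)
        nonsl_pairs.append(pair)

    sequences = _random_sequences(genes, cfg, rng)
    _plant_motifs(sequences, manifest_pairs, cfg, rng)
    ppi_edges = _ppi_edges(genes, manifest_pairs, cfg, rng)

    # --- cell lines -------------------------------------------------------
    lines = [f"CL{i:04d}" for i in range(cfg.n_cell_lines)]
    cl_mut = _mutation_table(lines, genes, cfg.mutation_rate, rng)
    cl_expr_z = pd.DataFrame(
        rng.standard_normal((cfg.n_cell_lines, cfg.n_genes)), index=lines, columns=genes
    )
    cl_cna = _cna_matrix(lines, genes, cfg.cna_deep_rate, rng)
    dependency = rng.normal(0.0, cfg.dependency_noise, size=(cfg.n_cell_lines, cfg.n_genes))
    mut_mask = _nonsilent_mask(cl_mut, lines, genes)
    g_idx = {g: i for i, g in enumerate(genes)}
    for pair in manifest_pairs:
        ia, ib = g_idx[pair.gene_a], g_idx[pair.gene_b]
        dependency[mut_mask[:, ib], ia] -= cfg.delta
        dependency[mut_mask[:, ia], ib] -= cfg.delta
    cell_lines = OmicsBundle(
        samples=lines,
        genes=genes,
        dependency=pd.DataFrame(dependency, index=lines, columns=genes),
        expr_z=cl_expr_z,
        mutations=cl_mut,
        cna=cl_cna,
        sample_context=pd.Series(CANCER, index=lines),
    )

    # --- patient tissue ---------------------------------------------------
    patients = [f"TP{i:04d}" for i in range(cfg.n_patients)]
    normals = [f"NT{i:04d}" for i in range(cfg.n_normals)]
    healthy = [f"HD{i:04d}" for i in range(cfg.n_healthy)]
    tp_mut = _mutation_table(patients, genes, cfg.patient_mutation_rate, rng)
    tp_expr_z = pd.DataFrame(
        rng.standard_normal((cfg.n_patients, cfg.n_genes)), index=patients, columns=genes
    )
    tp_cna = _cna_matrix(patients, genes, cfg.cna_deep_rate, rng)
    tp_level = _expression_levels(patients, genes, manifest_pairs, cfg, rng, correlate_sl=True)
    nt_level = _expression_levels(normals, genes, manifest_pairs, cfg, rng, correlate_sl=False)
    hd_level = _expression_levels(healthy, genes, manifest_pairs, cfg, rng, correlate_sl=False)

    # any-channel alteration per patient x gene (mutation | z | deep CNA)
    alt = (
        _nonsilent_mask(tp_mut, patients, genes)
        | (tp_expr_z.abs().to_numpy() > 1.96)
        | np.isin(tp_cna.to_numpy(), [-2, 2])
    )
    co_altered = np.zeros(cfg.n_patients, dtype=bool)
    for pair in manifest_pairs:
        ia, ib = g_idx[pair.gene_a], g_idx[pair.gene_b]
        co_altered |= alt[:, ia] & alt[:, ib]

    base_hazard = 1.0 / 60.0  # per month
    hazard = base_hazard * np.where(co_altered, cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(30.0, 150.0, size=cfg.n_patients)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame(
        {
            "sample": patients,
            "time_months": observed,
            "event": event,
            "age": np.clip(rng.normal(60.0, 10.0, size=cfg.n_patients), 25, 90),
            "sex": rng.choice(["F", "M"], size=cfg.n_patients),
            "cancer": CANCER,
        }
    )
    tissue = OmicsBundle(
        samples=patients,
        genes=genes,
        expr_z=tp_expr_z,
        expr_level=tp_level,
        mutations=tp_mut,
        cna=tp_cna,
        clinical=clinical,
        sample_context=pd.Series(CANCER, index=patients),
        expr_level_normal=nt_level,
        expr_level_healthy=hd_level,
    )

    labels = SLLabelTable.from_records(
        [(p, 1) for p in sl_pairs] + [(p, 0) for p in nonsl_pairs],
        source="planted",
        cancer=CANCER,
    )
    return SyntheticWorld(
        config=cfg,
        genes=genes,
        sequences=sequences,
        ppi_edges=ppi_edges,
        cell_lines=cell_lines,
        tissue=tissue,
        labels=labels,
        sl_pairs=sl_pairs,
        nonsl_pairs=nonsl_pairs,
        manifest_pairs=manifest_pairs,
    )


def verify_planted_effects(world: SyntheticWorld) -> pd.DataFrame:
    """Recover each planted parameter with its natural estimator and flag
    deviations beyond 3 standard errors.

    delta: mean drop in a gene's dependency between partner-mutated and
    partner-unmutated cell lines, over SL pairs. r: mean tumour Pearson
    correlation of log2-expression over SL pairs. hazard_ratio: CoxPH
    hazard ratio of the co-altered-in-any-SL-pair indicator.
    """
    from scipy import stats as sps

    cfg = world.config
    cl = world.cell_lines
    dep = cl.dependency.to_numpy()
    mut_mask = _nonsilent_mask(cl.mutations, cl.samples, cl.genes)
    g_idx = {g: i for i, g in enumerate(cl.genes)}

    deltas = []
    for pair in world.manifest_pairs:
        ia, ib = g_idx[pair.gene_a], g_idx[pair.gene_b]
        for target, partner in ((ia, ib), (ib, ia)):
            m = mut_mask[:, partner]
            if m.any() and (~m).any():
                deltas.append(dep[~m, target].mean() - dep[m, target].mean())
    delta_hat = float(np.mean(deltas))
    delta_se = float(np.std(deltas, ddof=1) / np.sqrt(len(deltas)))

    logged = np.log2(world.tissue.expr_level + 1.0)
    rs = [
        float(sps.pearsonr(logged[p.gene_a], logged[p.gene_b])[0])
        for p in world.manifest_pairs
    ]
    r_hat = float(np.mean(rs))
    r_se = float(np.std(rs, ddof=1) / np.sqrt(len(rs))) if len(rs) > 1 else 0.0
    if cfg.r_target == 0.0:
        # nothing planted: SL pairs share the background structure, so the
        # diagnostic is the excess of SL-pair correlation over background
        bg = [
            float(sps.pearsonr(logged[p.gene_a], logged[p.gene_b])[0])
            for p in world.nonsl_pairs
        ]
        r_hat -= float(np.mean(bg))
        r_se = float(np.sqrt(r_se**2 + np.var(bg, ddof=1) / len(bg)))

    # hazard ratio via CoxPH on the planted co-alteration indicator
    from lifelines import CoxPHFitter

    tissue = world.tissue
    alt = (
        _nonsilent_mask(tissue.mutations, tissue.samples, tissue.genes)
        | (tissue.expr_z.abs().to_numpy() > 1.96)
        | np.isin(tissue.cna.to_numpy(), [-2, 2])
    )
    gi = {g: i for i, g in enumerate(tissue.genes)}
    co = np.zeros(len(tissue.samples), dtype=bool)
    for pair in world.manifest_pairs:
        co |= alt[:, gi[pair.gene_a]] & alt[:, gi[pair.gene_b]]
    clin = tissue.clinical
    data = pd.DataFrame(
        {
            "time": clin["time_months"].to_numpy(),
            "event": clin["event"].to_numpy(),
            "co": co.astype(int),
        }
    )
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time", event_col="event")
    h_hat = float(np.exp(cph.summary.loc["co", "coef"]))
    h_se = float(cph.summary.loc["co", "se(coef)"])  # on log scale

    rows = [
        ("delta", cfg.delta, delta_hat, delta_se, abs(delta_hat - cfg.delta) > 3 * delta_se),
        ("r_target", cfg.r_target, r_hat, r_se, abs(r_hat - cfg.r_target) > 3 * max(r_se, 1e-12)),
        (
            "hazard_ratio",
            cfg.hazard_ratio,
            h_hat,
            h_se,
            abs(np.log(h_hat) - np.log(cfg.hazard_ratio)) > 3 * h_se,
        ),
    ]
    return pd.DataFrame(
        rows, columns=["parameter", "configured", "estimated", "se", "flag"]
    )


def write_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Write every table in the formats the readers consume (FASTA + TSV),
    plus the planted-truth label table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sequences(world.sequences, directory / "sequences.fasta")
    world.ppi_edges.to_csv(directory / "ppi_edges.tsv", sep="\t", index=False)
    cl, ti = world.cell_lines, world.tissue
    write_matrix(cl.dependency, directory / "cellline_dependency.tsv")
    write_matrix(cl.expr_z, directory / "cellline_expression_z.tsv")
    write_matrix(cl.cna, directory / "cellline_cna.tsv")
    cl.mutations.to_csv(directory / "cellline_mutations.tsv", sep="\t", index=False)
    write_matrix(ti.expr_z, directory / "tissue_expression_z.tsv")
    write_matrix(ti.expr_level, directory / "tissue_expression_level.tsv")
    write_matrix(ti.expr_level_normal, directory / "normal_expression_level.tsv")
    write_matrix(ti.expr_level_healthy, directory / "healthy_expression_level.tsv")
    write_matrix(ti.cna, directory / "tissue_cna.tsv")
    ti.mutations.to_csv(directory / "tissue_mutations.tsv", sep="\t", index=False)
    ti.clinical.to_csv(directory / "tissue_clinical.tsv", sep="\t", index=False)
    world.labels.to_tsv(directory / "labels.tsv")
    truth = pd.DataFrame(
        [(p.gene_a, p.gene_b, 1) for p in world.sl_pairs]
        + [(p.gene_a, p.gene_b, 0) for p in world.nonsl_pairs],
        columns=["gene_a", "gene_b", "planted_sl"],
    )
    truth.to_csv(directory / "planted_truth.tsv", sep="\t", index=False)
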
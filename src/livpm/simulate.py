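"""Synthetic cohort and multi-omics data generation with known ground truth.

Emulates the statistical structure of a living-biopsy (LIV) versus
postmortem (PM) prefrontal-cortex comparison study: a cohort of living
participants (some with bilateral biopsies, so two samples per individual)
and postmortem donors (one sample each); negative-binomial primary and
mature RNA counts with group log-fold-changes and splicing-rate shifts;
TMT-style log2 sample-to-reference protein ratio matrices with multiplex
batch effects, group-confounded multiplex composition and ~39.7% overall
missingness; per-sample intron junction count tables with multinomial usage
within 2-10 intron clusters; and gene-set tables for enrichment tests.

Every generator is driven by a single :class:`SimulationConfig` and a seed;
identical (config, seed) pairs give bit-identical output. True effects are
recorded in :class:`GroundTruth` so downstream recovery and calibration
tests can compare estimates against the generating parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "OmicsBundle",
    "generate_cohort",
    "generate_rna_counts",
    "generate_protein_matrix",
    "generate_junction_counts",
    "generate_gene_sets",
    "generate_paired_residuals",
    "simulate_bundle",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 171 living individuals of
    whom 117 (bilateral_fraction ~ 0.684) contribute two hemispheric
    samples, 246 postmortem donors with one sample each, ~34 TMT multiplexes
    of 14-16 samples with composition partially confounded with LIV/PM
    status, and a 39.7% overall proteomics missing rate.
    """

    n_liv_individuals: int = 171
    n_pm_individuals: int = 246
    bilateral_fraction: float = 117 / 171
    n_genes: int = 2000
    de_fraction: float = 0.5
    logfc_scale: float = 1.0
    splicing_shift_fraction: float = 0.5
    splice_shift_log2: float = 1.0
    n_proteins: int = 2000
    n_multiplexes: int = 34
    multiplex_group_confounding: float = 0.5
    missing_rate_target: float = 0.397
    mnar_weight: float = 0.5
    n_clusters: int = 200
    introns_per_cluster: tuple[int, int] = (2, 10)
    usage_shift_fraction: float = 0.5
    dispersion: float = 0.1
    seed: int = 0
    # secondary knobs (variance components, depths, decoys)
    individual_sd: float = 0.3
    depth_sd: float = 0.2
    protein_noise_sd: float = 0.4
    protein_batch_sd: float = 0.5
    cluster_depth: float = 100.0
    low_contrib_decoy_fraction: float = 0.2
    decoy_contribution: float = 0.03
    high_zero_decoy_fraction: float = 0.2
    decoy_zero_rate: float = 0.4
    n_gene_sets: int = 30

    _PROPORTIONS = (
        "bilateral_fraction",
        "de_fraction",
        "splicing_shift_fraction",
        "multiplex_group_confounding",
        "missing_rate_target",
        "mnar_weight",
        "usage_shift_fraction",
        "low_contrib_decoy_fraction",
        "high_zero_decoy_fraction",
    )
    _POSITIVE_COUNTS = (
        "n_liv_individuals",
        "n_pm_individuals",
        "n_genes",
        "n_proteins",
        "n_multiplexes",
        "n_clusters",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._PROPORTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in self._POSITIVE_COUNTS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        lo, hi = self.introns_per_cluster
        if not (2 <= lo <= hi <= 10):
            raise ValueError(
                f"introns_per_cluster must be a range within [2, 10], got {self.introns_per_cluster}"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def rng(self, stream: int = 0) -> np.random.Generator:
        # independent, reproducible stream per generator
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside the synthetic data."""

    rna_logfc_primary: pd.Series | None = None
    rna_logfc_mature: pd.Series | None = None
    splicing_delta: pd.Series | None = None
    protein_logfc: pd.Series | None = None
    protein_batch_effects: pd.DataFrame | None = None
    cluster_usage: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    decoy_introns: dict[str, list[str]] = field(default_factory=dict)
    affected_genes: list[str] = field(default_factory=list)
    diffcoex_pairs: list[tuple[str, str]] = field(default_factory=list)
    gene_set_enriched: dict[str, bool] = field(default_factory=dict)


@dataclass
class OmicsBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimulationConfig
    metadata: pd.DataFrame
    primary_counts: pd.DataFrame
    mature_counts: pd.DataFrame
    protein: "object"  # TmtMatrix; imported lazily to avoid a cycle
    junctions: dict[str, pd.DataFrame]
    gene_sets: dict[str, list[str]]
    truth: GroundTruth


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata table: one row per sample.

    LIV individuals contribute one or (for the bilateral fraction) two
    samples; PM individuals exactly one. Covariates are drawn from simple
    documented distributions (sex ~ Bernoulli(0.5), age ~ N(60, 10) clipped
    to [18, 95], RIN-like score ~ N(7, 1) clipped to [4, 10],
    neuronal-fraction-like proportion ~ Beta(5, 5)), plus a round-robin
    sequencing batch label.
    """
    config.validate()
    rng = config.rng(1)
    n_bilateral = int(round(config.bilateral_fraction * config.n_liv_individuals))
    rows = []
    for i in range(config.n_liv_individuals):
        ind = f"LIV{i + 1:04d}"
        hemis = ("L", "R") if i < n_bilateral else ("L",)
        for h in hemis:
            rows.append((f"{ind}_{h}", ind, "LIV"))
    for i in range(config.n_pm_individuals):
        ind = f"PM{i + 1:04d}"
        rows.append((f"{ind}_S", ind, "PM"))
    meta = pd.DataFrame(rows, columns=["sample_id", "individual_id", "liv_pm_status"])
    n_ind = config.n_liv_individuals + config.n_pm_individuals
    ind_ids = [f"LIV{i + 1:04d}" for i in range(config.n_liv_individuals)] + [
        f"PM{i + 1:04d}" for i in range(config.n_pm_individuals)
    ]
    per_ind = pd.DataFrame(
        {
            "individual_id": ind_ids,
            "sex": rng.choice(["F", "M"], size=n_ind),
            "age": np.clip(rng.normal(60.0, 10.0, size=n_ind), 18.0, 95.0),
        }
    )
    meta = meta.merge(per_ind, on="individual_id", how="left")
    n_samp = len(meta)
    meta["rin"] = np.clip(rng.normal(7.0, 1.0, size=n_samp), 4.0, 10.0)
    meta["neuronal_fraction"] = rng.beta(5.0, 5.0, size=n_samp)
    meta["seq_batch"] = [f"B{(i % 12) + 1:02d}" for i in range(n_samp)]
    return meta


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_rna_counts(
    meta: pd.DataFrame, config: SimulationConfig, truth_out: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary and mature RNA count matrices (genes x samples).

    Log2 mean model per gene g, sample s of individual i in group G:

        primary: b_g - s_g/2 + (beta_g - delta_g/2) * [G=PM] + u_i + d_s
        mature:  b_g + s_g/2 + (beta_g + delta_g/2) * [G=PM] + u_i + d_s

    where b_g is the baseline, s_g > 0 the mature:primary abundance gap,
    beta_g the shared expression logFC (positive = higher in PM), delta_g
    the splicing-rate log2 shift (mature:primary ratio difference, positive
    = higher splicing rate in PM), u_i an individual random intercept shared
    by bilateral replicates, and d_s a per-sample depth offset. Counts are
    negative binomial with common dispersion.
    """
    if len(meta) == 0:
        raise ValueError("metadata is empty")
    rng = config.rng(2)
    G, S = config.n_genes, len(meta)
    genes = [f"gene{j + 1:05d}" for j in range(G)]

    base = rng.normal(5.0, 1.5, size=G)
    splice_gap = np.abs(rng.normal(2.0, 0.5, size=G))

    beta = np.zeros(G)
    n_de = int(round(config.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    beta[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * config.logfc_scale

    delta = np.zeros(G)
    n_shift = int(round(config.splicing_shift_fraction * G))
    shift_idx = rng.choice(G, size=n_shift, replace=False)
    delta[shift_idx] = rng.choice([-1.0, 1.0], size=n_shift) * config.splice_shift_log2

    individuals = meta["individual_id"].to_numpy()
    uniq_ind, ind_pos = np.unique(individuals, return_inverse=True)
    # per-gene random intercept shared by an individual's bilateral replicates
    u = rng.normal(0.0, config.individual_sd, size=(G, len(uniq_ind)))[:, ind_pos]
    depth = rng.normal(0.0, config.depth_sd, size=S)
    is_pm = (meta["liv_pm_status"].to_numpy() == "PM").astype(float)

    log2_primary = (
        (base - splice_gap / 2.0)[:, None]
        + (beta - delta / 2.0)[:, None] * is_pm[None, :]
        + u
        + depth[None, :]
    )
    log2_mature = (
        (base + splice_gap / 2.0)[:, None]
        + (beta + delta / 2.0)[:, None] * is_pm[None, :]
        + u
        + depth[None, :]
    )
    primary = _nb_sample(rng, 2.0**log2_primary, config.dispersion)
    mature = _nb_sample(rng, 2.0**log2_mature, config.dispersion)

    samples = meta["sample_id"].tolist()
    truth_out.rna_logfc_primary = pd.Series(beta - delta / 2.0, index=genes)
    truth_out.rna_logfc_mature = pd.Series(beta + delta / 2.0, index=genes)
    truth_out.splicing_delta = pd.Series(delta, index=genes)
    truth_out.affected_genes = [genes[j] for j in sorted(set(de_idx) | set(shift_idx))]
    return (
        pd.DataFrame(primary, index=genes, columns=samples),
        pd.DataFrame(mature, index=genes, columns=samples),
    )


def assign_multiplexes(meta: pd.DataFrame, config: SimulationConfig, rng) -> pd.Series:
    """Assign samples to TMT multiplexes with tunable group confounding.

    Samples are ranked by ``gamma * [G=PM] + U(0,1)`` and chunked into
    multiplexes in rank order: gamma=0 gives composition independent of
    group, gamma=1 gives fully separated (group-pure) multiplexes, and
    intermediate values mix the groups with a graded imbalance.
    """
    n = len(meta)
    if config.n_multiplexes > n:
        raise ValueError(
            f"n_multiplexes ({config.n_multiplexes}) exceeds the number of samples ({n})"
        )
    gamma = config.multiplex_group_confounding
    score = gamma * (meta["liv_pm_status"].to_numpy() == "PM") + rng.uniform(size=n)
    order = np.argsort(score, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = np.linspace(0, n, config.n_multiplexes + 1).astype(int)
    for m in range(config.n_multiplexes):
        labels[order[bounds[m] : bounds[m + 1]]] = f"TMT{m + 1:02d}"
    return pd.Series(labels, index=meta["sample_id"].to_numpy(), name="multiplex")


def generate_protein_matrix(meta: pd.DataFrame, config: SimulationConfig, truth_out: GroundTruth):
    """TMT-style log2 sample-to-reference ratio matrix with missingness.

    Per protein p, sample s in multiplex m: value = beta_p * [G=PM] +
    gamma_{p,m} + e, with gamma_{p,m} ~ N(0, protein_batch_sd) additive
    multiplex effects and e ~ N(0, protein_noise_sd). Missingness is a
    mixture of completely-at-random and abundance-dependent cells whose
    per-protein rates are rescaled so the expected overall rate equals
    ``missing_rate_target``.
    """
    from .proteomics import TmtMatrix  # local import; proteomics owns the container

    if config.n_multiplexes < 2:
        raise ValueError("n_multiplexes must be >= 2")
    rng = config.rng(3)
    P, S = config.n_proteins, len(meta)
    proteins = [f"prot{j + 1:05d}" for j in range(P)]
    multiplex = assign_multiplexes(meta, config, rng)
    mux_codes, mux_pos = np.unique(multiplex.to_numpy(), return_inverse=True)

    beta = np.zeros(P)
    n_de = int(round(config.de_fraction * P))
    de_idx = rng.choice(P, size=n_de, replace=False)
    beta[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * config.logfc_scale

    gamma = rng.normal(0.0, config.protein_batch_sd, size=(P, len(mux_codes)))
    is_pm = (meta["liv_pm_status"].to_numpy() == "PM").astype(float)
    values = (
        beta[:, None] * is_pm[None, :]
        + gamma[:, mux_pos]
        + rng.normal(0.0, config.protein_noise_sd, size=(P, S))
    )

    # per-protein missing rates: MCAR/MNAR mixture rescaled to hit the target
    abundance = rng.normal(0.0, 1.0, size=P)
    mnar = 1.0 / (1.0 + np.exp(2.0 * abundance))  # low abundance -> more missing
    w = config.mnar_weight
    rates = config.missing_rate_target * ((1.0 - w) + w * mnar / mnar.mean())
    rates = np.clip(rates, 0.0, 0.95)
    if rates.mean() > 0:
        rates *= config.missing_rate_target / rates.mean()
        rates = np.clip(rates, 0.0, 0.95)
    mask = rng.uniform(size=(P, S)) < rates[:, None]
    values = values.astype(float)
    values[mask] = np.nan

    df = pd.DataFrame(values, index=proteins, columns=meta["sample_id"].to_numpy())
    truth_out.protein_logfc = pd.Series(beta, index=proteins)
    truth_out.protein_batch_effects = pd.DataFrame(gamma, index=proteins, columns=list(mux_codes))
    sample_info = pd.DataFrame(
        {
            "multiplex": multiplex.to_numpy(),
            "group": meta["liv_pm_status"].to_numpy(),
        },
        index=meta["sample_id"].to_numpy(),
    )
    return TmtMatrix(values=df, sample_info=sample_info)


def generate_junction_counts(
    meta: pd.DataFrame, config: SimulationConfig, truth_out: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Per-sample BED-like junction tables with clustered multinomial usage.

    Each true cluster is a star of introns sharing one start coordinate on a
    synthetic contig (0-based half-open), so clustered introns always share
    an endpoint. Per sample, a negative-binomial cluster total is split
    multinomially by the group's usage vector. Shifted clusters use a cyclic
    rotation of the LIV usage vector for PM samples. Decoy introns exercise
    the downstream filters: low-contribution decoys carry ~3% of cluster
    reads; high-zero-rate decoys are zeroed in a fraction of samples.
    """
    rng = config.rng(4)
    lo, hi = config.introns_per_cluster
    samples = meta["sample_id"].tolist()
    is_pm = meta["liv_pm_status"].to_numpy() == "PM"
    intron_rows = []  # (name, contig, start, end, strand, cluster)
    usage_by_cluster = {}
    n_shift = int(round(config.usage_shift_fraction * config.n_clusters))
    shifted = set(rng.choice(config.n_clusters, size=n_shift, replace=False).tolist())
    n_low = int(round(config.low_contrib_decoy_fraction * config.n_clusters))
    low_decoy = set(rng.choice(config.n_clusters, size=n_low, replace=False).tolist())
    n_zero = int(round(config.high_zero_decoy_fraction * config.n_clusters))
    zero_decoy = set(rng.choice(config.n_clusters, size=n_zero, replace=False).tolist())

    count_blocks = []
    zero_decoy_names = []
    for c in range(config.n_clusters):
        k = int(rng.integers(lo, hi + 1))
        start = 100_000 * (c + 1)
        strand = "+" if c % 2 == 0 else "-"
        ends = start + 100 + 150 * np.arange(k)
        usage_liv = rng.dirichlet(np.full(k, 3.0))
        usage_pm = np.roll(usage_liv, 1) if c in shifted else usage_liv.copy()
        names = [f"clu{c + 1:04d}_i{j + 1}" for j in range(k)]
        if c in low_decoy:
            k += 1
            ends = np.append(ends, start + 100 + 150 * k + 37)
            usage_liv = np.append(usage_liv * (1 - config.decoy_contribution), config.decoy_contribution)
            usage_pm = np.append(usage_pm * (1 - config.decoy_contribution), config.decoy_contribution)
            names.append(f"clu{c + 1:04d}_decoyLC")
            truth_out.decoy_introns.setdefault("low_contribution", []).append(names[-1])
        if c in zero_decoy:
            k += 1
            ends = np.append(ends, start + 100 + 150 * k + 73)
            usage_liv = np.append(usage_liv * 0.9, 0.1)
            usage_pm = np.append(usage_pm * 0.9, 0.1)
            names.append(f"clu{c + 1:04d}_decoyHZ")
            zero_decoy_names.append(names[-1])
            truth_out.decoy_introns.setdefault("high_zero_rate", []).append(names[-1])
        for j, name in enumerate(names):
            intron_rows.append((name, "chrS", start, int(ends[j]), strand, f"clu{c + 1:04d}"))
        totals = _nb_sample(rng, np.full(len(samples), config.cluster_depth), config.dispersion)
        counts = np.empty((k, len(samples)), dtype=int)
        for s in range(len(samples)):
            p = usage_pm if is_pm[s] else usage_liv
            counts[:, s] = rng.multinomial(totals[s], p)
        count_blocks.append(counts)
        usage_by_cluster[f"clu{c + 1:04d}"] = (usage_liv, usage_pm)

    introns = pd.DataFrame(
        intron_rows, columns=["name", "contig", "start", "end", "strand", "cluster"]
    ).set_index("name")
    counts = pd.DataFrame(np.vstack(count_blocks), index=introns.index, columns=samples)
    if zero_decoy_names:
        drop = rng.uniform(size=(len(zero_decoy_names), len(samples))) < config.decoy_zero_rate
        counts.loc[zero_decoy_names] = counts.loc[zero_decoy_names].where(~drop, 0)

    truth_out.cluster_usage = usage_by_cluster
    tables = {}
    for s in samples:
        tables[s] = pd.DataFrame(
            {
                "contig": introns["contig"],
                "start": introns["start"],
                "end": introns["end"],
                "name": introns.index,
                "count": counts[s],
                "strand": introns["strand"],
            }
        ).reset_index(drop=True)
    return tables


def generate_gene_sets(config: SimulationConfig, truth_out: GroundTruth) -> dict[str, list[str]]:
    """Gene-set families over the synthetic gene universe.

    Produces families of varying size, including a few below the downstream
    >=10-member filter, and marks ~30% as truly enriched: enriched families
    draw 80% of their members from the affected-gene list, background
    families draw uniformly from all genes.
    """
    rng = config.rng(5)
    genes = [f"gene{j + 1:05d}" for j in range(config.n_genes)]
    affected = truth_out.affected_genes or genes[: max(1, config.n_genes // 4)]
    unaffected = [g for g in genes if g not in set(affected)] or genes
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        name = f"SET{i + 1:03d}"
        if i < max(2, config.n_gene_sets // 10):
            size = int(rng.integers(5, 10))  # exercises the >=10 filter
        else:
            size = int(rng.integers(10, 80))
        size = min(size, config.n_genes)
        enriched = rng.uniform() < 0.3
        if enriched:
            n_hit = min(int(round(0.8 * size)), len(affected))
            n_bg = min(size - n_hit, len(unaffected))
            members = list(rng.choice(affected, size=n_hit, replace=False)) + list(
                rng.choice(unaffected, size=n_bg, replace=False)
            )
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[name] = sorted(members)
        truth_out.gene_set_enriched[name] = bool(enriched)
    return sets


def generate_paired_residuals(
    n_rna: int,
    n_protein: int,
    n_liv: int,
    n_pm: int,
    n_diff_pairs: int = 0,
    n_stable_pairs: int = 0,
    corr: float = 0.8,
    seed: int = 0,
    truth_out: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired RNA/protein residual matrices for co-expression analyses.

    Background features are independent standard normals (exchangeable
    between groups). Each truly differentially co-expressed pair
    (rna_i, prot_i) has correlation +corr in LIV samples and -corr in PM
    samples; each stable pair (laid out after the differential ones) has
    correlation +corr in both groups. Returns (rna, protein, metadata).
    """
    if n_diff_pairs + n_stable_pairs > min(n_rna, n_protein):
        raise ValueError("more structured pairs than features")
    rng = np.random.default_rng([seed, 6])
    samples = [f"L{i + 1:03d}" for i in range(n_liv)] + [f"P{i + 1:03d}" for i in range(n_pm)]
    group = np.array(["LIV"] * n_liv + ["PM"] * n_pm)
    rna = rng.normal(size=(n_rna, len(samples)))
    prot = rng.normal(size=(n_protein, len(samples)))
    pairs = []
    for i in range(n_diff_pairs):
        sign = np.where(group == "LIV", 1.0, -1.0)
        shared = rna[i]
        prot[i] = sign * corr * shared + np.sqrt(1 - corr**2) * rng.normal(size=len(samples))
        pairs.append((f"rna{i + 1:04d}", f"prot{i + 1:04d}"))
    for j in range(n_diff_pairs, n_diff_pairs + n_stable_pairs):
        prot[j] = corr * rna[j] + np.sqrt(1 - corr**2) * rng.normal(size=len(samples))
    rna_df = pd.DataFrame(rna, index=[f"rna{i + 1:04d}" for i in range(n_rna)], columns=samples)
    prot_df = pd.DataFrame(
        prot, index=[f"prot{i + 1:04d}" for i in range(n_protein)], columns=samples
    )
    meta = pd.DataFrame({"sample_id": samples, "liv_pm_status": group})
    if truth_out is not None:
        truth_out.diffcoex_pairs = pairs
    return rna_df, prot_df, meta


def simulate_bundle(config: SimulationConfig | None = None) -> OmicsBundle:
    """Run every generator under one config and collect the results."""
    config = config or SimulationConfig()
    truth = GroundTruth()
    meta = generate_cohort(config)
    primary, mature = generate_rna_counts(meta, config, truth)
    protein = generate_protein_matrix(meta, config, truth)
    junctions = generate_junction_counts(meta, config, truth)
    gene_sets = generate_gene_sets(config, truth)
    return OmicsBundle(
        config=config,
        metadata=meta,
        primary_counts=primary,
        mature_counts=mature,
        protein=protein,
        junctions=junctions,
        gene_sets=gene_sets,
        truth=truth,
    )
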
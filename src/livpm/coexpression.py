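"""RNA-protein co-expression differences between LIV and PM samples.

Computes covariate-adjusted residual matrices for mature RNA and protein,
per-group Pearson correlation matrices with BH adjustment over all RNA x
protein tests, same-gene pair enrichment, the regression of same-gene
correlations on DE logFCs, the LIV-PM absolute correlation-difference
matrix with a half-split permutation empirical null, the differential
co-expression enrichment odds ratio OR = (a/b)/(c/d), and gene-set family
enrichment over the significant-in-either-group background.

The permutation null follows the half-split scheme: each permutation splits
the LIV samples in half and the PM samples in half, combines one half of
each into two mixed "random" groups, and recomputes the absolute
correlation difference; the empirical p-value for a pair (or for the
matrix mean) is the fraction of null values strictly greater than the
observed one, so its resolution is exactly 1/n_perm and p = 0 is possible
(an optional (1+k)/(1+N) correction is available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fisher_2x2, odds_ratio_from_counts

__all__ = [
    "PairedResiduals",
    "CorrelationResult",
    "DiffCoexResult",
    "compute_residuals",
    "correlate_groups",
    "same_gene_enrichment",
    "samegene_logfc_model",
    "permutation_diff_null",
    "diffcoex_enrichment",
    "family_enrichment",
]


@dataclass
class PairedResiduals:
    rna: pd.DataFrame
    protein: pd.DataFrame
    group: pd.Series  # per shared sample: LIV or PM

    def samples(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])


def _residualize(values: pd.DataFrame, meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """OLS residuals of each feature on the covariate design (plus intercept)."""
    cols, names = [np.ones(len(meta))], ["intercept"]
    for c in covariates:
        col = meta[c]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
            names.append(c)
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for kname in dummies.columns:
                cols.append(dummies[kname].to_numpy(float))
                names.append(f"{c}[{kname}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cc = np.corrcoef(X[:, 1:].T) if X.shape[1] > 2 else np.ones((1, 1))
        pair = "unknown"
        for i in range(cc.shape[0]):
            for j in range(i + 1, cc.shape[0]):
                if abs(cc[i, j]) > 0.999:
                    pair = f"{names[i + 1]} ~ {names[j + 1]}"
        raise ValueError(f"collinear covariates: {pair}")
    y = values.to_numpy(float)
    beta = y @ X @ np.linalg.inv(X.T @ X)
    return pd.DataFrame(y - beta @ X.T, index=values.index, columns=values.columns)


def compute_residuals(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    meta: pd.DataFrame,
    rna_covariates: list[str] | None = None,
    protein_covariates: list[str] | None = None,
) -> PairedResiduals:
    """Covariate-adjusted residuals on the samples shared by both matrices.

    Covariate lists are caller-supplied; the RNA preset for co-expression
    deliberately omits the neuronal-fraction covariate (cell-type effects
    cannot be removed from the protein side, so they are left in the RNA
    side as well).
    """
    shared = [s for s in rna.columns if s in set(protein.columns)]
    meta = meta.set_index("sample_id").loc[shared]
    rna_res = _residualize(rna[shared], meta, rna_covariates or [])
    prot_res = _residualize(protein[shared], meta, protein_covariates or [])
    return PairedResiduals(rna=rna_res, protein=prot_res, group=meta["liv_pm_status"])


def _corr_matrix(rna: np.ndarray, prot: np.ndarray) -> np.ndarray:
    """Pearson correlations between rna rows and protein rows (shared columns)."""
    a = rna - rna.mean(axis=1, keepdims=True)
    b = prot - prot.mean(axis=1, keepdims=True)
    a_norm = np.sqrt((a**2).sum(axis=1, keepdims=True))
    b_norm = np.sqrt((b**2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a @ b.T) / (a_norm * b_norm.T)
    return np.clip(r, -1.0, 1.0, out=r) if np.isfinite(r).all() else r


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    adjusted_p: pd.DataFrame
    n_samples: int


def correlate_groups(resid: PairedResiduals) -> dict[str, CorrelationResult]:
    """Per-group RNA x protein Pearson correlations with BH over all pairs."""
    out = {}
    for grp in ("LIV", "PM"):
        cols = resid.samples(grp)
        if len(cols) < 3:
            raise ValueError(f"group {grp} has fewer than 3 samples")
        n = len(cols)
        r = _corr_matrix(resid.rna[cols].to_numpy(), resid.protein[cols].to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p[np.isnan(r)] = np.nan
        p[np.isclose(np.abs(r), 1.0)] = 0.0
        adj = bh_adjust(p.ravel()).reshape(p.shape)
        idx, cols_p = resid.rna.index, resid.protein.index
        out[grp] = CorrelationResult(
            r=pd.DataFrame(r, index=idx, columns=cols_p),
            p=pd.DataFrame(p, index=idx, columns=cols_p),
            adjusted_p=pd.DataFrame(adj, index=idx, columns=cols_p),
            n_samples=n,
        )
    return out


def same_gene_mask(links: pd.DataFrame, rna_ids, protein_ids) -> pd.DataFrame:
    """Boolean RNA x protein matrix marking same-gene pairs.

    ``links`` has columns rna_id / protein_id, one row per same-gene pair.
    """
    mask = pd.DataFrame(False, index=rna_ids, columns=protein_ids)
    for _, row in links.iterrows():
        if row["rna_id"] in mask.index and row["protein_id"] in mask.columns:
            mask.loc[row["rna_id"], row["protein_id"]] = True
    return mask


def same_gene_enrichment(
    corr: CorrelationResult, links: pd.DataFrame, alpha: float = 0.05
):
    """One-sided Fisher test: are same-gene pairs enriched for
    positive-and-significant correlations?

    Significance uses the full-matrix adjusted p-values (computed before any
    same-gene subsetting). Returns the Fisher2x2 result; a fully saturated
    table (OR unbounded) reports an infinite odds ratio.
    """
    same = same_gene_mask(links, corr.r.index, corr.r.columns).to_numpy()
    pos_sig = (corr.r.to_numpy() > 0) & (corr.adjusted_p.to_numpy() < alpha)
    a = int((same & pos_sig).sum())
    b = int((same & ~pos_sig).sum())
    c = int((~same & pos_sig).sum())
    d = int((~same & ~pos_sig).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("degenerate margin in the same-gene 2x2 table")
    return fisher_2x2(a, b, c, d, alternative="greater")


def samegene_logfc_model(
    samegene_corr: dict[str, pd.Series],
    rna_logfc: pd.Series,
    protein_logfc: pd.Series,
) -> pd.DataFrame:
    """Per group: same-gene correlation ~ RNA logFC + protein logFC.

    ``samegene_corr`` maps group -> Series of same-gene correlation values
    indexed like the logFC series (one entry per same-gene pair). All four
    slope p-values (2 groups x 2 predictors) are Bonferroni-adjusted with a
    factor of exactly 4.
    """
    import statsmodels.api as sm

    rows = []
    for grp, corr in samegene_corr.items():
        shared = corr.index.intersection(rna_logfc.index).intersection(protein_logfc.index)
        if len(shared) < 3:
            raise ValueError(f"group {grp}: fewer than 3 same-gene pairs with logFCs")
        X = np.column_stack([rna_logfc.loc[shared], protein_logfc.loc[shared]])
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(shared)), X])) < 3:
            raise ValueError(f"group {grp}: degenerate (collinear or constant) predictors")
        fit = sm.OLS(corr.loc[shared].to_numpy(), sm.add_constant(X)).fit()
        for j, name in enumerate(("rna_logfc", "protein_logfc"), start=1):
            rows.append(
                {
                    "group": grp,
                    "predictor": name,
                    "coef": fit.params[j],
                    "t": fit.tvalues[j],
                    "p_value": fit.pvalues[j],
                }
            )
    res = pd.DataFrame(rows)
    res["adjusted_p"] = np.minimum(res["p_value"] * 4.0, 1.0)
    return res


@dataclass
class DiffCoexResult:
    observed_diff: pd.DataFrame
    empirical_p: pd.DataFrame | None
    mean_statistic: float
    mean_empirical_p: float | None
    n_perm: int
    null_means: np.ndarray = field(default=None, repr=False)


def _half_split(idx: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(idx)
    half = len(idx) // 2
    return perm[:half], perm[half:]


def permutation_diff_null(
    resid: PairedResiduals,
    n_perm: int = 10_000,
    seed: int = 0,
    scope: str = "per_pair",
    add_one: bool = False,
) -> DiffCoexResult:
    """Absolute correlation-difference matrix with a half-split null.

    Observed statistic: |corr_PM - corr_LIV| per RNA-protein pair, and its
    grand mean. Each of ``n_perm`` permutations splits both groups in half
    (floor/ceil for odd sizes, the larger LIV half joining the smaller PM
    half), forms two mixed groups, and recomputes the statistic. Empirical
    p-values are exceedance fractions (strictly greater; ties do not count).
    ``scope`` selects whether per-pair p-values are accumulated
    ("per_pair") or only the matrix-mean statistic ("matrix_mean"). One
    shared set of splits serves all pairs.
    """
    if scope not in ("per_pair", "matrix_mean"):
        raise ValueError(f"unknown scope {scope!r}")
    liv = np.array(resid.samples("LIV"))
    pm = np.array(resid.samples("PM"))
    if len(liv) < 4 or len(pm) < 4:
        raise ValueError("need >=4 samples per group to form non-empty halves")
    rna, prot = resid.rna, resid.protein
    r_liv = _corr_matrix(rna[list(liv)].to_numpy(), prot[list(liv)].to_numpy())
    r_pm = _corr_matrix(rna[list(pm)].to_numpy(), prot[list(pm)].to_numpy())
    observed = np.abs(r_pm - r_liv)
    obs_mean = float(np.nanmean(observed))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.shape, dtype=np.int64) if scope == "per_pair" else None
    null_means = np.empty(n_perm)
    rna_np, prot_np = rna.to_numpy(), prot.to_numpy()
    col_pos = {s: j for j, s in enumerate(rna.columns)}
    liv_pos = np.array([col_pos[s] for s in liv])
    pm_pos = np.array([col_pos[s] for s in pm])
    for b in range(n_perm):
        liv_a, liv_b = _half_split(liv_pos, rng)
        pm_a, pm_b = _half_split(pm_pos, rng)
        # larger LIV half (ceil) pairs with the smaller PM half (floor)
        set1 = np.concatenate([liv_b, pm_a])
        set2 = np.concatenate([liv_a, pm_b])
        r1 = _corr_matrix(rna_np[:, set1], prot_np[:, set1])
        r2 = _corr_matrix(rna_np[:, set2], prot_np[:, set2])
        null = np.abs(r1 - r2)
        null_means[b] = np.nanmean(null)
        if exceed is not None:
            exceed += null > observed
    denom = n_perm + 1 if add_one else n_perm
    offset = 1 if add_one else 0
    emp = None
    if exceed is not None:
        emp = pd.DataFrame(
            (exceed + offset) / denom, index=rna.index, columns=prot.index
        )
    mean_p = float((np.sum(null_means > obs_mean) + offset) / denom)
    return DiffCoexResult(
        observed_diff=pd.DataFrame(observed, index=rna.index, columns=prot.index),
        empirical_p=emp,
        mean_statistic=obs_mean,
        mean_empirical_p=mean_p,
        n_perm=n_perm,
        null_means=null_means,
    )


@dataclass
class EnrichmentCounts:
    a: int  # significant in either group AND differentially co-expressed
    b: int  # significant in either group, not differential
    c: int  # not significant in either group, differential
    d: int  # neither
    odds_ratio: float
    fisher_p: float
    percent_differential_of_significant: float
    flagged_zero_cell: bool = False


def enrichment_from_counts(a: int, b: int, c: int, d: int) -> EnrichmentCounts:
    """OR = (a/b)/(c/d) plus Fisher's exact p for the same 2x2 table."""
    flagged = min(a, b, c, d) == 0
    if flagged:
        from scipy.stats.contingency import odds_ratio as _cond_or

        orr = float(_cond_or([[a, b], [c, d]]).statistic)
    else:
        orr = odds_ratio_from_counts(a, b, c, d)
    fisher = fisher_2x2(a, b, c, d)
    pct = float(np.floor(1000.0 * a / (a + b) + 0.5) / 10.0) if a + b else np.nan
    return EnrichmentCounts(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=orr,
        fisher_p=fisher.p_value,
        percent_differential_of_significant=pct,
        flagged_zero_cell=flagged,
    )


def diffcoex_enrichment(
    diff: DiffCoexResult,
    corr: dict[str, CorrelationResult],
    alpha: float = 0.05,
) -> EnrichmentCounts:
    """Are pairs significantly correlated in either group enriched for being
    differentially co-expressed?

    Significance-in-either uses the within-group BH-adjusted p-values;
    differential uses the permutation empirical p-values, both at ``alpha``.
    """
    if diff.empirical_p is None:
        raise ValueError("diffcoex_enrichment needs per-pair empirical p-values")
    sig_either = (corr["LIV"].adjusted_p.to_numpy() < alpha) | (
        corr["PM"].adjusted_p.to_numpy() < alpha
    )
    differential = diff.empirical_p.to_numpy() < alpha
    a = int((sig_either & differential).sum())
    b = int((sig_either & ~differential).sum())
    c = int((~sig_either & differential).sum())
    d = int((~sig_either & ~differential).sum())
    return enrichment_from_counts(a, b, c, d)


def family_enrichment(
    diff: DiffCoexResult,
    corr: dict[str, CorrelationResult],
    protein_sets: dict[str, list[str]],
    min_set_size: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per protein-family Fisher enrichment of differential pairs.

    The background is the set of RNA-protein pairs significantly correlated
    in either group; set membership is decided by the protein member of the
    pair. Sets with fewer than ``min_set_size`` member proteins present in
    the data are skipped (reported with tested=False). P-values are
    BH-adjusted across tested sets.
    """
    sig_either = (corr["LIV"].adjusted_p < alpha) | (corr["PM"].adjusted_p < alpha)
    differential = diff.empirical_p < alpha
    background = sig_either.to_numpy()
    diff_np = differential.to_numpy()
    proteins = diff.empirical_p.columns
    rows = []
    for name, members in protein_sets.items():
        present = [p for p in members if p in set(proteins)]
        if len(present) < min_set_size:
            rows.append({"set": name, "tested": False, "reason": "fewer_than_min_proteins"})
            continue
        in_set = np.asarray(proteins.isin(present))[None, :] & np.ones(
            (len(diff.empirical_p.index), 1), dtype=bool
        )
        bg = background
        a = int((bg & diff_np & in_set).sum())
        b = int((bg & diff_np & ~in_set).sum())
        c = int((bg & ~diff_np & in_set).sum())
        d = int((bg & ~diff_np & ~in_set).sum())
        fisher = fisher_2x2(a, b, c, d)
        rows.append(
            {
                "set": name,
                "tested": True,
                "n_proteins": len(present),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": fisher.odds_ratio,
                "p_value": fisher.p_value,
            }
        )
    res = pd.DataFrame(rows)
    if "p_value" in res:
        res["adjusted_p"] = bh_adjust(res["p_value"]) if res["p_value"].notna().any() else np.nan
    return res
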
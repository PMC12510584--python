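"""Differential expression and differential splicing rate between LIV and PM.

Covers low-expression filtering, trimmed-mean (TMM) normalization to log2
counts-per-million, replicate-aware two-group differential expression for
primary RNA / mature RNA / protein with DEF classification (positive logFC =
higher in postmortem samples), Spearman signature comparison, and the joint
primary/mature interaction model for differential splicing rate: the two
count matrices are stacked long (for normalization factors) and joined wide
(two columns per sample, one per spliced status) and the per-gene
interaction between spliced status and LIV-PM status estimates the log2
difference in mature:primary ratio between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, ols_fit, percent_significant

__all__ = [
    "filter_low_expression",
    "tmm_norm_factors",
    "normalize_counts",
    "fit_de",
    "classify_and_summarize",
    "summarize_def_counts",
    "build_long_and_wide",
    "fit_splicing_rate",
    "compare_signatures",
    "three_level_overlap",
    "SignatureComparison",
]

LIV_DEF = "LIV_DEF"
PM_DEF = "PM_DEF"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


def filter_low_expression(
    abundance: pd.DataFrame, threshold: float = -5.0, log_base: float | None = None
) -> list:
    """Features whose log mean abundance is at or above the threshold.

    The mean of each feature's TPM-like abundances is taken across samples
    and log-transformed (natural log by default); features strictly below
    ``threshold`` are removed, so a feature at exactly exp(-5) survives.
    All-zero features have log mean -inf and are always removed.
    """
    if (abundance.to_numpy() < 0).any():
        raise ValueError("abundance values must be non-negative")
    mean = abundance.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        logmean = np.log(mean)
        if log_base is not None:
            logmean = logmean / np.log(log_base)
    keep = logmean >= threshold
    if not keep.any():
        warnings.warn("no features pass the low-expression filter", stacklevel=2)
    return list(abundance.index[keep])


def tmm_norm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.3, sum_trim: float = 0.05
) -> pd.Series:
    """Trimmed mean of M-values scaling factors, unit geometric mean.

    The reference sample is the one whose 75th percentile of count
    proportions is closest to the mean across samples. For every other
    sample the factor is the precision-weighted mean of gene-wise log2
    ratios (M values), after trimming the most extreme 30% of M values and
    5% of average-abundance (A) values on each side.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    q75 = np.array([np.quantile(y[:, s][y[:, s] > 0] / lib[s], 0.75) if (y[:, s] > 0).any() else 0 for s in range(y.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for s in range(y.shape[1]):
        if s == ref:
            continue
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 2:
            continue
        m = np.log2((ys[ok] / ns) / (yr[ok] / nr))
        a = 0.5 * np.log2((ys[ok] / ns) * (yr[ok] / nr))
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[s] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log2 counts-per-million with TMM effective library sizes.

    Returns (log2 CPM matrix, per-sample normalization factors). A 0.5
    offset stabilizes zeros: log2((count + 0.5) / (libsize * factor) * 1e6).
    """
    factors = tmm_norm_factors(counts)
    lib = counts.sum(axis=0) * factors
    logcpm = np.log2((counts + 0.5).div(lib, axis=1) * 1e6)
    return logcpm, factors


def _encode_design(meta: pd.DataFrame, trait: str, covariates: list[str]) -> np.ndarray:
    """Intercept + binary trait (second sorted level = 1) + covariates."""
    levels = sorted(meta[trait].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"trait {trait!r} must have exactly two levels, got {levels}")
    cols = [np.ones(len(meta)), (meta[trait].astype(str) == levels[1]).to_numpy(float)]
    for c in covariates:
        col = meta[c]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            cols.extend(dummies[k].to_numpy(float) for k in dummies.columns)
    return np.column_stack(cols)


def _average_replicates(
    values: pd.DataFrame, meta: pd.DataFrame, extra_keys: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate samples of one individual to their mean column.

    Numeric covariates are averaged, categorical ones take the first value
    (replicates share individual-level covariates by construction).
    """
    keys = ["individual_id"] + (extra_keys or [])
    meta = meta.reset_index(drop=True)
    grouped = meta.groupby(keys, sort=False)
    new_meta = []
    new_cols = {}
    for key, idx in grouped.indices.items():
        rows = meta.iloc[idx]
        rep = rows.iloc[0].copy()
        for c in rows.columns:
            if pd.api.types.is_numeric_dtype(rows[c]):
                rep[c] = rows[c].mean()
        name = "__".join(map(str, key)) if isinstance(key, tuple) else str(key)
        rep["sample_id"] = name
        new_meta.append(rep)
        new_cols[name] = values[rows["sample_id"]].mean(axis=1)
    return pd.DataFrame(new_cols), pd.DataFrame(new_meta).reset_index(drop=True)


def _finalize_signature(
    features, logfc, t, p, fdr: float
) -> pd.DataFrame:
    adj = bh_adjust(p)
    def_class = np.where(
        adj < fdr, np.where(np.asarray(logfc) < 0, LIV_DEF, PM_DEF), NOT_SIGNIFICANT
    )
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_statistic": t,
            "p_value": p,
            "adjusted_p": adj,
            "def_class": def_class,
        },
        index=pd.Index(features, name="feature"),
    )


def fit_de(
    norm: pd.DataFrame,
    meta: pd.DataFrame,
    trait: str = "liv_pm_status",
    covariates: list[str] | None = None,
    method: str = "auto",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on a normalized matrix.

    Replicate samples from one individual are handled either by a
    random-intercept linear mixed model per feature (``method="mixed"``,
    statsmodels MixedLM) or by averaging each individual's replicate columns
    before a vectorized OLS fit (``method="average"``; the default under
    ``method="auto"`` when replicates exist). Positive logFC means higher
    expression in the second sorted trait level (PM for LIV/PM labels).
    Returns a DESignature frame: logFC, t, p, BH-adjusted p and DEF class at
    the given FDR.
    """
    covariates = covariates or []
    meta = meta.set_index("sample_id").loc[norm.columns].rename_axis("sample_id").reset_index()
    if meta[trait].nunique() < 2:
        raise ValueError(f"trait {trait!r} is constant")
    variances = norm.var(axis=1)
    if (variances == 0).any():
        warnings.warn(
            f"excluding {(variances == 0).sum()} zero-variance features", stacklevel=2
        )
        norm = norm.loc[variances > 0]
    has_reps = meta["individual_id"].duplicated().any()
    if method == "auto":
        method = "average" if has_reps else "ols"
    if method == "average" and has_reps:
        norm, meta = _average_replicates(norm, meta)
    if method == "mixed" and has_reps:
        return _fit_de_mixed(norm, meta, trait, covariates, fdr)
    design = _encode_design(meta, trait, covariates)
    res = ols_fit(norm.to_numpy(), design)
    return _finalize_signature(norm.index, res.coef[:, 1], res.t[:, 1], res.p[:, 1], fdr)


def _fit_de_mixed(norm, meta, trait, covariates, fdr):
    import statsmodels.api as sm

    design = _encode_design(meta, trait, covariates)
    groups = meta["individual_id"].to_numpy()
    logfc, tstat, pval = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in range(norm.shape[0]):
            y = norm.iloc[f].to_numpy()
            fit = None
            for opt in ("bfgs", "powell", "cg"):
                try:
                    fit = sm.MixedLM(y, design, groups=groups).fit(reml=True, method=opt)
                    if np.isfinite(fit.fe_params[1]) and np.isfinite(fit.pvalues[1]):
                        break
                    fit = None
                except (np.linalg.LinAlgError, ValueError):
                    fit = None
            if fit is None:  # variance structure degenerate: plain OLS
                res = ols_fit(y[None, :], design)
                logfc.append(res.coef[0, 1])
                tstat.append(res.t[0, 1])
                pval.append(res.p[0, 1])
            else:
                logfc.append(fit.fe_params[1])
                tstat.append(fit.tvalues[1])
                pval.append(fit.pvalues[1])
    return _finalize_signature(norm.index, np.array(logfc), np.array(tstat), np.array(pval), fdr)


def summarize_def_counts(n_liv_def: int, n_pm_def: int, n_tested: int) -> dict:
    """Contingency summary from DEF counts: the printed-percentage arithmetic."""
    return {
        "n_liv_def": int(n_liv_def),
        "n_pm_def": int(n_pm_def),
        "n_not_significant": int(n_tested - n_liv_def - n_pm_def),
        "n_tested": int(n_tested),
        "percent_def": percent_significant(n_liv_def + n_pm_def, n_tested),
    }


def classify_and_summarize(signature: pd.DataFrame) -> dict:
    """Counts of LIV/PM DEFs and the integer percent of features that are DEFs."""
    counts = signature["def_class"].value_counts()
    return summarize_def_counts(
        counts.get(LIV_DEF, 0), counts.get(PM_DEF, 0), len(signature)
    )


def build_long_and_wide(
    primary: pd.DataFrame, mature: pd.DataFrame, meta: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stack primary/mature matrices long (2G x S) and join them wide (G x 2S).

    Only genes present in both matrices are used. Long-form rows are
    suffixed ``-Primary`` / ``-Mature``; wide-form columns are suffixed per
    sample. The returned wide metadata has one row per wide column with the
    source sample, a ``spliced`` indicator (1 = mature) and, when sample
    metadata is given, the sample's group and covariates.
    """
    shared = primary.index.intersection(mature.index)
    if len(shared) == 0:
        raise ValueError("primary and mature matrices share no features")
    samples = primary.columns.intersection(mature.columns)
    p = primary.loc[shared, samples]
    m = mature.loc[shared, samples]
    long = pd.concat(
        [p.rename(index=lambda g: f"{g}-Primary"), m.rename(index=lambda g: f"{g}-Mature")]
    )
    wide = pd.concat(
        [p.rename(columns=lambda s: f"{s}-Primary"), m.rename(columns=lambda s: f"{s}-Mature")],
        axis=1,
    )
    wide_meta = pd.DataFrame(
        {
            "column": list(wide.columns),
            "sample_id": [c.rsplit("-", 1)[0] for c in wide.columns],
            "spliced": [1 if c.endswith("-Mature") else 0 for c in wide.columns],
        }
    )
    if meta is not None:
        wide_meta = wide_meta.merge(meta, on="sample_id", how="left")
    return long, wide, wide_meta


def fit_splicing_rate(
    wide: pd.DataFrame,
    long_norm_factors: pd.Series,
    wide_meta: pd.DataFrame,
    trait: str = "liv_pm_status",
    covariates: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene spliced-status x LIV-PM interaction on the wide matrix.

    Normalization factors are computed once on the long form (one factor per
    original sample, paired primary+mature library size) and applied to both
    of a sample's wide columns. The interaction logFC is the log2 difference
    in mature:primary ratio, PM minus LIV: positive values mean PM samples
    have the higher splicing rate. Genes with zero counts throughout any
    (spliced x group) stratum are excluded and reported via a warning.
    Replicate columns of one individual (within spliced status) are averaged
    before the fit.
    """
    covariates = covariates or []
    wide_meta = wide_meta.set_index("column").loc[wide.columns].rename_axis("column").reset_index()
    sample_ids = wide_meta["sample_id"]
    lib_long = {
        s: wide[f"{s}-Primary"].sum() + wide[f"{s}-Mature"].sum() for s in sample_ids.unique()
    }
    eff_lib = np.array(
        [lib_long[s] * long_norm_factors[s] for s in sample_ids], dtype=float
    )
    logcpm = np.log2((wide + 0.5).div(eff_lib, axis=1) * 1e6)

    # degenerate strata: all-zero counts within a spliced x group cell
    groups = wide_meta[trait].astype(str).to_numpy()
    spliced = wide_meta["spliced"].to_numpy()
    bad = np.zeros(len(wide), dtype=bool)
    for sp in (0, 1):
        for g in np.unique(groups):
            cols = (spliced == sp) & (groups == g)
            bad |= (wide.loc[:, cols].sum(axis=1) == 0).to_numpy()
    if bad.any():
        warnings.warn(
            f"excluding {bad.sum()} genes with an all-zero spliced/group stratum",
            stacklevel=2,
        )
    logcpm = logcpm.loc[~bad]

    meta2 = wide_meta.rename(columns={"column": "sample_id", "sample_id": "individual_sample"})
    meta2["individual_id"] = wide_meta.get(
        "individual_id", pd.Series(sample_ids.to_numpy())
    ).to_numpy()
    if meta2["individual_id"].isna().any():
        meta2["individual_id"] = meta2["individual_sample"]
    if meta2.duplicated(subset=["individual_id", "spliced"]).any():
        logcpm, meta2 = _average_replicates(logcpm, meta2, extra_keys=["spliced"])

    design = _encode_design(meta2, trait, covariates)
    inter = design[:, 1] * meta2["spliced"].to_numpy(float)
    design = np.column_stack([design, meta2["spliced"].to_numpy(float), inter])
    res = ols_fit(logcpm.to_numpy(), design)
    j = design.shape[1] - 1
    adj = bh_adjust(res.p[:, j])
    direction = np.where(
        adj < fdr, np.where(res.coef[:, j] > 0, "PM_higher", "LIV_higher"), "NS"
    )
    return pd.DataFrame(
        {
            "interaction_logFC": res.coef[:, j],
            "t_statistic": res.t[:, j],
            "p_value": res.p[:, j],
            "adjusted_p": adj,
            "direction": direction,
        },
        index=pd.Index(logcpm.index, name="feature"),
    )


@dataclass
class SignatureComparison:
    spearman_rho: float
    p_value: float
    n_shared_features: int


def compare_signatures(a: pd.DataFrame, b: pd.DataFrame) -> SignatureComparison:
    """Spearman correlation of two DE signatures' logFC over shared features."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared features, got {len(shared)}")
    rho, p = sps.spearmanr(a.loc[shared, "logFC"], b.loc[shared, "logFC"])
    return SignatureComparison(float(rho), float(p), len(shared))


def three_level_overlap(
    primary_sig: pd.DataFrame,
    mature_sig: pd.DataFrame,
    splicing_sig: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-gene significance at the three levels and the union fraction.

    A gene counts toward the union if it is significant (adjusted p < fdr)
    in the primary DE, mature DE or splicing-rate analysis. The fraction is
    over genes present in all three results.
    """
    shared = primary_sig.index.intersection(mature_sig.index).intersection(splicing_sig.index)
    table = pd.DataFrame(
        {
            "primary_significant": primary_sig.loc[shared, "adjusted_p"] < fdr,
            "mature_significant": mature_sig.loc[shared, "adjusted_p"] < fdr,
            "splicing_significant": splicing_sig.loc[shared, "adjusted_p"] < fdr,
        },
        index=shared,
    )
    union = table.any(axis=1)
    frac = float(union.mean()) if len(table) else float("nan")
    return table, frac
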
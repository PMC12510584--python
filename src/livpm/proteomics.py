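"""TMT proteomics preprocessing: alignment, outlier scan, batch correction.

Works on log2 sample-to-reference ratio matrices (proteins x samples, NaN =
missing) with per-sample multiplex and LIV/PM group labels. The pipeline
order is fixed: sample median alignment -> inter-multiplex outlier scan ->
batch correction that preserves the group effect (missingness mask
untouched) -> >=50%-observed missingness filter -> final KNN imputation.

The batch correction fits, per protein, an additive model
``value ~ group + multiplex`` on the protein's observed cells and subtracts
only the centered multiplex component, so the LIV-PM effect (and residuals)
survive; this is an unshrunk analogue of reference ComBat-with-covariate
workflows. The outlier scan runs, per protein x multiplex, a Welch t-test
of the values inside the multiplex against those outside, transforms the
p-values as log(-log p), and blanks blocks whose transformed value falls
more than ``sd_threshold`` standard deviations from the median of all
transformed values (two-sided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TmtMatrix",
    "QcReport",
    "median_align",
    "inter_multiplex_outlier_scan",
    "missingness_filter",
    "batch_correct_preserving_group",
    "impute",
    "run_qc_pipeline",
]


@dataclass
class TmtMatrix:
    """Log2 sample/reference ratios with multiplex and group labels.

    ``values`` is proteins x samples with NaN marking missing cells;
    ``sample_info`` is indexed by sample id with ``multiplex`` and ``group``
    columns (reference channels are expected to be excluded upstream).
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_info.index]
        if missing:
            raise ValueError(f"samples without sample_info rows: {missing[:3]}")
        self.sample_info = self.sample_info.loc[self.values.columns]

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.values.isna()

    @property
    def missing_rate(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def copy(self) -> "TmtMatrix":
        return TmtMatrix(self.values.copy(), self.sample_info.copy())


@dataclass
class QcReport:
    removed_blocks: pd.DataFrame | None = None
    skipped_tests: int = 0
    per_protein_missing: pd.Series | None = None
    retained_proteins: list[str] | None = None
    batch_summary: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)


def median_align(m: TmtMatrix, target: float = 0.0) -> TmtMatrix:
    """Shift each sample so its observed median equals ``target``.

    The missingness mask is unchanged; a sample with no observed values is
    an error.
    """
    med = m.values.median(axis=0, skipna=True)
    if med.isna().any():
        bad = med.index[med.isna()][0]
        raise ValueError(f"sample {bad!r} has no observed values")
    return TmtMatrix(m.values.sub(med - target, axis=1), m.sample_info.copy())


def inter_multiplex_outlier_scan(
    m: TmtMatrix, sd_threshold: float = 4.0
) -> tuple[TmtMatrix, QcReport]:
    """Flag and blank outlying protein x multiplex blocks.

    Requires >=2 multiplexes. Per protein and multiplex, a Welch t-test
    compares observed values inside the multiplex with those outside
    (needing >=2 observations on each side); p-values are transformed to
    log(-log p) and blocks beyond ``sd_threshold`` SDs from the median of
    all transformed values (either side) are set to missing.
    """
    multiplexes = m.sample_info["multiplex"].unique()
    if len(multiplexes) < 2:
        raise ValueError("inter-multiplex outlier scan requires >=2 multiplexes")
    vals = m.values.to_numpy()
    pvals = {}
    skipped = 0
    for mux in multiplexes:
        inside_cols = (m.sample_info["multiplex"] == mux).to_numpy()
        inside, outside = vals[:, inside_cols], vals[:, ~inside_cols]
        n_in = np.sum(~np.isnan(inside), axis=1)
        n_out = np.sum(~np.isnan(outside), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_in, mean_out = np.nanmean(inside, axis=1), np.nanmean(outside, axis=1)
            var_in, var_out = np.nanvar(inside, axis=1, ddof=1), np.nanvar(outside, axis=1, ddof=1)
        se2 = var_in / n_in + var_out / n_out
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_in - mean_out) / np.sqrt(se2)
            df = se2**2 / (
                (var_in / n_in) ** 2 / (n_in - 1) + (var_out / n_out) ** 2 / (n_out - 1)
            )
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p[(n_in < 2) | (n_out < 2) | ~np.isfinite(t)] = np.nan
        skipped += int(np.sum((n_in >= 2) & (n_out >= 2) & ~np.isfinite(t)))
        pvals[mux] = p
    pmat = pd.DataFrame(pvals, index=m.values.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(-np.log(pmat.to_numpy()))
    finite = z[np.isfinite(z)]
    med, sd = np.median(finite), np.std(finite)
    flagged = np.abs(z - med) > sd_threshold * sd
    flagged |= np.isposinf(z)  # p ~ 0: infinitely far in the tail
    out = m.values.copy()
    blocks = []
    for j, mux in enumerate(pmat.columns):
        hit = pmat.index[flagged[:, j]]
        for prot in hit:
            cols = m.sample_info.index[m.sample_info["multiplex"] == mux]
            out.loc[prot, cols] = np.nan
            blocks.append({"protein": prot, "multiplex": mux, "p_value": pmat.loc[prot, mux]})
    report = QcReport(
        removed_blocks=pd.DataFrame(blocks, columns=["protein", "multiplex", "p_value"]),
        skipped_tests=skipped,
    )
    return TmtMatrix(out, m.sample_info.copy()), report


def missingness_filter(m: TmtMatrix, min_observed: float = 0.5) -> TmtMatrix:
    """Retain proteins observed in at least ``min_observed`` of samples."""
    obs = 1.0 - m.values.isna().mean(axis=1)
    return TmtMatrix(m.values.loc[obs >= min_observed], m.sample_info.copy())


def impute(m: TmtMatrix, k: int = 10) -> TmtMatrix:
    """Fill missing cells from the k most correlated proteins.

    Neighbor distance is correlation distance over shared observed samples;
    a missing cell takes the mean of the k nearest proteins' observed values
    in that sample. Observed cells are never modified. Proteins with no
    usable neighbor fall back to the protein's own mean (flagged via a
    warning).
    """
    vals = m.values.to_numpy(dtype=float)
    if not np.isnan(vals).any():
        return m.copy()
    corr = pd.DataFrame(vals.T).corr(min_periods=3).to_numpy()
    np.fill_diagonal(corr, -np.inf)
    out = vals.copy()
    fallback = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prot_means = np.nanmean(vals, axis=1)
    observed = ~np.isnan(vals)
    for i in np.where(np.isnan(vals).any(axis=1))[0]:
        order = np.argsort(-corr[i], kind="stable")
        order = order[np.isfinite(corr[i][order])]
        # shortlist of candidate donors; widened per-cell only when needed
        short = order[: max(4 * k, 40)]
        for s in np.where(np.isnan(vals[i]))[0]:
            donors = short[observed[short, s]][:k]
            if len(donors) < k:
                donors = order[observed[order, s]][:k]
            if len(donors):
                out[i, s] = np.mean(vals[donors, s])
            else:
                out[i, s] = prot_means[i]
                fallback += 1
    if fallback:
        warnings.warn(f"{fallback} cells imputed with the protein mean (no neighbors)", stacklevel=2)
    return TmtMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.sample_info.copy())


def batch_correct_preserving_group(m: TmtMatrix) -> tuple[TmtMatrix, dict]:
    """Remove additive multiplex effects while keeping the LIV-PM effect.

    Per protein, an additive OLS model ``value ~ group + multiplex`` is fit
    on that protein's observed cells, and only the (sample-weighted,
    centered) multiplex component is subtracted from the protein's row;
    group effect and residuals pass through, and the missingness mask is
    untouched. Fitting on observed cells keeps the batch estimates free of
    the attenuation a temporary imputation would introduce. A protein whose
    observations miss an entire multiplex gets no adjustment for that
    multiplex (its cells there are missing anyway).
    """
    info = m.sample_info
    group = pd.get_dummies(info["group"].astype(str), drop_first=True).to_numpy(float)
    mux = pd.get_dummies(info["multiplex"].astype(str), drop_first=True)
    design = np.column_stack([np.ones(len(info)), group, mux.to_numpy(float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "multiplex labels are perfectly collinear with the group label; "
            "the batch effect cannot be separated from the LIV-PM effect"
        )
    y = m.values.to_numpy()
    observed = ~np.isnan(y)
    mux_cols = slice(1 + group.shape[1], design.shape[1])
    batch_component = np.zeros_like(y)
    for i in range(y.shape[0]):
        obs = observed[i]
        if obs.sum() <= design.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(design[obs], y[i, obs], rcond=None)
        batch_component[i] = design[:, mux_cols] @ beta[mux_cols]
    batch_component -= batch_component.mean(axis=1, keepdims=True)
    corrected = y - batch_component  # NaNs stay NaN
    out = pd.DataFrame(corrected, index=m.values.index, columns=m.values.columns)
    summary = {
        "n_multiplexes": int(info["multiplex"].nunique()),
        "mean_abs_batch_shift": float(np.abs(batch_component).mean()),
    }
    return TmtMatrix(out, info.copy()), summary


def run_qc_pipeline(
    m: TmtMatrix, sd_threshold: float = 4.0, min_observed: float = 0.5, knn_k: int = 10
) -> tuple[TmtMatrix, QcReport]:
    """The fixed-order preprocessing pipeline with a stage-by-stage report."""
    report = QcReport()
    m = median_align(m)
    report.stages.append("median_align")
    m, scan = inter_multiplex_outlier_scan(m, sd_threshold=sd_threshold)
    report.removed_blocks = scan.removed_blocks
    report.skipped_tests = scan.skipped_tests
    report.stages.append("inter_multiplex_outlier_scan")
    m, batch_summary = batch_correct_preserving_group(m)
    report.batch_summary = batch_summary
    report.stages.append("batch_correct_preserving_group")
    report.per_protein_missing = m.values.isna().mean(axis=1)
    m = missingness_filter(m, min_observed=min_observed)
    report.retained_proteins = list(m.values.index)
    report.stages.append("missingness_filter")
    m = impute(m, k=knn_k)
    report.stages.append("impute")
    return m, report
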
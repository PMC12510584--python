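"""Intron clusters from junction counts: build, filter, prune, test.

An intron cluster is a set of introns that forms a connected graph when
introns are edges and intron start/stop coordinates are vertices: every
intron in a retained cluster shares a start or stop position with at least
one other intron in the cluster. Coordinates are 0-based half-open on
ingestion; introns on opposite strands never cluster together.

The pipeline mirrors a LeafCutter-style workflow: cluster construction with
read-support and span thresholds, per-intron zero-rate and contribution
filters, connectivity reassessment with subgraph pruning, group usage
summaries, and a per-cluster differential-usage test. The differential test
here is a chi-square (with seeded permutation fallback at low expected
counts) comparison of group usage vectors — deliberately simpler than the
Dirichlet-multinomial model used at full scale — applied under the same
eligibility rules (min_samples_per_intron / min_samples_per_group = 10, one
LIV sample retained per individual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, percent_significant

__all__ = [
    "IntronClusterSet",
    "read_junctions",
    "build_clusters",
    "filter_introns",
    "reassess_and_prune",
    "usage_ratios",
    "test_differential_usage",
    "summarize_usage_significance",
]

JUNCTION_COLUMNS = ["contig", "start", "end", "name", "count", "strand"]


@dataclass
class IntronClusterSet:
    """Cluster membership plus per-intron filter provenance.

    ``introns`` carries one row per intron (contig, start, end, strand);
    ``clusters`` maps cluster id -> list of intron ids; ``flags`` maps
    intron id -> removal reason (high_zero_rate, low_contribution,
    pruned_subgraph, size_filtered); ``removed_clusters`` maps cluster id ->
    reason.
    """

    introns: pd.DataFrame
    clusters: dict[str, list[str]] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    removed_clusters: dict[str, str] = field(default_factory=dict)

    def retained_introns(self, cluster: str) -> list[str]:
        return [i for i in self.clusters[cluster] if i not in self.flags]

    def copy(self) -> "IntronClusterSet":
        return IntronClusterSet(
            introns=self.introns.copy(),
            clusters={k: list(v) for k, v in self.clusters.items()},
            flags=dict(self.flags),
            removed_clusters=dict(self.removed_clusters),
        )


def read_junctions(paths: dict[str, "str | object"]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read per-sample BED-like junction files into one zero-filled matrix.

    ``paths`` maps sample id to a 6-column TSV (contig, start, end, name,
    count, strand; 0-based half-open). Intron identity is
    (contig, start, end, strand); introns absent from a sample get count 0.
    Returns (counts matrix introns x samples, intron table).
    """
    per_sample = {}
    for sample, path in paths.items():
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                names=JUNCTION_COLUMNS,
                header=None,
                comment="#",
                dtype={"contig": str, "strand": str},
            )
            if df[["start", "end", "count"]].isna().any().any():
                raise ValueError("non-numeric coordinate or count")
            df["start"] = df["start"].astype(int)
            df["end"] = df["end"].astype(int)
            df["count"] = df["count"].astype(int)
        except (ValueError, TypeError) as exc:
            line = _first_bad_line(path)
            raise ValueError(f"malformed junction row in {path} at line {line}: {exc}") from exc
        if (df["end"] <= df["start"]).any():
            line = int(df.index[df["end"] <= df["start"]][0]) + 1
            raise ValueError(f"malformed junction row in {path} at line {line}: end <= start")
        key = list(zip(df["contig"], df["start"], df["end"], df["strand"]))
        per_sample[sample] = pd.Series(df["count"].to_numpy(), index=pd.MultiIndex.from_tuples(key))
    counts = pd.DataFrame(per_sample).fillna(0).astype(int)
    counts.index.names = ["contig", "start", "end", "strand"]
    counts = counts.sort_index()
    introns = counts.index.to_frame(index=False)
    introns["name"] = [
        f"{c}:{s}-{e}:{st}" for c, s, e, st in zip(
            introns["contig"], introns["start"], introns["end"], introns["strand"]
        )
    ]
    counts.index = pd.Index(introns["name"], name="intron")
    return counts, introns.set_index("name")


def _first_bad_line(path) -> int:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    return i
                try:
                    int(parts[1]), int(parts[2]), int(parts[4])
                except ValueError:
                    return i
    except OSError:
        pass
    return -1


def _shared_endpoint_graph(introns: pd.DataFrame) -> nx.Graph:
    """Vertices are (contig, strand, position); each intron is an edge."""
    g = nx.Graph()
    for name, row in introns.iterrows():
        u = (row["contig"], row["strand"], int(row["start"]))
        v = (row["contig"], row["strand"], int(row["end"]))
        g.add_edge(u, v, name=name)
    return g


def _components_as_intron_sets(introns: pd.DataFrame) -> list[list[str]]:
    g = _shared_endpoint_graph(introns)
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append(sorted(data["name"] for _, _, data in sub.edges(data=True)))
    return comps


def build_clusters(
    counts: pd.DataFrame,
    introns: pd.DataFrame,
    min_cluster_reads: int = 50,
    max_span: int = 500_000,
    min_intron_len: int = 50,
) -> IntronClusterSet:
    """Connected components over the shared-endpoint graph.

    Introns shorter than ``min_intron_len`` or spanning more than
    ``max_span`` bases are excluded before clustering; clusters supported by
    fewer than ``min_cluster_reads`` total split reads (summed across all
    samples and member introns) are dropped.
    """
    span = introns["end"] - introns["start"]
    eligible = introns[(span >= min_intron_len) & (span <= max_span)]
    cs = IntronClusterSet(introns=introns.copy())
    total = counts.sum(axis=1)
    cid = 0
    for members in _components_as_intron_sets(eligible):
        cid += 1
        name = f"cluster{cid:05d}"
        if total.reindex(members).sum() < min_cluster_reads:
            cs.removed_clusters[name] = "low_read_support"
            continue
        cs.clusters[name] = members
    return cs


def filter_introns(
    clusters: IntronClusterSet,
    counts: pd.DataFrame,
    max_zero_fraction: float = 0.25,
    min_contribution: float = 0.05,
) -> IntronClusterSet:
    """Flag high-zero-rate and low-contribution introns.

    An intron is flagged if it has zero counts in at least
    ``max_zero_fraction`` of samples, or if its share of the cluster's total
    counts (both summed across all samples, computed before any removal) is
    strictly below ``min_contribution``. Zero-rate flags take precedence in
    the recorded provenance.
    """
    out = clusters.copy()
    zero_frac = (counts == 0).mean(axis=1)
    total = counts.sum(axis=1)
    for cname, members in out.clusters.items():
        cluster_total = total.reindex(members).sum()
        for intron in members:
            if zero_frac[intron] >= max_zero_fraction:
                out.flags[intron] = "high_zero_rate"
            elif cluster_total > 0 and total[intron] / cluster_total < min_contribution:
                out.flags[intron] = "low_contribution"
    return out


def reassess_and_prune(clusters: IntronClusterSet) -> IntronClusterSet:
    """Re-check connectivity after filtering, prune subgraphs, size-filter.

    Per cluster (over its retained introns): a single remaining edge removes
    the cluster; a still-connected graph is retained; a disconnected graph
    is decomposed into connected components — if every component has one
    intron the cluster is removed, otherwise all components of maximal
    intron count are retained (kept as separate clusters when tied) and
    smaller components are pruned. Finally only clusters of 2-10 introns
    survive. The procedure is idempotent.
    """
    out = IntronClusterSet(
        introns=clusters.introns.copy(),
        flags=dict(clusters.flags),
        removed_clusters=dict(clusters.removed_clusters),
    )
    for cname, members in clusters.clusters.items():
        retained = [i for i in members if i not in out.flags]
        if len(retained) <= 1:
            out.removed_clusters[cname] = "single_edge"
            continue
        comps = _components_as_intron_sets(clusters.introns.loc[retained])
        sizes = [len(c) for c in comps]
        if len(comps) > 1 and max(sizes) == 1:
            out.removed_clusters[cname] = "disconnected_singletons"
            continue
        best = max(sizes)
        keep = [c for c in comps if len(c) == best]
        for comp in comps:
            if len(comp) != best:
                for intron in comp:
                    out.flags[intron] = "pruned_subgraph"
        parts = {}
        if len(keep) == 1:
            parts[cname] = keep[0]
        else:
            for j, comp in enumerate(sorted(keep), start=1):
                parts[f"{cname}.{j}"] = comp
        for pname, comp in parts.items():
            if 2 <= len(comp) <= 10:
                out.clusters[pname] = comp
            else:
                out.removed_clusters[pname] = "size_filtered"
                for intron in comp:
                    out.flags[intron] = "size_filtered"
    return out


def usage_ratios(
    clusters: IntronClusterSet, counts: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-intron group mean counts, within-cluster usages, and usage ratio.

    Mean counts are taken separately over LIV and PM samples; usage is the
    intron's group mean divided by the cluster's summed group means; the
    usage ratio is the larger of the two group means over the smaller.
    Clusters with a zero total in one group get undefined ratios and a
    flag column.
    """
    meta = meta.set_index("sample_id")
    liv_cols = [s for s in counts.columns if meta.loc[s, "liv_pm_status"] == "LIV"]
    pm_cols = [s for s in counts.columns if meta.loc[s, "liv_pm_status"] == "PM"]
    rows = []
    for cname in clusters.clusters:
        members = clusters.retained_introns(cname)
        liv_means = counts.loc[members, liv_cols].mean(axis=1)
        pm_means = counts.loc[members, pm_cols].mean(axis=1)
        liv_tot, pm_tot = liv_means.sum(), pm_means.sum()
        undefined = liv_tot == 0 or pm_tot == 0
        for intron in members:
            lm, pm_ = liv_means[intron], pm_means[intron]
            if lm == pm_:
                higher, ratio = "tie", 1.0 if lm > 0 else np.nan
            elif lm > pm_:
                higher = "LIV"
                ratio = lm / pm_ if pm_ > 0 else np.inf
            else:
                higher = "PM"
                ratio = pm_ / lm if lm > 0 else np.inf
            rows.append(
                {
                    "cluster": cname,
                    "intron": intron,
                    "liv_mean_count": lm,
                    "pm_mean_count": pm_,
                    "liv_usage": lm / liv_tot if liv_tot > 0 else np.nan,
                    "pm_usage": pm_ / pm_tot if pm_tot > 0 else np.nan,
                    "usage_ratio": np.nan if undefined else ratio,
                    "higher_group": higher,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def _downsample_liv(meta: pd.DataFrame, rng: np.random.Generator) -> list[str]:
    """One sample per LIV individual (seeded random pick); all PM samples."""
    keep = []
    for ind, rows in meta.groupby("individual_id", sort=False):
        ids = rows["sample_id"].tolist()
        if rows["liv_pm_status"].iloc[0] == "LIV" and len(ids) > 1:
            keep.append(ids[rng.integers(len(ids))])
        else:
            keep.extend(ids)
    return keep


def test_differential_usage(
    clusters: IntronClusterSet,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_samples_per_intron: int = 10,
    min_samples_per_group: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster test of equal group usage vectors, BH-adjusted.

    LIV samples are first downsampled to one per individual (seeded). A
    cluster is eligible when each group has at least
    ``min_samples_per_group`` samples with cluster reads and every retained
    intron has nonzero counts in at least ``min_samples_per_intron``
    samples. The test is a chi-square on the 2 x k group-by-intron summed
    count table, falling back to a label-permutation chi-square when any
    expected count drops below 5. Ineligible clusters are reported untested
    with the reason.
    """
    rng = np.random.default_rng(seed)
    keep = _downsample_liv(meta, rng)
    counts = counts[[s for s in counts.columns if s in set(keep)]]
    meta = meta.set_index("sample_id").loc[counts.columns]
    group = (meta["liv_pm_status"] == "PM").to_numpy()

    rows = []
    for cname in sorted(clusters.clusters):
        members = clusters.retained_introns(cname)
        sub = counts.loc[members]
        cluster_tot = sub.sum(axis=0)
        n_liv = int(((cluster_tot > 0) & ~group).sum())
        n_pm = int(((cluster_tot > 0) & group).sum())
        reason = None
        if n_liv < min_samples_per_group or n_pm < min_samples_per_group:
            reason = "too_few_samples_per_group"
        elif ((sub > 0).sum(axis=1) < min_samples_per_intron).any():
            reason = "too_few_samples_per_intron"
        elif len(members) < 2:
            reason = "single_intron"
        if reason:
            rows.append({"cluster": cname, "p_value": np.nan, "tested": False, "reason": reason})
            continue
        table = np.vstack([sub.loc[:, ~group].sum(axis=1), sub.loc[:, group].sum(axis=1)])
        table = table[:, table.sum(axis=0) > 0]
        chi2, p, _, expected = sps.chi2_contingency(table)
        method = "chi2"
        if (expected < 5).any():
            method = "permutation"
            stat_obs = chi2
            exceed = 0
            arr = sub.to_numpy()
            for _ in range(n_perm):
                perm = rng.permutation(group)
                t = np.vstack([arr[:, ~perm].sum(axis=1), arr[:, perm].sum(axis=1)])
                t = t[:, t.sum(axis=0) > 0]
                with np.errstate(invalid="ignore"):
                    stat, _, _, _ = sps.chi2_contingency(t)
                if stat >= stat_obs:
                    exceed += 1
            p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {"cluster": cname, "p_value": p, "tested": True, "reason": method}
        )
    res = pd.DataFrame(rows)
    res["adjusted_p"] = bh_adjust(res["p_value"].where(res["tested"]))
    return res


def summarize_usage_significance(
    results: pd.DataFrame,
    clusters: IntronClusterSet | None = None,
    cluster_genes: dict[str, str] | None = None,
    fdr: float = 0.05,
) -> dict:
    """Percent of tested clusters (and introns/genes they cover) significant.

    Percentages are rounded to the nearest integer over the tested
    denominators. Intron and gene percentages require the cluster set and a
    cluster -> gene mapping respectively.
    """
    tested = results[results["tested"].astype(bool)]
    sig = tested[tested["adjusted_p"] < fdr]
    out = {
        "n_clusters_tested": len(tested),
        "n_clusters_significant": len(sig),
        "percent_clusters": percent_significant(len(sig), len(tested)) if len(tested) else np.nan,
    }
    if clusters is not None:
        n_introns = {c: len(clusters.retained_introns(c)) for c in clusters.clusters}
        tot = sum(n_introns.get(c, 0) for c in tested["cluster"])
        hit = sum(n_introns.get(c, 0) for c in sig["cluster"])
        out.update(
            n_introns_tested=tot,
            n_introns_significant=hit,
            percent_introns=percent_significant(hit, tot) if tot else np.nan,
        )
    if cluster_genes is not None:
        genes_tested = {cluster_genes[c] for c in tested["cluster"] if c in cluster_genes}
        genes_sig = {cluster_genes[c] for c in sig["cluster"] if c in cluster_genes}
        out.update(
            n_genes_tested=len(genes_tested),
            n_genes_significant=len(genes_sig),
            percent_genes=percent_significant(len(genes_sig), len(genes_tested))
            if genes_tested
            else np.nan,
        )
    return out
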
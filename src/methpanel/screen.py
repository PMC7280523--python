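"""Differential-methylation screening and hierarchical structure.

Candidate marker CpGs are selected by a per-CpG two-sided Wilcoxon-Mann-
Whitney test between response groups at raw p < alpha (no multiple-testing
correction by default, mirroring the original screening rule; a Benjamini-
Hochberg option is available), restricted to transcription start sites, and
organised by agglomerative clustering with the Manhattan metric and the
ward.D2 criterion. Sample-level clustering with the same metric recovers the
highly vs moderately methylated cohort structure.

ward.D2 note: SciPy's ``linkage(..., method="ward")`` applied to a
*precomputed* condensed dissimilarity matrix runs the Lance-Williams Ward
update on those dissimilarities, which is exactly R's ``hclust`` with
``method="ward.D2"`` when the same dissimilarities are supplied; the merge
height of two singletons equals their input (here Manhattan) distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .simulate import ReferenceSequence, SampleAnnotation


@dataclass
class Dendrogram:
    """A fitted hierarchy: SciPy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray
    labels: list
    metric: str = "cityblock"
    method: str = "ward"

    def cut_k(self, k: int) -> pd.Series:
        lab = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.labels, name="cluster")

    def cut_height(self, height: float) -> pd.Series:
        lab = fcluster(self.linkage_matrix, t=height, criterion="distance")
        return pd.Series(lab, index=self.labels, name="cluster")

    def to_nested_lists(self):
        """Serialize the merge tree as nested lists of leaf labels."""
        nodes: dict[int, object] = {i: self.labels[i] for i in range(len(self.labels))}
        n = len(self.labels)
        for i, (a, b, _h, _c) in enumerate(self.linkage_matrix):
            nodes[n + i] = [nodes.pop(int(a)), nodes.pop(int(b))]
        return nodes[n + len(self.linkage_matrix) - 1] if len(self.linkage_matrix) else self.labels


def _split_groups(betas: pd.DataFrame, ann: list[SampleAnnotation]) -> tuple[list[str], list[str]]:
    by_id = {a.sample_id: a.response for a in ann}
    pr = [s for s in betas.columns if by_id.get(s) == "PR"]
    sd = [s for s in betas.columns if by_id.get(s) == "SD"]
    if not pr or not sd:
        raise ValueError("both PR and SD samples are required")
    return pr, sd


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first sample) and p-value.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; tie-corrected normal approximation (without continuity
    correction) otherwise.
    """
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    res = mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def differential_cpgs(
    betas: pd.DataFrame,
    ann: list[SampleAnnotation],
    alpha: float = 0.01,
    min_per_group: int = 2,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-CpG two-group Wilcoxon-Mann-Whitney screen; significant rows only.

    Returns a DataFrame (chrom, pos, u_statistic, p_value, delta_beta, n_pr,
    n_sd) with p < alpha strictly. ``delta_beta`` is mean(PR) - mean(SD) over
    non-missing betas. CpGs with fewer than ``min_per_group`` non-missing
    values in either group are not tested. ``correction="bh"`` applies
    Benjamini-Hochberg to the tested p-values before thresholding; the default
    is no correction.
    """
    pr, sd = _split_groups(betas, ann)
    records = []
    for (chrom, pos), row in betas.iterrows():
        x = row[pr].dropna().to_numpy(float)
        y = row[sd].dropna().to_numpy(float)
        if len(x) < min_per_group or len(y) < min_per_group:
            continue
        u, p = mann_whitney(x, y)
        records.append((chrom, pos, u, p, float(x.mean() - y.mean()), len(x), len(y)))
    res = pd.DataFrame(
        records, columns=["chrom", "pos", "u_statistic", "p_value", "delta_beta", "n_pr", "n_sd"]
    )
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        if len(res):
            res["p_adjusted"] = multipletests(res["p_value"], method="fdr_bh")[1]
            return res[res["p_adjusted"] < alpha].reset_index(drop=True)
        res["p_adjusted"] = []
        return res
    if correction not in (None, "none"):
        raise ValueError(f"unknown correction {correction!r}")
    return res[res["p_value"] < alpha].reset_index(drop=True)


def filter_tss(results: pd.DataFrame, ref: ReferenceSequence, window: int = 1000) -> pd.DataFrame:
    """Keep CpGs within +/- ``window`` bp of a TSS; annotate the nearest gene."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if not len(ref.tss) or not len(results):
        return results.iloc[0:0].assign(gene=pd.Series(dtype=str), tss_distance=pd.Series(dtype=int))
    tss_pos = np.array([t.pos for t in ref.tss])
    order = np.argsort(tss_pos)
    tss_pos = tss_pos[order]
    genes = np.array([t.gene for t in ref.tss])[order]
    pos = results["pos"].to_numpy(int)
    idx = np.searchsorted(tss_pos, pos)
    best = np.empty(len(pos), dtype=int)
    dist = np.empty(len(pos), dtype=int)
    for i, p in enumerate(pos):
        cands = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(tss_pos)]
        j = min(cands, key=lambda j: abs(int(tss_pos[j]) - int(p)))
        best[i] = j
        dist[i] = abs(int(tss_pos[j]) - int(p))
    out = results.copy()
    out["gene"] = genes[best]
    out["tss_distance"] = dist
    keep = (results["chrom"] == ref.name).to_numpy() & (dist <= window)
    return out[keep].reset_index(drop=True)


def _impute_rows(m: pd.DataFrame) -> np.ndarray:
    """Median-impute missing entries per row (group-free)."""
    x = m.to_numpy(float)
    med = np.nanmedian(x, axis=1)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(x))
    x = x.copy()
    x[idx] = med[idx[0]]
    return x


def cluster_cpgs(betas: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering of CpGs (rows): Manhattan metric, ward.D2."""
    if len(betas) < 2:
        raise ValueError("need at least 2 CpGs to cluster")
    x = _impute_rows(betas)
    z = linkage(pdist(x, metric="cityblock"), method="ward")
    return Dendrogram(z, labels=list(betas.index))


def cluster_samples(
    betas: pd.DataFrame,
    ann: list[SampleAnnotation] | None = None,
    k: int = 2,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster samples (columns) with the same metric/linkage.

    Clusters are renumbered 1..k by descending mean beta (cluster 1 is the
    most methylated). Returns per-sample labels and a summary table with each
    cluster's mean beta and, when annotations are given, its PR/SD makeup.
    """
    if betas.shape[1] < k:
        raise ValueError("need at least k samples")
    x = _impute_rows(betas.T)
    if k == 1:
        labels = pd.Series(1, index=betas.columns, name="cluster")
    else:
        z = linkage(pdist(x, metric="cityblock"), method="ward")
        raw = fcluster(z, t=k, criterion="maxclust")
        means = {c: x[raw == c].mean() for c in np.unique(raw)}
        order = sorted(means, key=means.get, reverse=True)
        remap = {c: i + 1 for i, c in enumerate(order)}
        labels = pd.Series([remap[c] for c in raw], index=betas.columns, name="cluster")
    rows = []
    resp = {a.sample_id: a.response for a in ann} if ann else {}
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        row = {
            "cluster": c,
            "n": len(members),
            "mean_beta": float(np.nanmean(betas[members].to_numpy(float))),
        }
        if resp:
            row["n_pr"] = sum(resp.get(s) == "PR" for s in members)
            row["n_sd"] = sum(resp.get(s) == "SD" for s in members)
        rows.append(row)
    return labels, pd.DataFrame(rows)
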
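"""Cluster identity assignment and ECM-source scoring for scRNA-seq data.

Given a gene x cell count matrix with cluster labels, this module
normalizes counts (counts-per-10k, log1p), assigns each cluster an
identity from marker panels (a cluster hits an identity when at least
one panel gene's cluster mean exceeds that gene's grand mean across
clusters, with exclusion of all other panels' markers), scores ECM gene
expression per cluster on a tri-level "+/++/+++" scale relative to the
grand mean, and ranks genes between two clusters by log fold change.

"Average" in the tri-level scheme means the unweighted grand mean of
cluster means, so large clusters do not dominate; a cell-weighted
variant is available via ``weight_by_cells``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy.stats import ranksums
from sklearn.cluster import KMeans

from .reference import canonical_gene
from .simulate import IDENTITY_MARKERS
from .stats import bh_qvalues

IDENTITY_OUTCOMES = ("Epithelial", "Endothelial", "Fibroblast", "Immune", "Tumor")
SCORE_LEVELS = ("", "+", "++", "+++")


@dataclass(frozen=True)
class MarkerPanelSet:
    """Identity -> marker gene panels (uppercase HGNC symbols).

    Defaults follow the kidney tumor marker scheme: fibroblasts by
    PDGFRB/PDGFRA, epithelia by AQP1/AQP2/EPCAM, endothelia by
    PLVAP/PECAM1/CD34, immune cells by PTPRC, and tumor cells by
    CXCR4/VIM/KRT18/PAX8/PAX2/CA9/MME.  CD names are resolved through
    the packaged alias table on construction.
    """

    panels: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        (identity, genes) for identity, genes in IDENTITY_MARKERS.items()
    )

    def __post_init__(self) -> None:
        if len(self.panels) < 2:
            raise ValueError("need panels for at least 2 identities")
        for identity, genes in self.panels:
            if not genes:
                raise ValueError(f"empty marker panel for {identity!r}")

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str]]) -> "MarkerPanelSet":
        return cls(
            panels=tuple(
                (identity, tuple(canonical_gene(g) for g in genes))
                for identity, genes in mapping.items()
            )
        )

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.panels)


@dataclass(frozen=True)
class ScoreThresholds:
    """Tri-level score band edges, as multiples of the gene's grand mean.

    A cluster scores "" at or below ``t_plus`` x grand mean, "+" up to
    ``t_2plus``, "++" up to ``t_3plus`` and "+++" above that.  The bands
    (1x, 2x, 3x] are a documented reading of the above-average /
    2x-above-average scheme, which is ambiguous exactly at its 2x
    boundary; all three edges are configurable.
    """

    t_plus: float = 1.0
    t_2plus: float = 2.0
    t_3plus: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.t_plus < self.t_2plus < self.t_3plus:
            raise ValueError("thresholds must satisfy 0 < t_plus < t_2plus < t_3plus")


# ---------------------------------------------------------------------------

def normalize_counts(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Counts-per-10k per cell followed by log1p.

    Returns a new AnnData; the input is unchanged.  Cells with zero
    total counts are rejected.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("all-zero cell(s) in count matrix")
    norm = adata.copy()
    norm.X = sparse.csr_matrix(norm.X, dtype=np.float64)
    sc.pp.normalize_total(norm, target_sum=target_sum)
    sc.pp.log1p(norm)
    return norm


def cluster_means(
    adata: ad.AnnData, labels: pd.Series | str = "cluster"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster arithmetic mean per gene on the supplied matrix.

    ``labels`` may be a column name in ``adata.obs`` or a Series indexed
    by cell.  Returns ``(means, n_cells)`` with clusters as rows.
    """
    if isinstance(labels, str):
        if labels not in adata.obs:
            raise ValueError(f"no obs column {labels!r}")
        lab = adata.obs[labels]
    else:
        lab = labels.reindex(adata.obs_names)
    if lab.isna().any():
        raise ValueError("unlabeled cell(s)")
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    df = pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    grouped = df.groupby(np.asarray(lab.astype(str)), observed=True)
    means = grouped.mean()
    n_cells = grouped.size().rename("n_cells")
    return means, n_cells


def grand_means(
    means: pd.DataFrame,
    n_cells: pd.Series | None = None,
    weight_by_cells: bool = False,
) -> pd.Series:
    """Per-gene average across clusters (unweighted by default)."""
    if weight_by_cells:
        if n_cells is None:
            raise ValueError("cell-weighted grand mean needs n_cells")
        w = n_cells.reindex(means.index).to_numpy(dtype=float)
        return pd.Series(
            np.average(means.to_numpy(), axis=0, weights=w), index=means.columns
        )
    return means.mean(axis=0)


def assign_identity(
    means: pd.DataFrame,
    panels: MarkerPanelSet | None = None,
    n_cells: pd.Series | None = None,
    weight_by_cells: bool = False,
) -> pd.Series:
    """Assign one identity per cluster from marker panels.

    A cluster hits an identity when at least one of its panel genes has
    a cluster mean strictly above that gene's grand mean across
    clusters.  The identity is assigned only when exactly one identity
    is hit (so no marker of any other panel exceeds its grand mean);
    multiple hits yield "Ambiguous" and none yield "Unassigned" — both
    explicit outcomes, never dropped.
    """
    panels = panels or MarkerPanelSet()
    gm = grand_means(means, n_cells, weight_by_cells)
    out = {}
    for cluster in means.index:
        hits = []
        for identity, genes in panels.panels:
            present = [g for g in genes if g in means.columns]
            if any(means.loc[cluster, g] > gm[g] for g in present):
                hits.append(identity)
        if len(hits) == 1:
            out[cluster] = hits[0]
        elif hits:
            out[cluster] = "Ambiguous"
        else:
            out[cluster] = "Unassigned"
    return pd.Series(out, name="identity")


def score_ecm(
    means: pd.DataFrame,
    ecm_genes: list[str],
    thresholds: ScoreThresholds | None = None,
    n_cells: pd.Series | None = None,
    weight_by_cells: bool = False,
) -> pd.DataFrame:
    """Tri-level "+/++/+++" ECM expression scores per cluster.

    For gene g with grand mean m across clusters, a cluster scores ""
    at or below t_plus*m, "+" in (t_plus*m, t_2plus*m], "++" in
    (t_2plus*m, t_3plus*m], and "+++" above t_3plus*m.  A gene with zero
    grand mean scores "" everywhere, with a warning.
    """
    thresholds = thresholds or ScoreThresholds()
    missing = [g for g in ecm_genes if g not in means.columns]
    if missing:
        raise ValueError(f"ECM gene(s) absent from matrix: {missing}")
    gm = grand_means(means, n_cells, weight_by_cells)
    scores = pd.DataFrame("", index=means.index, columns=list(ecm_genes))
    for g in ecm_genes:
        m = gm[g]
        if m <= 0:
            warnings.warn(f"gene {g} has zero grand mean; scored blank")
            continue
        v = means[g]
        scores.loc[v > thresholds.t_plus * m, g] = "+"
        scores.loc[v > thresholds.t_2plus * m, g] = "++"
        scores.loc[v > thresholds.t_3plus * m, g] = "+++"
    return scores


def compare_clusters(
    adata: ad.AnnData,
    cluster_a: str,
    cluster_b: str,
    labels: pd.Series | str = "cluster",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank genes between two clusters, weighted by log fold change.

    Per gene: log2((mean_a + eps) / (mean_b + eps)) on the supplied
    (normalized) matrix, Wilcoxon rank-sum p-value on per-cell values,
    and BH q-values; sorted by |log2fc| descending.  If either cluster
    has fewer than 3 cells the p-values are reported as NaN but fold
    changes are still returned.
    """
    lab = adata.obs[labels] if isinstance(labels, str) else labels.reindex(adata.obs_names)
    lab = lab.astype(str)
    for c in (cluster_a, cluster_b):
        if not (lab == c).any():
            raise ValueError(f"cluster {c!r} not present")
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    A = X[np.asarray(lab == cluster_a)]
    B = X[np.asarray(lab == cluster_b)]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    if min(len(A), len(B)) < 3:
        pvals = np.full(X.shape[1], np.nan)
    else:
        pvals = np.array(
            [
                1.0 if np.array_equal(A[:, j], B[:, j]) and len(A) == len(B)
                else ranksums(A[:, j], B[:, j]).pvalue
                for j in range(X.shape[1])
            ]
        )
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
        }
    ).set_index("gene")
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out.sort_values("log2fc", key=np.abs, ascending=False)


def kmeans_clusters(adata: ad.AnnData, k: int, seed: int = 0) -> pd.Series:
    """Unsupervised k-means labels (Lloyd's algorithm, k-means++ init)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > adata.n_obs:
        raise ValueError("k exceeds the number of cells")
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return pd.Series(labels.astype(str), index=adata.obs_names, name="cluster")


def profile_clusters(
    adata_norm: ad.AnnData,
    ecm_genes: list[str],
    labels: pd.Series | str = "cluster",
    panels: MarkerPanelSet | None = None,
    thresholds: ScoreThresholds | None = None,
) -> pd.DataFrame:
    """Convenience: means -> identities -> tri-level ECM scores.

    Returns one row per cluster with ``n_cells``, ``identity`` and one
    score column per ECM gene.
    """
    means, n_cells = cluster_means(adata_norm, labels)
    identity = assign_identity(means, panels, n_cells)
    scores = score_ecm(means, ecm_genes, thresholds, n_cells)
    out = pd.concat([n_cells, identity, scores], axis=1)
    out.index.name = "cluster_id"
    return out
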
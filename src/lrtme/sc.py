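"""Composition, differential expression, diffusion maps, and
ligand-receptor interaction scoring on cluster-labeled expression data.

The substrate is an :class:`anndata.AnnData` with log2-normalized
expression in ``.X`` and per-cell annotations ``sample_id``, ``subtype``,
and ``cluster`` in ``.obs``.  Clustering itself (and batch correction) is
out of scope: cluster labels are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

REQUIRED_OBS = ("sample_id", "subtype", "cluster")


def validate_dataset(adata: ad.AnnData) -> None:
    for col in REQUIRED_OBS:
        if col not in adata.obs.columns:
            raise ValueError(f"dataset .obs is missing column {col!r}")
    if adata.var_names.duplicated().any():
        raise ValueError("gene names are not unique")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


def lognormalize(counts: np.ndarray, library_size: int = 1000) -> np.ndarray:
    """Scale each cell to a fixed library size and apply log2(x+1).

    With this convention a log2 fold change equals a difference of mean
    normalized values.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log2(counts / totals * library_size + 1.0)


def lognormalize_adata(adata: ad.AnnData, library_size: int = 1000) -> None:
    """Replace ``.X`` with the log2-normalized transform of itself,
    in place."""
    adata.X = lognormalize(_dense(adata.X), library_size)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def composition(
    adata: ad.AnnData, type_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-sample cell-type proportions.

    ``type_map`` maps each cluster label to a cell-type name (identity
    when omitted).  Returns a tidy frame with one row per (sample,
    cell_type): ``sample_id, subtype, cell_type, n_cells, proportion``;
    proportions within a sample sum to 1.
    """
    validate_dataset(adata)
    clusters = adata.obs["cluster"].astype(str)
    if type_map is None:
        type_map = {c: c for c in clusters.unique()}
    unmapped = sorted(set(clusters.unique()) - set(type_map))
    if unmapped:
        raise ValueError(f"unmapped clusters: {unmapped}")
    df = pd.DataFrame(
        {
            "sample_id": adata.obs["sample_id"].to_numpy(),
            "subtype": adata.obs["subtype"].to_numpy(),
            "cell_type": clusters.map(type_map).to_numpy(),
        }
    )
    counts = (
        df.groupby(["sample_id", "subtype", "cell_type"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    # Complete the grid so absent types appear with proportion 0.
    all_types = sorted(set(type_map.values()))
    samples = counts[["sample_id", "subtype"]].drop_duplicates()
    grid = samples.merge(pd.DataFrame({"cell_type": all_types}), how="cross")
    counts = grid.merge(
        counts, on=["sample_id", "subtype", "cell_type"], how="left"
    ).fillna({"n_cells": 0})
    counts["n_cells"] = counts["n_cells"].astype(int)
    totals = counts.groupby("sample_id")["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    return counts.sort_values(
        ["sample_id", "cell_type"], ignore_index=True
    )


def type_ratio(
    comp: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-sample ratio of two cell-type counts (e.g. naive B / GC B).

    A zero denominator yields an undefined (NaN, flagged) ratio; no
    pseudocount is applied.
    """
    for t in (numerator, denominator):
        if t not in set(comp["cell_type"]):
            raise ValueError(f"cell type {t!r} absent from composition table")
    wide = comp.pivot_table(
        index="sample_id", columns="cell_type", values="n_cells", fill_value=0
    )
    num = wide[numerator].astype(float)
    den = wide[denominator].astype(float)
    ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(
        {
            "sample_id": wide.index,
            "n_numerator": num.to_numpy(int),
            "n_denominator": den.to_numpy(int),
            "ratio": ratio,
            "defined": den.to_numpy() > 0,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    adata: ad.AnnData,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    test: str = "wilcoxon",
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression between two cell selections.

    The log2 fold change is ``mean(A) - mean(B)`` of the log2-normalized
    values; p-values come from a two-sided Wilcoxon rank-sum test
    (``test='wilcoxon'``, the single-cell convention) or Welch's t-test
    (``test='t'``), Benjamini-Hochberg corrected across all tested genes.
    A gene is flagged significant when ``q < q_threshold`` and
    ``|log2FC| >= lfc_threshold`` (the volcano-plot rule).
    """
    validate_dataset(adata)
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least 2 cells on each side")
    if test not in ("wilcoxon", "t"):
        raise ValueError("test must be 'wilcoxon' or 't'")
    A = _dense(adata.X[mask_a])
    B = _dense(adata.X[mask_b])
    genes = list(adata.var_names)
    lfc = A.mean(axis=0) - B.mean(axis=0)
    pvals = np.empty(len(genes))
    for j in range(len(genes)):
        a, b = A[:, j], B[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0  # identical constant values carry no evidence
            continue
        if test == "wilcoxon":
            pvals[j] = _ranksum_p(a, b)
        else:
            pvals[j] = stats.ttest_ind(a, b, equal_var=False)[1]
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "significant": (qvals < q_threshold)
            & (np.abs(lfc) >= lfc_threshold),
        }
    )


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of group assignments.

    Handles ties correctly (the null distribution of the Mann-Whitney U
    is built over all C(n, n_a) relabelings of the pooled sample), which
    the large-sample normal approximation does not for tiny groups.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    def u_stat(x, y):
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    observed = u_stat(a, b)
    center = na * (n - na) / 2.0
    count = 0
    total = 0
    idx = np.arange(n)
    for combo in combinations(idx, na):
        sel = np.zeros(n, bool)
        sel[list(combo)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - center) >= abs(observed - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def _ranksum_p(a: np.ndarray, b: np.ndarray, exact_limit: int = 3000) -> float:
    """Two-sided rank-sum p: exact enumeration when the number of group
    assignments is small, normal approximation with tie correction
    otherwise."""
    from math import comb

    if comb(a.size + b.size, a.size) <= exact_limit:
        return _exact_ranksum_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Diffusion map
# ---------------------------------------------------------------------------


@dataclass
class DiffusionEmbedding:
    """Diffusion-map coordinates: leading nontrivial right eigenvectors of
    the density-normalized transition operator, scaled by eigenvalue.

    ``coordinates[:, 1]`` is the "dimension 2 score".  Components are
    defined up to sign; :func:`diffusion_map` fixes each sign by positive
    correlation with the first alphabetical gene exceeding |r| > 0.1.
    """

    coordinates: np.ndarray  # cells x n_components
    eigenvalues: np.ndarray  # nonincreasing, trivial eigenvalue removed
    kernel_bandwidth: float

    def dimension_score(self, dimension: int) -> np.ndarray:
        """1-based index over nontrivial components (dimension 2 ->
        second column)."""
        return self.coordinates[:, dimension - 1]


def _normalized_kernel(
    X: np.ndarray, bandwidth: float, alpha: float
) -> np.ndarray:
    """Gaussian kernel on Euclidean distances with density normalization
    ``K / (q_i q_j)^alpha``."""
    d2 = np.square(np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1))
    K = np.exp(-d2 / (2.0 * bandwidth**2))
    if alpha > 0:
        q = K.sum(axis=1)
        K = K / np.outer(q, q) ** alpha
    return K


def transition_matrix(
    X: np.ndarray, bandwidth: float, alpha: float = 1.0
) -> np.ndarray:
    """Density-normalized diffusion transition matrix (rows sum to 1)."""
    K = _normalized_kernel(X, bandwidth, alpha)
    return K / K.sum(axis=1, keepdims=True)


def median_bandwidth(
    X: np.ndarray, max_cells: int = 500, seed: int = 0
) -> float:
    """Median nonzero pairwise distance over a (seeded) subsample."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_cells:
        X = X[rng.choice(X.shape[0], max_cells, replace=False)]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(
            "degenerate input: all cells identical, kernel is singular"
        )
    return float(np.median(vals))


def diffusion_map(
    adata: ad.AnnData,
    mask: np.ndarray | None = None,
    n_components: int = 2,
    bandwidth: float | None = None,
    alpha: float = 1.0,
    seed: int = 0,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of a cell selection.

    The transition operator is built on Euclidean distances in gene space
    with a Gaussian kernel (bandwidth defaulting to the median pairwise
    distance of a 500-cell subsample) and density normalization; the
    embedding consists of the leading nontrivial right eigenvectors scaled
    by their eigenvalues, the constant eigenvector being discarded.
    """
    mask = (
        np.ones(adata.n_obs, bool) if mask is None else np.asarray(mask, bool)
    )
    X = _dense(adata.X[mask])
    n = X.shape[0]
    if n < n_components + 2:
        raise ValueError(
            f"need at least {n_components + 2} cells, got {n}"
        )
    if bandwidth is None:
        bandwidth = median_bandwidth(X, seed=seed)

    # The transition matrix P = D^-1 K is similar to the symmetric
    # A = D^-1/2 K D^-1/2, so eigh applies and right eigenvectors of P are
    # D^-1/2 times the symmetric eigenvectors.
    K = _normalized_kernel(X, bandwidth, alpha)
    rows = K.sum(axis=1)
    A = K / np.sqrt(np.outer(rows, rows))
    eigvals, eigvecs = linalg.eigh(A)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    # Right eigenvectors of P from the symmetric problem.
    psi = eigvecs[:, order] / np.sqrt(rows)[:, None]
    # Drop the trivial (constant) leading eigenvector.
    lambdas = eigvals[1 : n_components + 1]
    coords = psi[:, 1 : n_components + 1] * lambdas[None, :]

    # Deterministic sign: positive correlation with the first alphabetical
    # gene whose correlation magnitude exceeds 0.1.
    gene_order = np.argsort(np.asarray(adata.var_names, dtype=object))
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if np.ptp(col) == 0:
            continue
        for gi in gene_order:
            g = X[:, gi]
            if np.ptp(g) == 0:
                continue
            r = np.corrcoef(g, col)[0, 1]
            if abs(r) > 0.1:
                if r < 0:
                    coords[:, k] = -col
                break
    return DiffusionEmbedding(
        coordinates=coords,
        eigenvalues=lambdas,
        kernel_bandwidth=float(bandwidth),
    )


def gene_dimension_correlation(
    adata: ad.AnnData,
    embedding: DiffusionEmbedding,
    dimension: int = 2,
    mask: np.ndarray | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate every gene with a diffusion-dimension score.

    Returns genes sorted by descending correlation (ties broken
    lexicographically); genes with zero variance have an undefined
    correlation and are reported with ``r = NaN``, sorted last.
    """
    mask = (
        np.ones(adata.n_obs, bool) if mask is None else np.asarray(mask, bool)
    )
    score = embedding.dimension_score(dimension)
    X = _dense(adata.X[mask])
    if X.shape[0] != score.shape[0]:
        raise ValueError("mask does not match the embedded cell set")
    if np.ptp(score) == 0:
        raise ValueError(f"dimension {dimension} score has zero variance")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rs = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        g = X[:, j]
        if np.ptp(g) == 0:
            continue
        if method == "pearson":
            rs[j] = stats.pearsonr(g, score)[0]
        else:
            rs[j] = stats.spearmanr(g, score)[0]
    out = pd.DataFrame(
        {"gene": list(adata.var_names), "r": rs, "defined": ~np.isnan(rs)}
    )
    out = out.sort_values(
        ["r", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Ligand-receptor interaction scoring
# ---------------------------------------------------------------------------


def interaction_scores(
    adata: ad.AnnData,
    pairs: Sequence[tuple[str, str]],
    sender_clusters: Sequence[str],
    receiver_clusters: Sequence[str],
    condition_col: str = "subtype",
    condition_a: Sequence[str] = ("LR",),
    condition_b: Sequence[str] = ("otherCHL",),
    n_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score ligand-receptor interactions between cell groups, per condition.

    For each (ligand, receptor) pair, the score under a condition is
    ``mean ligand expression over sender cells x mean receptor expression
    over receiver cells`` (cells restricted to that condition); ``delta``
    is score(A) - score(B), so a positive delta marks enrichment in
    condition A.  An optional permutation p-value shuffles condition
    labels over the sender/receiver cells (seeded).  Pairs whose genes are
    absent are skipped with a warning.
    """
    validate_dataset(adata)
    genes = {g: i for i, g in enumerate(adata.var_names)}
    obs = adata.obs
    in_a = obs[condition_col].isin(condition_a).to_numpy()
    in_b = obs[condition_col].isin(condition_b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError("both conditions must be populated")
    sender = obs["cluster"].isin(sender_clusters).to_numpy()
    receiver = obs["cluster"].isin(receiver_clusters).to_numpy()
    X = _dense(adata.X)
    rng = np.random.default_rng(seed)

    def score(ligand_ix, receptor_ix, cond_mask):
        s = cond_mask & sender
        r = cond_mask & receiver
        lig = X[s, ligand_ix].mean() if s.any() else 0.0
        rec = X[r, receptor_ix].mean() if r.any() else 0.0
        return float(lig * rec)

    rows = []
    involved = (sender | receiver) & (in_a | in_b)
    for ligand, receptor in pairs:
        if ligand not in genes or receptor not in genes:
            warnings.warn(
                f"skipping pair {ligand}->{receptor}: gene absent from dataset",
                stacklevel=2,
            )
            continue
        li, ri = genes[ligand], genes[receptor]
        s_a = score(li, ri, in_a)
        s_b = score(li, ri, in_b)
        delta = s_a - s_b
        perm_p = np.nan
        if n_permutations > 0:
            idx = np.flatnonzero(involved)
            labels_a = in_a[idx]
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(labels_a)
                pa = np.zeros_like(in_a)
                pa[idx] = perm
                pb = np.zeros_like(in_b)
                pb[idx] = ~perm
                d = score(li, ri, pa) - score(li, ri, pb)
                if abs(d) >= abs(delta):
                    count += 1
            perm_p = (count + 1) / (n_permutations + 1)
        rows.append(
            dict(
                ligand=ligand,
                receptor=receptor,
                score_a=s_a,
                score_b=s_b,
                delta=delta,
                permutation_p=perm_p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "score_a", "score_b", "delta",
            "permutation_p",
        ],
    )
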
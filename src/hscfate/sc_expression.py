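"""Single-cell expression QC, normalization, module scores, and LR-test DE.

Works on :class:`anndata.AnnData` objects (cells x genes, raw integer
counts in ``X``) carrying per-cell metadata columns ``total_reads``,
``mito_fraction`` and ``ercc_fraction`` in ``obs``.

The QC gate keeps cells with 50,000-750,000 total reads, <10% mitochondrial
reads and <10% ERCC spike-in contribution; genes with <=400 reads across all
retained cells (and configured contaminants) are dropped. Normalization is
per-cell depth scaling to the median depth followed by log1p — a deliberate,
deterministic stand-in for variance-stabilizing transforms, with the
mitochondrial fraction instead entering the differential test as a
covariate.

Differential expression between two cell groups uses a logistic-regression
likelihood-ratio test: for each gene, group membership is regressed on
normalized expression plus the mitochondrial fraction, against the
covariate-only null; the LR statistic is referred to chi-square(1) and
BH-adjusted across genes.

Module scores are per-cell gene-set means relative to expression-matched
control genes drawn from mean-expression bins (seeded), the standard
signature-scoring construction for proliferation/quiescence sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from anndata import AnnData
from scipy.stats import chi2

from ._stats import bh_adjust

QC_MIN_READS = 50_000
QC_MAX_READS = 750_000
QC_MAX_MITO = 0.10
QC_MAX_ERCC = 0.10
GENE_MIN_TOTAL_READS = 400  # genes with totals <= this are removed
DEFAULT_CONTAMINANTS = ("CT010467.1",)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_filter(
    adata: AnnData,
    min_reads: int = QC_MIN_READS,
    max_reads: int = QC_MAX_READS,
    max_mito: float = QC_MAX_MITO,
    max_ercc: float = QC_MAX_ERCC,
) -> tuple[AnnData, pd.DataFrame]:
    """Cell-level QC gate; returns (retained cells, rejection log).

    A cell is retained iff min_reads <= total_reads <= max_reads AND
    mito_fraction < max_mito AND ercc_fraction < max_ercc (both strict).
    The rejection log has one row per removed cell listing every failed
    clause.
    """
    obs = adata.obs
    reads = obs["total_reads"].to_numpy()
    mito = obs["mito_fraction"].to_numpy()
    ercc = obs["ercc_fraction"].to_numpy()
    clauses = {
        "low_reads": reads < min_reads,
        "high_reads": reads > max_reads,
        "high_mito": mito >= max_mito,
        "high_ercc": ercc >= max_ercc,
    }
    failed = np.zeros(adata.n_obs, dtype=bool)
    for mask in clauses.values():
        failed |= mask
    log_rows = []
    for i in np.flatnonzero(failed):
        reasons = [name for name, mask in clauses.items() if mask[i]]
        log_rows.append({"cell_id": adata.obs_names[i], "failed": ";".join(reasons)})
    rejection_log = pd.DataFrame(log_rows, columns=["cell_id", "failed"])
    return adata[~failed].copy(), rejection_log


def gene_filter(
    adata: AnnData,
    min_total: int = GENE_MIN_TOTAL_READS,
    contaminants: tuple[str, ...] = DEFAULT_CONTAMINANTS,
) -> AnnData:
    """Drop contaminant genes, then genes with <= min_total reads overall."""
    keep_name = ~adata.var_names.isin(contaminants)
    adata = adata[:, keep_name]
    totals = np.asarray(adata.X.sum(axis=0)).ravel()
    return adata[:, totals > min_total].copy()


def normalize(adata: AnnData, target_sum: float | None = None) -> AnnData:
    """Per-cell depth normalization to a common target, then log1p.

    ``target_sum`` defaults to the median cell depth. Stores the result in
    ``layers['lognorm']`` and returns the (copied) object.
    """
    X = _dense(adata.X).astype(float)
    depths = X.sum(axis=1)
    if np.any(depths == 0):
        raise ValueError("zero-depth cell encountered; run qc_filter first")
    if target_sum is None:
        target_sum = float(np.median(depths))
    out = adata.copy()
    out.layers["lognorm"] = np.log1p(X * (target_sum / depths)[:, None])
    out.uns["normalize_target_sum"] = target_sum
    return out


def module_score(
    adata: AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.Series:
    """Per-cell gene-set score vs expression-matched controls.

    Genes are binned into ``n_bins`` equal-size bins of mean expression;
    for each bin containing set genes, up to ``n_ctrl`` control genes are
    drawn (seeded, without replacement) from the bin's non-set genes. The
    score is mean(set expression) - mean(control expression) per cell. Set
    genes absent from the matrix are dropped with a warning; an empty
    effective set is an error.
    """
    X = np.asarray(adata.layers[layer])
    names = pd.Index(adata.var_names)
    present = [g for g in gene_set if g in names]
    dropped = set(gene_set) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} gene-set genes absent from matrix; dropped",
                      stacklevel=2)
    if not present:
        raise ValueError("empty effective gene set")
    set_idx = names.get_indexer(present)
    gene_means = X.mean(axis=0)
    # equal-occupancy bins on mean expression (rank-based)
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(len(names), dtype=int)
    bins[order] = np.arange(len(names)) * n_bins // len(names)
    rng = np.random.default_rng(seed)
    set_mask = np.zeros(len(names), dtype=bool)
    set_mask[set_idx] = True
    ctrl_idx: list[np.ndarray] = []
    for b in np.unique(bins[set_idx]):
        pool = np.flatnonzero((bins == b) & ~set_mask)
        if pool.size == 0:
            pool = np.flatnonzero(bins == b)
            warnings.warn(f"bin {b} has no non-set genes; controls overlap set",
                          stacklevel=2)
        take = min(n_ctrl, pool.size)
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.concatenate(ctrl_idx)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_score")


def _logit_llf(y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """Maximized log-likelihood of a logistic regression; (llf, converged)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # perfect separation: refit with a whisper of L2 to get a
            # finite, near-saturated likelihood
            res = model.fit_regularized(disp=0, alpha=1e-6, L1_wt=0.0, maxiter=500)
            converged = False
    return float(res.llf), converged


def differential_expression_lr(
    adata: AnnData,
    group_col: str,
    group_a: str,
    group_b: str,
    covariate_col: str = "mito_fraction",
    layer: str = "lognorm",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Logistic-regression LR-test differential expression between two groups.

    Per gene: LR = 2*(llf{expr + covariate} - llf{covariate only}), p from
    chi-square(1), BH across genes. log2FC is the log2 ratio of group mean
    normalized expressions with a pseudocount. Genes whose full fit did not
    converge (separation) are flagged in the ``flag`` column.
    """
    labels = adata.obs[group_col].astype(str)
    mask = labels.isin([group_a, group_b]).to_numpy()
    if mask.sum() < adata.n_obs:
        adata = adata[mask]
        labels = labels[mask]
    y = (labels == group_a).to_numpy(dtype=float)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    X = np.asarray(adata.layers[layer])
    cov = adata.obs[covariate_col].to_numpy(dtype=float)
    if np.std(cov) == 0:  # constant covariate would make the design singular
        base = np.ones((len(cov), 1))
    else:
        base = np.column_stack([np.ones_like(cov), cov])
    llf_null, _ = _logit_llf(y, base)
    in_a = y.astype(bool)
    mean_a = X[in_a].mean(axis=0)
    mean_b = X[~in_a].mean(axis=0)
    rows = []
    for j, gene in enumerate(adata.var_names):
        expr = X[:, j]
        if expr.std() == 0:
            rows.append((gene, 0.0, 1.0, ""))
            continue
        llf_full, converged = _logit_llf(y, np.column_stack([base, expr]))
        stat = max(0.0, 2.0 * (llf_full - llf_null))
        p = float(chi2.sf(stat, df=1))
        rows.append((gene, stat, p, "" if converged else "separation"))
    out = pd.DataFrame(rows, columns=["gene", "lr_stat", "p", "flag"])
    out["log2FC"] = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny)
    out["p_adj"] = bh_adjust(out["p"])
    return out[["gene", "log2FC", "lr_stat", "p", "p_adj", "flag"]]


def significant_genes(deg: pd.DataFrame, p_adj: float = 0.01,
                      min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Apply the reporting thresholds (p_adj < 0.01 and |log2FC| > 1)."""
    return deg[(deg["p_adj"] < p_adj) & (deg["log2FC"].abs() > min_abs_log2fc)]


def variable_genes_and_pcs(
    adata: AnnData, n_hvg: int = 3000, n_pcs: int = 10, layer: str = "lognorm"
) -> dict:
    """Dispersion-ranked variable genes and a deterministic PCA.

    Top ``n_hvg`` genes by variance/mean dispersion of the normalized
    values, z-scored, then SVD. Sign convention: each component's largest-
    magnitude gene loading is made positive. Returns a dict with ``coords``
    (cells x n_pcs), ``loadings``, ``hvg`` names and ``explained_variance_ratio``.
    """
    X = np.asarray(adata.layers[layer])
    if adata.n_obs < n_pcs:
        raise ValueError("need at least n_pcs cells")
    means = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, var / means, 0.0)
    if n_hvg > X.shape[1]:
        warnings.warn("fewer genes than n_hvg; using all genes", stacklevel=2)
        n_hvg = X.shape[1]
    hvg_idx = np.sort(np.argsort(dispersion, kind="stable")[::-1][:n_hvg])
    Xh = X[:, hvg_idx]
    sd = Xh.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xh - Xh.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    signs = np.sign(Vt[np.arange(n_pcs), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    total_var = (S**2).sum() if S.size else 1.0
    all_sq = np.linalg.norm(Z) ** 2
    return {
        "coords": U * S * signs,
        "loadings": (Vt.T * signs),
        "hvg": adata.var_names[hvg_idx].to_list(),
        "explained_variance_ratio": (S**2) / (all_sq if all_sq > 0 else 1.0),
    }
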
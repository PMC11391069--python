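"""Chromatin-accessibility analysis for ATAC-seq peak count matrices.

The pipeline mirrors a bulk ATAC-seq workflow on sorted stem/progenitor
populations: sample QC by fraction of reads in peaks (FRiP >= 10%),
Tn5-insertion read-position correction (+4/-5 bp), normalization to 1e6
reads in peaks, an FPKM-based presence rule (a region is "found" in a
population when more than 5 FPKM in at least a third of its samples),
log10 + quantile normalization for visualization/clustering, a
negative-binomial Wald test for differential accessibility, hierarchical
clustering of differential regions, the derivation of lineage-bias DARs
(lineage-contrast DARs minus aging-associated DARs), PWM motif scanning
with a one-sided binomial enrichment test, and nearest-gene annotation.

The differential test is a from-scratch DESeq2-style analysis: size
factors by median-of-ratios, per-region NB dispersion by maximum
likelihood shrunk toward a log-linear mean-dispersion trend, and a
two-group NB GLM with log link and library-size offsets fitted by IRLS
(vectorized across regions); the Wald z of the group coefficient gives
two-sided normal p-values, BH-adjusted per contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from scipy.stats import norm, rankdata

from ._stats import bh_adjust, binomial_tail_p

FRIP_MIN = 0.10
FPKM_PRESENCE_MIN = 5.0  # strict: "more than 5"
PRESENCE_FRACTION = 1 / 3
DEFAULT_P_ADJ_AGING = 1e-4
DEFAULT_P_ADJ_SUBSET = 0.05
MOTIF_SCORE_FRACTION = 0.8
PWM_PSEUDOCOUNT = 0.25

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# sample QC, read shifting, normalization
# ---------------------------------------------------------------------------

def frip_filter(sample_meta: pd.DataFrame, min_frip: float = FRIP_MIN) -> pd.DataFrame:
    """Drop poor-quality samples (FRiP below 10%)."""
    retained = sample_meta[sample_meta["frip"] >= min_frip]
    if retained.empty:
        raise ValueError("no samples survive the FRiP filter")
    return retained


def tn5_shift(fragments: pd.DataFrame) -> pd.DataFrame:
    """Correct read positions for the Tn5 insertion offset.

    Plus-strand intervals have their start moved +4 bp; minus-strand
    intervals their end moved -5 bp. Records whose interval collapses
    (end <= start) are dropped and counted in ``attrs['n_dropped']``.
    Refuses to run twice on the same frame (``attrs['tn5_shifted']`` guard).
    """
    if fragments.attrs.get("tn5_shifted"):
        raise ValueError("fragments already Tn5-shifted; refusing to re-apply")
    out = fragments.copy()
    plus = out["strand"] == "+"
    out.loc[plus, "start"] += 4
    out.loc[~plus, "end"] -= 5
    valid = out["end"] > out["start"]
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records collapsed by the shift",
                      stacklevel=2)
    out = out[valid].reset_index(drop=True)
    out.attrs["tn5_shifted"] = True
    out.attrs["n_dropped"] = n_dropped
    return out


def normalize_counts(counts: pd.DataFrame, reads_in_peaks: pd.Series) -> pd.DataFrame:
    """Scale each sample column to 1e6 mapped reads in peaks."""
    rip = reads_in_peaks.reindex(counts.columns)
    if rip.isna().any() or (rip <= 0).any():
        raise ValueError("every sample needs a positive reads_in_peaks")
    return counts * (1e6 / rip)


def fpkm(counts: pd.DataFrame, region_lengths_bp: pd.Series,
         reads_in_peaks: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of region per million reads in peaks."""
    lengths_kb = region_lengths_bp.reindex(counts.index) / 1000.0
    if (lengths_kb <= 0).any():
        raise ValueError("region lengths must be positive")
    per_million = normalize_counts(counts, reads_in_peaks)
    return per_million.div(lengths_kb, axis=0)


def presence_filter(
    counts: pd.DataFrame,
    region_lengths_bp: pd.Series,
    sample_meta: pd.DataFrame,
    population_col: str = "population",
    min_fpkm: float = FPKM_PRESENCE_MIN,
    fraction: float = PRESENCE_FRACTION,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-population found flags and the retained region set.

    A region is found in a population when strictly more than ``min_fpkm``
    FPKM is observed in at least ceil(fraction * n_samples) of that
    population's samples. Regions found in no population are dropped.
    Returns (found_in boolean frame regions x populations, retained index).
    """
    rip = sample_meta.set_index("sample_id")["reads_in_peaks"]
    values = fpkm(counts, region_lengths_bp, rip)
    found = {}
    for pop, sub in sample_meta.groupby(population_col, sort=True):
        cols = [s for s in sub["sample_id"] if s in values.columns]
        if not cols:
            raise ValueError(f"population {pop} has no samples in the matrix")
        need = math.ceil(fraction * len(cols))
        found[pop] = (values[cols] > min_fpkm).sum(axis=1) >= need
    found_in = pd.DataFrame(found, index=counts.index)
    retained = found_in.index[found_in.any(axis=1)]
    return found_in, retained


def log_quantile_normalize(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(x + pseudocount) then quantile-normalize columns (ties averaged).

    After normalization every column shares the same sorted value
    distribution: the mean of the columns' sorted log values.
    """
    logged = np.log10(matrix.to_numpy(dtype=float) + pseudocount)
    reference = np.sort(logged, axis=0).mean(axis=1)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        ranks = rankdata(logged[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, logged.shape[0] + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# negative-binomial Wald differential accessibility
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame, reads_in_peaks: pd.Series | None = None,
                 min_regions: int = 50) -> pd.Series:
    """Median-of-ratios size factors; reads-in-peaks fallback.

    Uses regions with nonzero counts in every sample; when fewer than
    ``min_regions`` such regions exist, falls back to scaling by reads in
    peaks (normalized to geometric mean 1).
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if positive.sum() >= min_regions:
        logX = np.log(X[positive])
        log_geo = logX.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logX - log_geo, axis=0))
    else:
        if reads_in_peaks is None:
            raise ValueError(
                "too few all-positive regions for median-of-ratios and no "
                "reads_in_peaks fallback provided"
            )
        rip = reads_in_peaks.reindex(counts.columns).to_numpy(dtype=float)
        sf = rip / np.exp(np.mean(np.log(rip)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik_grid(Y: np.ndarray, mu: np.ndarray, alphas: np.ndarray,
                    group_masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Adjusted profile NB log-likelihood per region over an alpha grid.

    When ``group_masks`` is given, the Cox-Reid adjustment
    -0.5 log det(X'WX) for the group-means design is subtracted, removing
    the downward bias of plugging in estimated means (one fitted mean per
    group costs half a log-weight-mass term).
    """
    R, S = Y.shape
    out = np.empty((R, len(alphas)))
    mu = np.maximum(mu, 1e-8)
    for k, a in enumerate(alphas):
        r = 1.0 / a
        ll = (
            gammaln(Y + r) - gammaln(r) - gammaln(Y + 1)
            + r * np.log(r / (r + mu))
            + Y * np.log(mu / (r + mu))
        ).sum(axis=1)
        if group_masks is not None:
            w = mu / (1.0 + a * mu)
            for mask in group_masks:
                ll -= 0.5 * np.log(np.maximum(w[:, mask].sum(axis=1), 1e-12))
        out[:, k] = ll
    return out


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    shrink_weight: float = 0.5,
    alpha_min: float = 1e-8,
    alpha_max: float = 100.0,
) -> pd.DataFrame:
    """Per-region NB dispersion: grid MLE shrunk toward a mean trend.

    The per-region Cox-Reid adjusted profile likelihood (group means
    fitted by normalized averages) is maximized over a log-spaced alpha
    grid; log alpha is then shrunk with weight ``shrink_weight`` toward a
    log-linear regression of log alpha on log mean normalized count,
    fitted over regions whose likelihood peaks inside the grid.
    """
    Y = counts.to_numpy(dtype=float)
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    norm_counts = Y / s
    mu = np.zeros_like(Y)
    group_masks = []
    for g in groups.unique():
        cols = (groups == g).to_numpy()
        mu[:, cols] = norm_counts[:, cols].mean(axis=1, keepdims=True) * s[cols]
        group_masks.append(cols)
    alphas = np.exp(np.linspace(np.log(alpha_min), np.log(alpha_max), 80))
    loglik = _nb_loglik_grid(Y, mu, alphas, group_masks)
    best = loglik.argmax(axis=1)
    log_alpha = np.log(alphas)[best]
    # quadratic refinement on interior grid points
    interior = (best > 0) & (best < len(alphas) - 1)
    if interior.any():
        i = best[interior]
        l0 = loglik[interior, i - 1]
        l1 = loglik[interior, i]
        l2 = loglik[interior, i + 1]
        denom = l0 - 2 * l1 + l2
        step = np.log(alphas[1]) - np.log(alphas[0])
        shift = np.where(denom < 0, 0.5 * (l0 - l2) / denom, 0.0)
        log_alpha[interior] = np.log(alphas)[i] + np.clip(shift, -1, 1) * step
    mean_norm = norm_counts.mean(axis=1)
    # trend over informative regions only: positive mean and an interior
    # likelihood peak (boundary MLEs carry no dispersion information)
    usable = (mean_norm > 0) & interior
    if usable.sum() >= 10:
        x = np.log(mean_norm[usable])
        coef = np.polyfit(x, log_alpha[usable], deg=1)
        trend = np.polyval(coef, np.log(np.maximum(mean_norm, 1e-8)))
    else:
        fill = np.median(log_alpha[interior]) if interior.any() else np.median(log_alpha)
        trend = np.full_like(log_alpha, fill)
    shrunk = (1 - shrink_weight) * log_alpha + shrink_weight * trend
    # boundary peaks carry no dispersion information (flat likelihood):
    # the trend is the whole estimate there
    shrunk = np.where(interior, shrunk, trend)
    # one-sided moderation: a handful of samples cannot establish that a
    # region is *less* dispersed than its peers, so the final estimate is
    # floored at the trend; letting chance below-trend MLEs through makes
    # the Wald tails anticonservative
    shrunk = np.maximum(shrunk, trend)
    return pd.DataFrame(
        {
            "mean_norm_count": mean_norm,
            "alpha_mle": np.exp(log_alpha),
            "alpha": np.clip(np.exp(shrunk), alpha_min, alpha_max),
        },
        index=counts.index,
    )


def nb_wald(
    Y: np.ndarray,
    group_indicator: np.ndarray,
    offsets: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict:
    """Vectorized two-group NB GLM Wald test across regions.

    Fits log mu_ij = beta0_i + beta1_i * x_j + offset_j per region by IRLS
    (x is the group indicator) with fixed per-region dispersion ``alpha``.
    Returns coefficient, standard error, Wald z, two-sided p and a
    convergence flag (non-converged regions get p = 1).
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(group_indicator, dtype=float)
    o = np.asarray(offsets, dtype=float)
    a = np.asarray(alpha, dtype=float)[:, None]
    R = Y.shape[0]
    in_a = x.astype(bool)
    eps = 1e-8
    mean_a = (Y[:, in_a] / np.exp(o[in_a])).mean(axis=1)
    mean_b = (Y[:, ~in_a] / np.exp(o[~in_a])).mean(axis=1)
    b0 = np.log(np.maximum(mean_b, eps))
    b1 = np.log(np.maximum(mean_a, eps)) - b0
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + o[None, :]
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        w = mu / (1.0 + a * mu)
        z = (eta - o[None, :]) + (Y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swx - swx**2  # = sum_A(w) * sum_B(w) for binary x
        det = np.where(det <= 0, np.nan, det)
        new_b1 = (sw * swxz - swx * swz) / det
        new_b0 = (swz - swx * new_b1) / sw
        delta = np.nanmax(
            np.abs(np.column_stack([new_b0 - b0, new_b1 - b1])), axis=1
        )
        b0, b1 = new_b0, new_b1
        converged |= delta < tol
        if converged.all():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :] + o[None, :]
    mu = np.clip(np.exp(eta), 1e-10, 1e12)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sw / det)
        zstat = b1 / se
    bad = ~np.isfinite(zstat) | ~converged
    zstat = np.where(bad, 0.0, zstat)
    p = 2.0 * norm.sf(np.abs(zstat))
    p = np.where(bad, 1.0, p)
    return {"coef": b1, "se": se, "z": zstat, "p": p, "converged": ~bad}


def dar_test(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    group_a: dict,
    group_b: dict,
    found_in: pd.DataFrame | None = None,
    shrink_weight: float = 0.5,
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential accessibility between two sample groups (A vs B).

    ``group_a`` / ``group_b`` select samples by metadata equality, e.g.
    ``{"population": "CD49b-", "age_group": "O"}``. log2FC is log2(A / B).
    Regions not found in either compared population (per ``found_in``
    columns named by the groups' populations) are excluded before testing,
    as are all-zero regions. BH adjustment runs across the tested regions
    of this contrast only.
    """

    def _select(spec: dict) -> list:
        mask = np.ones(len(sample_meta), dtype=bool)
        for key, val in spec.items():
            mask &= (sample_meta[key] == val).to_numpy()
        return sample_meta.loc[mask, "sample_id"].tolist()

    cols_a, cols_b = _select(group_a), _select(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    sub = counts[cols_a + cols_b]
    keep = sub.index
    if found_in is not None:
        sel = sample_meta["sample_id"].isin(cols_a + cols_b)
        pops = sorted(set(sample_meta.loc[sel, "population"])) \
            if "population" in sample_meta else []
        pops = [p for p in pops if p in found_in.columns]
        if pops:
            keep = keep[found_in.loc[keep, pops].any(axis=1)]
    keep = keep[sub.loc[keep].sum(axis=1) > 0]
    sub = sub.loc[keep]
    if sf is None:
        rip = None
        if "reads_in_peaks" in sample_meta:
            rip = sample_meta.set_index("sample_id")["reads_in_peaks"]
        sf = size_factors(sub, reads_in_peaks=rip)
    sf = sf.reindex(sub.columns)
    group_labels = pd.Series(
        ["A"] * len(cols_a) + ["B"] * len(cols_b), index=sub.columns
    )
    if dispersion is None:
        disp_table = estimate_dispersions(sub, sf, group_labels,
                                          shrink_weight=shrink_weight)
        alpha = disp_table["alpha"].to_numpy()
        mean_norm = disp_table["mean_norm_count"].to_numpy()
    else:
        alpha = dispersion.reindex(sub.index).to_numpy()
        mean_norm = (sub / sf).mean(axis=1).to_numpy()
    res = nb_wald(
        sub.to_numpy(dtype=float),
        np.array([1.0] * len(cols_a) + [0.0] * len(cols_b)),
        np.log(sf.to_numpy(dtype=float)),
        alpha,
    )
    log2fc = res["coef"] / math.log(2)
    out = pd.DataFrame(
        {
            "mean_norm_count": mean_norm,
            "log2FC": log2fc,
            "wald_z": res["z"],
            "p": res["p"],
            "p_adj": bh_adjust(res["p"]),
            "direction": np.where(log2fc >= 0, "up", "down"),
            "converged": res["converged"],
            "alpha": alpha,
        },
        index=sub.index,
    )
    out.index.name = "region_id"
    return out


def significant_regions(dar: pd.DataFrame, p_adj: float) -> pd.Index:
    """Region ids passing the contrast's adjusted-p threshold."""
    return dar.index[dar["p_adj"] < p_adj]


# ---------------------------------------------------------------------------
# clustering, open fractions, overlap, Lin DARs
# ---------------------------------------------------------------------------

def cluster_dars(
    matrix: pd.DataFrame,
    k: int,
    sample_groups: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Hierarchical clustering of differential regions.

    Rows (regions) are z-scored; distance is 1 - Pearson correlation;
    average linkage; the tree is cut at ``k`` clusters. Cluster labels are
    renumbered 1..k in order of first appearance (input order tie-break).
    Zero-variance rows cannot enter the correlation distance and are
    assigned post hoc to the cluster with the nearest mean profile
    (Euclidean on the raw matrix). Returns (labels, per-cluster median
    accessibility by sample group if ``sample_groups`` given).
    """
    if len(matrix) < k:
        raise ValueError("fewer regions than clusters requested")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    variable = sd > 0
    if k > variable.sum():
        raise ValueError("not enough variable regions for k clusters")
    Z = (X[variable] - X[variable].mean(axis=1, keepdims=True)) / sd[variable][:, None]
    if variable.sum() == 1:
        raw = np.array([1])
    else:
        link = average(pdist(Z, metric="correlation"))
        raw = fcluster(link, t=k, criterion="maxclust")
    # deterministic renumbering by first appearance
    remap, labels_var = {}, np.empty_like(raw)
    for i, c in enumerate(raw):
        labels_var[i] = remap.setdefault(c, len(remap) + 1)
    labels = np.zeros(len(matrix), dtype=int)
    labels[variable] = labels_var
    if (~variable).any():
        centroids = np.vstack(
            [X[variable][labels_var == c].mean(axis=0)
             for c in range(1, len(remap) + 1)]
        )
        for i in np.flatnonzero(~variable):
            labels[i] = 1 + np.argmin(
                np.linalg.norm(centroids - X[i][None, :], axis=1)
            )
    labels = pd.Series(labels, index=matrix.index, name="cluster")
    medians = None
    if sample_groups is not None:
        rows = {}
        for c in sorted(labels.unique()):
            sub = matrix.loc[labels == c]
            rows[c] = {
                g: float(np.median(sub[cols.index[cols].tolist()].to_numpy()))
                for g, cols in (
                    (g, sample_groups == g) for g in sample_groups.unique()
                )
            }
        medians = pd.DataFrame(rows).T.rename_axis("cluster")
    return labels, medians


def open_fraction(labels: pd.Series, found_in: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each cluster's regions called open per population."""
    out = {}
    for c in sorted(labels.unique()):
        regions = labels.index[labels == c]
        if len(regions) == 0:
            raise ValueError(f"empty cluster {c}")
        out[c] = 100.0 * found_in.loc[regions].mean(axis=0)
    return pd.DataFrame(out).T.rename_axis("cluster")


def aging_overlap(dar_a: pd.DataFrame, dar_b: pd.DataFrame,
                  p_adj: float = DEFAULT_P_ADJ_AGING) -> dict:
    """Venn counts of two DAR contrasts on the same region universe.

    Shared regions are partitioned by direction concordance. Requires both
    tables to come from the same region universe (intersection of tested
    regions is used; disjoint universes are an error).
    """
    if len(dar_a.index.intersection(dar_b.index)) == 0:
        raise ValueError("DAR tables share no regions: mismatched universes")
    sig_a = set(significant_regions(dar_a, p_adj))
    sig_b = set(significant_regions(dar_b, p_adj))
    shared = sig_a & sig_b
    concordant = {
        r for r in shared
        if dar_a.loc[r, "direction"] == dar_b.loc[r, "direction"]
    }
    return {
        "n_only_a": len(sig_a - sig_b),
        "n_only_b": len(sig_b - sig_a),
        "n_shared": len(shared),
        "shared_concordant": sorted(concordant),
        "shared_discordant": sorted(shared - concordant),
        "only_a": sorted(sig_a - sig_b),
        "only_b": sorted(sig_b - sig_a),
    }


def lin_dars(
    lineage_dar: pd.DataFrame,
    aging_dars: list[pd.DataFrame],
    lineage_p_adj: float = DEFAULT_P_ADJ_SUBSET,
    aging_p_adj: float = DEFAULT_P_ADJ_AGING,
    mode: str = "union",
) -> pd.Index:
    """Lineage-bias DARs: lineage-contrast DARs minus aging-associated DARs.

    The lineage contrast compares the most lymphoid-biased with the most
    myeloid-biased population across ages; regions also differential in
    either within-subset aging contrast (``mode='union'``, default) or in
    all of them (``mode='intersection'``) are filtered out.
    """
    lineage_sig = set(significant_regions(lineage_dar, lineage_p_adj))
    if not lineage_sig:
        warnings.warn("empty lineage DAR set", stacklevel=2)
        return pd.Index([])
    aging_sets = [set(significant_regions(d, aging_p_adj)) for d in aging_dars]
    if not aging_sets:
        aging = set()
    elif mode == "union":
        aging = set().union(*aging_sets)
    elif mode == "intersection":
        aging = set.intersection(*aging_sets)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = [r for r in lineage_dar.index if r in lineage_sig - aging]
    return pd.Index(kept)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    p_binomial: float
    neg_ln_p: float
    flag: str = ""


def pwm_log_odds(pfm: np.ndarray, pseudocount: float = PWM_PSEUDOCOUNT) -> np.ndarray:
    """Log-odds matrix (4 x L) vs uniform background from a count/frequency PFM."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.shape[0] != 4:
        raise ValueError("PFM must be 4 x L (A,C,G,T rows)")
    probs = (pfm + pseudocount) / (pfm + pseudocount).sum(axis=0, keepdims=True)
    return np.log(probs / 0.25)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=int)


def _revcomp_lut(lut: np.ndarray) -> np.ndarray:
    # reverse positions, complement base rows; N row (log-odds 0) unchanged
    return lut[[3, 2, 1, 0, 4], ::-1]


def motif_scan(
    sequences: dict[str, str],
    pfm: np.ndarray,
    score_fraction: float = MOTIF_SCORE_FRACTION,
    pseudocount: float = PWM_PSEUDOCOUNT,
) -> pd.Series:
    """Boolean per-region motif hits by thresholded log-odds scanning.

    A region is a hit when any window, on either strand, scores at least
    ``score_fraction`` of the maximal possible log-odds. Ambiguous bases
    (N) contribute log-odds 0. Sequences shorter than the motif never hit.
    """
    lo = pwm_log_odds(pfm, pseudocount)
    L = lo.shape[1]
    lut = np.vstack([lo, np.zeros((1, L))])  # row 4: N
    lut_rc = _revcomp_lut(lut)
    threshold = score_fraction * lo.max(axis=0).sum()
    hits = {}
    for name, seq in sequences.items():
        enc = _encode(seq)
        if enc.size < L:
            hits[name] = False
            continue
        n_win = enc.size - L + 1
        best = -np.inf
        for strand_lut in (lut, lut_rc):
            scores = np.zeros(n_win)
            for i in range(L):
                scores += strand_lut[enc[i : i + n_win], i]
            best = max(best, scores.max())
        hits[name] = bool(best >= threshold)
    return pd.Series(hits, name="hit")


def motif_enrichment(
    target_hits: pd.Series,
    background_hits: pd.Series,
    motif_id: str = "",
) -> MotifEnrichment:
    """One-sided binomial enrichment of motif hits in target vs background.

    p = P(X >= k_target | n_target, p0) with p0 the background hit rate.
    A zero background rate with target hits is handled by an add-one
    pseudo-background and flagged.
    """
    n_t, k_t = len(target_hits), int(target_hits.sum())
    n_b, k_b = len(background_hits), int(background_hits.sum())
    if n_t == 0 or n_b == 0:
        raise ValueError("target and background must be non-empty")
    flag = ""
    p0 = k_b / n_b
    if p0 == 0 and k_t > 0:
        p0 = (k_b + 1) / (n_b + 1)
        flag = "pseudo-background"
    p = binomial_tail_p(k_t, n_t, p0)
    p = max(p, np.finfo(float).tiny)
    return MotifEnrichment(motif_id, n_t, k_t, n_b, k_b, p, -math.log(p), flag)


def motif_enrichment_table(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    motifs: dict[str, np.ndarray],
    score_fraction: float = MOTIF_SCORE_FRACTION,
    neg_ln_p_min: float | None = None,
) -> pd.DataFrame:
    """Scan and test a motif set; optionally keep -ln(p) above a threshold."""
    rows = []
    for motif_id, pfm in motifs.items():
        t_hits = motif_scan(target_seqs, pfm, score_fraction)
        b_hits = motif_scan(background_seqs, pfm, score_fraction)
        rows.append(motif_enrichment(t_hits, b_hits, motif_id).__dict__)
    out = pd.DataFrame(rows)
    if neg_ln_p_min is not None:
        out = out[out["neg_ln_p"] > neg_ln_p_min]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def nearest_gene(regions: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Assign each region the gene whose TSS is closest to its midpoint.

    Distance is 0 when the TSS lies inside the region; ties are broken
    lexicographically by gene name. Regions on chromosomes with no TSS are
    returned unassigned with a flag.
    """
    out = []
    tss_by_chrom = {c: sub.sort_values(["pos", "gene"]) for c, sub in tss.groupby("chrom")}
    for _, r in regions.iterrows():
        rec = {"region_id": r["region_id"], "gene": None, "distance": np.nan,
               "flag": ""}
        sub = tss_by_chrom.get(r["chrom"])
        if sub is None:
            rec["flag"] = "no-TSS-on-chromosome"
            out.append(rec)
            continue
        mid = (r["start"] + r["end"]) / 2.0
        inside = sub[(sub["pos"] >= r["start"]) & (sub["pos"] < r["end"])]
        if not inside.empty:
            rec["gene"] = sorted(inside["gene"])[0]
            rec["distance"] = 0.0
        else:
            d = (sub["pos"] - mid).abs()
            dmin = d.min()
            rec["gene"] = sorted(sub.loc[d == dmin, "gene"])[0]
            rec["distance"] = float(dmin)
        out.append(rec)
    return pd.DataFrame(out)
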
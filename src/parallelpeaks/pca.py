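"""Population structure, local PCA of shared regions, and altitude models.

Global PCA describes genome-wide (putatively neutral) structure: sites are
restricted to windows without high differentiation, pruned for linkage by
distance, mean-imputed, centred, and decomposed by SVD. Local PCA of an
SHDR's outlier windows highlights divergent haplotypes; whether altitude
predicts the local PC1 beyond neutral structure is assessed with the
linear model

    local_PC1 ~ altitude_m + global_PC1

whose predictors' relative importance is summarised by LMG partial R^2
(the average of each predictor's sequential R^2 contribution over both
orderings — exact for two predictors, and the two values sum to the model
R^2). A segregating inversion shows up as three PC1 clusters (the two
homokaryotypes flanking the heterokaryotypes), recovered here with a
deterministic 1-D k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ld_thin",
    "PcaResult",
    "global_pca",
    "local_pca",
    "altitude_association",
    "karyotype_cluster",
    "pairwise_fst_matrix",
    "ibd_ibe_contrast",
]


def ld_thin(chrom, pos, min_gap: int = 10_000) -> np.ndarray:
    """Greedy left-to-right distance pruning: keep a site iff it lies at
    least ``min_gap`` from the last kept site on its chromosome. Returns
    indices of retained sites (input must be sorted within chromosomes)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    keep = []
    last: dict = {}
    for i in range(pos.size):
        c = chrom[i]
        if c not in last or pos[i] - last[c] >= min_gap:
            keep.append(i)
            last[c] = pos[i]
    return np.array(keep, dtype=np.int64)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components (PC1, PC2, ...)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray | None = None


def _pca(geno: np.ndarray, sample_ids: list[str], n_components: int) -> PcaResult:
    """PCA of a dosage matrix (samples x sites) with mean imputation of
    missing values, column centring, and a deterministic sign convention
    (the largest-|loading| site of each component is positive)."""
    x = np.asarray(geno, dtype=float)
    miss = x < 0
    x = np.where(miss, np.nan, x)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(~np.isfinite(x))
    x[inds] = col_mean[inds[1]]
    x = x - x.mean(axis=0)
    if not np.any(x != 0):
        raise ValueError("zero-variance genotype matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    var = s**2
    ratio = var / var.sum()
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(scores=scores, explained_variance_ratio=ratio[:k],
                     loadings=vt[:k])


def global_pca(
    geno: np.ndarray,
    sample_ids: list[str],
    chrom,
    pos,
    exclude_intervals=None,
    thin_gap: int = 10_000,
    exclude_chroms: list[str] | None = None,
    subsample_fraction: float | None = None,
    n_components: int = 10,
    seed: int = 0,
) -> PcaResult:
    """Genome-wide PCA on putatively neutral sites.

    ``geno`` is sites x samples (dosages, -1 missing). Sites inside
    ``exclude_intervals`` (an :class:`~parallelpeaks.genome.IntervalSet`
    of outlier windows / HDRs) or on excluded chromosomes are removed,
    remaining sites are distance-thinned, and optionally a random
    fraction of them is subsampled before decomposition.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    keep = np.ones(pos.size, dtype=bool)
    if exclude_chroms:
        keep &= ~np.isin(chrom, exclude_chroms)
    if exclude_intervals is not None and len(exclude_intervals):
        from .genome import overlaps_any

        merged = exclude_intervals.merged()
        lin = exclude_intervals.genome.linearise(chrom, pos)
        keep &= ~overlaps_any(lin, lin + 1, merged.lin_start, merged.lin_end)
    idx = np.flatnonzero(keep)
    thin = ld_thin(chrom[idx], pos[idx], thin_gap)
    idx = idx[thin]
    if subsample_fraction is not None:
        rng = np.random.default_rng(seed)
        m = max(2, int(round(subsample_fraction * idx.size)))
        idx = np.sort(rng.choice(idx, size=min(m, idx.size), replace=False))
    if idx.size < 2:
        raise ValueError("fewer than 2 sites left after filtering")
    return _pca(np.asarray(geno)[idx].T, sample_ids, n_components)


def local_pca(geno: np.ndarray, sample_ids: list[str], n_components: int = 5) -> PcaResult:
    """PCA of the sites of one SHDR's outlier windows (no exclusion or
    thinning)."""
    return _pca(np.asarray(geno).T, sample_ids, n_components)


def altitude_association(
    local_pc1: np.ndarray,
    altitude_m: np.ndarray,
    global_pc1: np.ndarray,
) -> dict:
    """OLS of local PC1 on altitude and global PC1, with LMG partial R^2.

    Returns coefficient/p-value for altitude, the model R^2, and partial
    R^2 for each predictor (averaged sequential contributions over both
    predictor orderings). Collinear predictors are flagged and yield a
    null association.
    """
    import statsmodels.api as sm

    y = np.asarray(local_pc1, dtype=float)
    x1 = np.asarray(altitude_m, dtype=float)
    x2 = np.asarray(global_pc1, dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 samples")
    if np.std(x1) == 0 or np.std(x2) == 0 or abs(np.corrcoef(x1, x2)[0, 1]) > 0.999:
        return {"collinear": True, "altitude_coef": np.nan, "altitude_p": np.nan,
                "r2": np.nan, "partial_r2_altitude": np.nan, "partial_r2_global": np.nan}

    def r2_of(*cols):
        X = sm.add_constant(np.column_stack(cols))
        return sm.OLS(y, X).fit().rsquared

    full = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
    r2_full = full.rsquared
    r2_1 = r2_of(x1)
    r2_2 = r2_of(x2)
    # LMG: average sequential contribution over the two orderings
    lmg_alt = 0.5 * (r2_1 + (r2_full - r2_2))
    lmg_glob = 0.5 * (r2_2 + (r2_full - r2_1))
    return {
        "collinear": False,
        "altitude_coef": float(full.params[1]),
        "altitude_p": float(full.pvalues[1]),
        "r2": float(r2_full),
        "partial_r2_altitude": float(lmg_alt),
        "partial_r2_global": float(lmg_glob),
    }


def karyotype_cluster(pc1_scores: np.ndarray) -> dict:
    """Three-cluster karyotype assignment along a local PC1.

    Deterministic 1-D k-means (k=3, centres initialised at the minimum,
    median and maximum score); clusters are ordered by mean PC1 and
    labelled hom_left / het / hom_right — the heterokaryotype is the
    middle cluster, while which homokaryotype is the non-inverted ("wt")
    arrangement is caller-supplied metadata. A silhouette-style diagnostic
    is reported and a warning flag set when the scores are not clearly
    trimodal.
    """
    x = np.asarray(pc1_scores, dtype=float)
    if x.size < 6:
        raise ValueError("need >= 6 samples for karyotype clustering")
    if np.unique(x).size < 3:
        return {"labels": np.array(["degenerate"] * x.size), "degenerate": True,
                "centres": np.full(3, np.nan), "silhouette": np.nan, "warning": True}
    centres = np.array([x.min(), np.median(x), x.max()], dtype=float)
    assign = np.zeros(x.size, dtype=int)
    for _ in range(100):
        d = np.abs(x[:, None] - centres[None, :])
        new_assign = np.argmin(d, axis=1)
        for k in range(3):
            if np.any(new_assign == k):
                centres[k] = x[new_assign == k].mean()
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    order = np.argsort(centres)
    rank = np.empty(3, dtype=int)
    rank[order] = np.arange(3)
    assign = rank[assign]
    centres = centres[order]
    names = np.array(["hom_left", "het", "hom_right"])
    # silhouette-style diagnostic on the 1-D clustering
    sil = _silhouette_1d(x, assign)
    # unimodal scores cluster with silhouette ~0.5; clean karyotype
    # trimodality sits near 0.9, so 0.75 separates the regimes
    return {"labels": names[assign], "assignment": assign, "centres": centres,
            "silhouette": sil, "warning": bool(sil < 0.75), "degenerate": False}


def _silhouette_1d(x: np.ndarray, assign: np.ndarray) -> float:
    vals = []
    for i in range(x.size):
        own = assign[i]
        same = x[(assign == own)]
        a = np.abs(x[i] - same).sum() / max(same.size - 1, 1)
        b = np.inf
        for k in set(assign.tolist()) - {own}:
            other = x[assign == k]
            b = min(b, np.abs(x[i] - other).mean())
        if np.isfinite(b) and max(a, b) > 0:
            vals.append((b - a) / max(a, b))
    return float(np.mean(vals)) if vals else np.nan


def pairwise_fst_matrix(counts, chrom, pos, thin_gap: int = 2_000) -> pd.DataFrame:
    """Hudson ratio-of-sums Fst between every pair of populations, over
    distance-thinned polymorphic sites. Symmetric with a zero diagonal;
    negative estimates are reported as computed."""
    from .windows import hudson_fst_site

    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    pops = list(counts.ac)
    # polymorphic across the dataset
    tot_ac = sum(counts.ac[p] for p in pops)
    tot_an = sum(counts.an[p] for p in pops)
    poly = (tot_ac > 0) & (tot_ac < tot_an)
    idx = np.flatnonzero(poly)
    thin = ld_thin(chrom[idx], pos[idx], thin_gap)
    idx = idx[thin]
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            alpha, beta = hudson_fst_site(
                counts.freq(a)[idx], counts.an[a][idx],
                counts.freq(b)[idx], counts.an[b][idx],
            )
            ok = np.isfinite(alpha) & np.isfinite(beta)
            denom = beta[ok].sum()
            fst = alpha[ok].sum() / denom if denom > 0 else np.nan
            mat.loc[a, b] = mat.loc[b, a] = fst
    return mat


def ibd_ibe_contrast(fst: pd.DataFrame, distance: pd.DataFrame,
                     altitude_class: dict[str, str]) -> dict:
    """Isolation-by-distance vs isolation-by-environment contrast.

    Pairs are labelled high-high / high-low / low-low from the altitude
    class of each population (low and low_distant both count as lowland).
    Reports a linear Fst~distance fit per class and a one-sided
    Mann-Whitney test of whether high-low residuals (from the pooled fit)
    exceed low-low residuals.
    """
    if not np.allclose(distance.values, distance.values.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    pops = [p for p in fst.index if p in altitude_class]
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            ca = "high" if altitude_class[a] == "high" else "low"
            cb = "high" if altitude_class[b] == "high" else "low"
            label = "-".join(sorted([ca, cb]))
            rows.append({"pop_a": a, "pop_b": b, "class": label,
                         "fst": fst.loc[a, b], "distance": distance.loc[a, b]})
    pairs = pd.DataFrame(rows)
    fits = {}
    for label, sub in pairs.groupby("class"):
        if len(sub) >= 2 and sub["distance"].std() > 0:
            fit = stats.linregress(sub["distance"], sub["fst"])
            fits[label] = {"slope": fit.slope, "intercept": fit.intercept,
                           "r": fit.rvalue}
        else:
            fits[label] = {"slope": np.nan,
                           "intercept": float(sub["fst"].mean()), "r": np.nan}
    if pairs["distance"].std() > 0:
        pooled = stats.linregress(pairs["distance"], pairs["fst"])
        resid = pairs["fst"] - (pooled.intercept + pooled.slope * pairs["distance"])
    else:
        resid = pairs["fst"] - pairs["fst"].mean()
    hl = resid[pairs["class"] == "high-low"]
    ll = resid[pairs["class"] == "low-low"]
    if len(hl) and len(ll):
        if np.allclose(pairs["fst"], pairs["fst"].iloc[0]):
            p = 1.0
            u = np.nan
        else:
            test = stats.mannwhitneyu(hl, ll, alternative="greater")
            u, p = float(test.statistic), float(test.pvalue)
    else:
        u, p = np.nan, np.nan
    return {"pairs": pairs, "fits": fits, "residual_test_u": u,
            "residual_test_p": p}
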
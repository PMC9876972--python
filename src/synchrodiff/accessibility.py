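"""Differential chromatin accessibility on binned signal curves.

Each candidate region's normalised ATAC signal is extracted in 31 bins per
replicate, smoothed on 10 equidistant cubic B-splines, and compared between
two conditions with a Hotelling T-squared test on functional principal
component scores. Significant regions (Bonferroni-adjusted p <= 1e-4 and
absolute fold change >= 2) are ranked by

    S_d = -log(adj.P) * FC * sqrt(Baseline)

with Baseline the mean of the two conditions' average normalised signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .core import GenomicInterval, IntervalSet, SignalTrack, binned_signal


@dataclass
class ComparisonConfig:
    n_bins: int = 31
    n_basis: int = 10
    var_fraction: float = 0.95
    fc_threshold: float = 2.0
    p_adj_threshold: float = 1e-4
    log_base: float = np.e  # base of the log in the ranking score
    pseudocount: float = 1e-9

    def __post_init__(self):
        if self.n_basis > self.n_bins:
            raise ValueError("n_basis must not exceed n_bins")
        if min(self.fc_threshold, self.p_adj_threshold) <= 0:
            raise ValueError("thresholds must be positive")


def peak_score(mu_ns: float, p_adj: float) -> float:
    """Peak score S_p = mu_ns * (-log10 p_adj).

    ``mu_ns`` is the mean background-normalised peak signal and ``p_adj``
    the BH-corrected enrichment p-value.
    """
    if mu_ns < 0:
        raise ValueError("mu_ns must be non-negative")
    if p_adj <= 0 or p_adj > 1:
        raise ValueError("p_adj must lie in (0, 1]; floor p before scoring")
    return mu_ns * (-np.log10(p_adj))


def rank_score(p_adj, fc, baseline, log_base: float = np.e):
    """Differential-region ranking score -log(p_adj) * FC * sqrt(Baseline)."""
    p_adj = np.asarray(p_adj, dtype=float)
    if np.any(p_adj <= 0):
        raise ValueError("p_adj must be > 0; floor p before ranking")
    return (-np.log(p_adj) / np.log(log_base)) * np.asarray(fc) * np.sqrt(np.asarray(baseline))


def bspline_basis(n_basis: int, n_points: int, degree: int = 3) -> np.ndarray:
    """Evaluation matrix (n_points x n_basis) of an equidistant B-spline basis
    on [0, 1]."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for the requested degree")
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.concatenate([[0.0] * (degree + 1), interior, [1.0] * (degree + 1)])
    x = np.linspace(0, 1, n_points)
    return BSpline.design_matrix(x, knots, degree).toarray()


def smooth_curves(curves: np.ndarray, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares B-spline smoothing of each row of ``curves``.

    Returns (coefficients, smoothed values on the original grid).
    """
    B = bspline_basis(n_basis, curves.shape[1])
    coef, *_ = np.linalg.lstsq(B, curves.T, rcond=None)
    return coef.T, (B @ coef).T


def fpca_scores(smoothed: np.ndarray, var_fraction: float) -> np.ndarray:
    """Principal-component scores of smoothed curves.

    Components are added until ``var_fraction`` of the variance is retained;
    at least one component is always kept.
    """
    centred = smoothed - smoothed.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
    k = int(np.searchsorted(frac, var_fraction) + 1)
    k = min(k, len(s))
    return centred @ vt[:k].T


def _pooled_hotelling(scores1: np.ndarray, scores2: np.ndarray, pooled_cov: np.ndarray):
    """Two-sample Hotelling T^2 with an externally pooled covariance."""
    n1, n2 = len(scores1), len(scores2)
    d = scores1.mean(axis=0) - scores2.mean(axis=0)
    try:
        sol = np.linalg.solve(pooled_cov, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(pooled_cov, d, rcond=None)[0]
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def diff_accessibility_test(
    tracks_t1: list[SignalTrack],
    tracks_t2: list[SignalTrack],
    regions: IntervalSet,
    cfg: ComparisonConfig | None = None,
) -> pd.DataFrame:
    """Functional differential-accessibility test between two conditions.

    With two replicates per condition a per-region covariance of the FPC
    scores is singular, so the score covariance is pooled across all regions
    in the comparison (ridge-regularised if ill-conditioned); T^2 is
    converted to an F statistic with the pooled degrees of freedom and
    Bonferroni-corrected over tested regions.
    """
    cfg = cfg or ComparisonConfig()
    if len(regions) == 0:
        raise ValueError("no regions to test")
    if len(tracks_t1) < 2 or len(tracks_t2) < 2:
        raise ValueError("at least two replicates per condition required")
    n1, n2 = len(tracks_t1), len(tracks_t2)
    R = len(regions)

    curves = np.empty((R, n1 + n2, cfg.n_bins))
    means = np.empty((R, 2))
    for i, iv in enumerate(regions):
        for j, tr in enumerate(tracks_t1 + tracks_t2):
            curves[i, j] = binned_signal(tr, iv, cfg.n_bins)
        means[i, 0] = curves[i, :n1].mean()
        means[i, 1] = curves[i, n1:].mean()

    flat = curves.reshape(R * (n1 + n2), cfg.n_bins)
    _, smoothed = smooth_curves(flat, cfg.n_basis)
    scores = fpca_scores(smoothed, cfg.var_fraction).reshape(R, n1 + n2, -1)
    p_dim = scores.shape[-1]

    # covariance pooled across regions and conditions
    scatter = np.zeros((p_dim, p_dim))
    dof = 0
    for i in range(R):
        for grp in (scores[i, :n1], scores[i, n1:]):
            c = grp - grp.mean(axis=0)
            scatter += c.T @ c
            dof += len(grp) - 1
    pooled = scatter / max(dof, 1)
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e8:
        pooled = pooled + 1e-8 * np.eye(p_dim) * max(np.trace(pooled) / p_dim, 1e-12)

    t2 = np.array(
        [_pooled_hotelling(scores[i, :n1], scores[i, n1:], pooled) for i in range(R)]
    )
    # T^2 -> F with nu pooled degrees of freedom
    nu = dof
    fstat = t2 * (nu - p_dim + 1) / (nu * p_dim)
    p = stats.f.sf(fstat, p_dim, nu - p_dim + 1)
    p_adj = np.minimum(p * R, 1.0)

    fc = (means[:, 1] + cfg.pseudocount) / (means[:, 0] + cfg.pseudocount)
    baseline = 0.5 * (means[:, 0] + means[:, 1])
    status = np.where(
        (p_adj <= cfg.p_adj_threshold) & (fc >= cfg.fc_threshold),
        "opening",
        np.where(
            (p_adj <= cfg.p_adj_threshold) & (fc <= 1.0 / cfg.fc_threshold),
            "closing",
            "untested",
        ),
    )
    p_floor = np.maximum(p_adj, np.finfo(float).tiny)
    s_d = rank_score(p_floor, fc, baseline, cfg.log_base)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "fc": fc,
            "t2": t2,
            "p_adj": p_adj,
            "baseline": baseline,
            "s_d": s_d,
            "status": status,
        }
    )


def aggregate_regions(peaks_t1: IntervalSet, peaks_t2: IntervalSet, max_gap: int = 40) -> IntervalSet:
    """Union of both conditions' peak sets, merged; the tested universe."""
    return IntervalSet(list(peaks_t1) + list(peaks_t2)).merge(max_gap)


def classify_invariant(comparisons: list[pd.DataFrame]) -> pd.DataFrame:
    """Regions significant in zero consecutive-time-point comparisons are
    'invariant'; all comparisons must share the same region universe."""
    if not comparisons:
        raise ValueError("no comparisons given")
    key = comparisons[0][["chrom", "start", "end"]]
    for df in comparisons[1:]:
        if not df[["chrom", "start", "end"]].equals(key):
            raise ValueError("comparisons cover different region universes")
    sig = np.zeros(len(key), dtype=bool)
    for df in comparisons:
        sig |= df.status.isin(["opening", "closing"]).to_numpy()
    out = key.copy()
    out["status"] = np.where(sig, "variant", "invariant")
    return out


def rna_atac_correlation(
    expr_log2fc: pd.Series,
    tracks_t1: list[SignalTrack],
    tracks_t2: list[SignalTrack],
    tss_table: pd.DataFrame,
    window: int = 10_000,
) -> dict:
    """Pearson correlation between expression change and promoter
    accessibility change.

    Per gene, the maximum normalised ATAC signal in the 10-kb window
    upstream of the TSS (strand-aware) is averaged over replicates at each
    time point; the log2 ratio between time points is correlated with the
    expression log2 fold change. Genes with a zero maximum in either
    condition are dropped and counted.
    """
    maxima = {"t1": [], "t2": []}
    genes = []
    for _, g in tss_table.iterrows():
        if g.gene_id not in expr_log2fc.index:
            continue
        if g.strand == "-":
            start, end = g.tss + 1, g.tss + 1 + window
        else:
            start, end = max(0, g.tss - window), g.tss
        if end <= start:
            continue
        iv = GenomicInterval(g.chrom, start, end)
        m1 = np.mean([tr.region(iv).max(initial=0.0) for tr in tracks_t1])
        m2 = np.mean([tr.region(iv).max(initial=0.0) for tr in tracks_t2])
        genes.append(g.gene_id)
        maxima["t1"].append(m1)
        maxima["t2"].append(m2)

    m1 = np.asarray(maxima["t1"])
    m2 = np.asarray(maxima["t2"])
    usable = (m1 > 0) & (m2 > 0)
    dropped = int((~usable).sum())
    if usable.sum() < 3:
        raise ValueError("fewer than 3 genes with usable ATAC maxima")
    atac_lfc = np.log2(m2[usable] / m1[usable])
    expr = expr_log2fc.loc[np.asarray(genes)[usable]].to_numpy(dtype=float)
    r, p = stats.pearsonr(expr, atac_lfc)
    return {"r": float(r), "p": float(p), "n": int(usable.sum()), "dropped": dropped}
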
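"""Temporal expression clustering with BIC model selection.

Rows of the expression matrix are transformed to log2(FPKM + 1) and scaled
to mean 0, SD 1 (constant rows become zeros). A Gaussian mixture is fitted
for each candidate cluster count K and the K minimising the Bayesian
Information Criterion is selected; assignments are maximum-posterior.
Cluster profiles are smoothed by least squares on 5 cubic B-splines over
the time interval with no roughness penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .accessibility import bspline_basis

DEFAULT_TIMES = (0, 12, 24, 36, 48, 60, 72)


def fpkm_normalize(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (library_size * gene_length)."""
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("library sizes must be positive for all samples")
    return counts.mul(1e9).div(libs, axis=1).div(lengths, axis=0)


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM+1) then per-row standardisation; constant rows -> zeros."""
    x = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    # constant rows (SD at floating-point noise level) scale to zeros
    ok = sd > 1e-12 * np.maximum(np.abs(mu), 1.0)
    scaled = np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series
    bic: pd.Series  # indexed by candidate K
    means: np.ndarray  # K x T cluster mean profiles (scaled space)
    sds: np.ndarray  # K x T per-time-point SDs


def select_k_cluster(
    fpkm: pd.DataFrame,
    k_range=range(1, 11),
    seed: int = 0,
    n_init: int = 10,
    covariance_type: str = "diag",
    method: str = "gmm",
) -> ClusterModel:
    """Cluster row-scaled profiles; pick K by minimal BIC (smaller = better).

    ``method='kmeans'`` is an alternative mode without BIC selection: the
    largest K in the range is used directly.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    if len(fpkm) < 2:
        raise ValueError("need at least 2 genes")
    ks = [k for k in ks if 1 <= k <= len(fpkm)]
    scaled = row_scale(fpkm)
    X = scaled.to_numpy()

    if method == "kmeans":
        k = max(ks)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        labels = km.labels_
        bic = pd.Series(dtype=float)
    else:
        bics = {}
        fits = {}
        for k in ks:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=covariance_type,
                n_init=n_init,
                random_state=seed,
                reg_covar=1e-6,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            bics[k] = gm.bic(X)
            fits[k] = gm
        bic = pd.Series(bics).sort_index()
        k = int(bic.idxmin())
        labels = fits[k].predict(X)

    means = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    sds = np.stack(
        [X[labels == c].std(axis=0) if (labels == c).sum() > 1 else np.zeros(X.shape[1]) for c in range(k)]
    )
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=fpkm.index, name="cluster"),
        bic=bic,
        means=means,
        sds=sds,
    )


def smooth_cluster_profiles(
    matrix: pd.DataFrame,
    assignments: pd.Series,
    times=DEFAULT_TIMES,
    n_basis: int = 5,
    n_eval: int = 101,
) -> dict[int, pd.DataFrame]:
    """Smooth each cluster's member profiles on 5 cubic B-splines (lambda=0)
    and return the mean curve with a pointwise +/- 2 SD band on a dense grid.

    Empty clusters are skipped with a warning.
    """
    times = np.asarray(times, dtype=float)
    X = matrix.to_numpy(dtype=float)
    B = bspline_basis(n_basis, len(times))
    coef, *_ = np.linalg.lstsq(B, X.T, rcond=None)  # (n_basis x genes)
    B_eval = bspline_basis(n_basis, n_eval)
    curves = (B_eval @ coef).T  # genes x n_eval
    grid = np.linspace(times[0], times[-1], n_eval)

    out = {}
    for c in range(int(assignments.max()) + 1):
        members = curves[(assignments == c).to_numpy()]
        if len(members) == 0:
            warnings.warn(f"cluster {c} is empty; skipped", stacklevel=2)
            continue
        mean = members.mean(axis=0)
        sd = members.std(axis=0, ddof=0) if len(members) > 1 else np.zeros_like(mean)
        out[int(c)] = pd.DataFrame(
            {"time": grid, "mean": mean, "lower": mean - 2 * sd, "upper": mean + 2 * sd}
        )
    return out


def smoothing_coefficients(matrix: pd.DataFrame, times=DEFAULT_TIMES, n_basis: int = 5) -> np.ndarray:
    """Least-squares B-spline coefficients per gene (genes x n_basis)."""
    X = matrix.to_numpy(dtype=float)
    B = bspline_basis(n_basis, len(np.asarray(times)))
    coef, *_ = np.linalg.lstsq(B, X.T, rcond=None)
    return coef.T
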
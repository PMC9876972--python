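"""Scalar-on-function regression of accessibility change on TF footprints.

The response is the log2 absolute fold change of a differential ATAC-seq
region; the functional covariate is the indicator function of a TF's
footprint coverage over the 1000-bp window centred on the region's peak,
represented on five order-4 (cubic) B-splines. The model

    y_i = alpha_0 + integral x_i(t) beta(t) dt + eps_i

reduces to ordinary least squares through the basis Gram matrix; fit
quality per TF is assessed by R^2 and the F-ratio against the intercept-only
model, with the upper-tail F probability as p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import bspline_basis
from .core import IntervalSet

WINDOW = 1000  # bp around the peak centre
N_BASIS = 5
DEGREE = 3


@dataclass
class RegressionConfig:
    fc_min: float = 1.5  # |FC| must exceed this
    fc_max: float = 10.0  # |FC| at or above this removed as outliers
    max_regions: int = 50_000
    min_footprints: int = 15  # footprints overlapping selected regions
    min_regions_hit: int = 10  # regions with >= 1 footprint (production: 50)
    signed_response: bool = False


def select_regions(diff: pd.DataFrame, cfg: RegressionConfig | None = None) -> pd.DataFrame:
    """Select differential regions and build the regression response.

    The effect magnitude is max(fc, 1/fc); regions with magnitude in
    (fc_min, fc_max) are kept, capped at ``max_regions`` by descending
    magnitude. The response y is log2 magnitude (or signed log2 fc when
    configured); the covariate window is peak centre +/- 500 bp.
    """
    cfg = cfg or RegressionConfig()
    fc = diff.fc.to_numpy(dtype=float)
    mag = np.maximum(fc, 1.0 / np.maximum(fc, 1e-300))
    keep = (mag > cfg.fc_min) & (mag < cfg.fc_max)
    out = diff.loc[keep].copy()
    out["magnitude"] = mag[keep]
    out = out.sort_values("magnitude", ascending=False).head(cfg.max_regions)
    if out.empty:
        raise ValueError("no regions survive the fold-change filters")
    out["y"] = (
        np.log2(out.fc.to_numpy()) if cfg.signed_response else np.log2(out.magnitude.to_numpy())
    )
    centre = ((out.start + out.end) // 2).astype(int)
    out["win_start"] = np.maximum(centre - WINDOW // 2, 0)
    out["win_end"] = out["win_start"] + WINDOW
    return out.reset_index(drop=True)


def _basis_and_gram(n_points: int = WINDOW, n_basis: int = N_BASIS) -> tuple[np.ndarray, np.ndarray]:
    """Basis evaluation matrix on a 1-bp grid and its Gram matrix.

    The Gram matrix carries the dt of the grid so the fitted linear form
    equals the integral of x_i(t) beta(t) over the window.
    """
    B = bspline_basis(n_basis, n_points, DEGREE)
    dt = 1.0 / n_points  # window rescaled to unit length
    G = B.T @ B * dt
    return B, G


def build_functional_covariate(
    regions: pd.DataFrame,
    footprints: IntervalSet,
    cfg: RegressionConfig | None = None,
    n_basis: int = N_BASIS,
) -> pd.DataFrame | None:
    """Project each region's footprint indicator onto the 5-spline basis.

    The indicator is 1.0 on window bases covered by a footprint and 0.0
    elsewhere, projected by least squares on a 1-bp grid. Returns one row
    per region with coefficient columns c0..c4 and the footprint count, or
    ``None`` when the TF fails the support thresholds (too few overlapping
    footprints, or too few regions hit).
    """
    cfg = cfg or RegressionConfig()
    B, _ = _basis_and_gram(n_basis=n_basis)
    proj = np.linalg.pinv(B.T @ B) @ B.T  # (n_basis x WINDOW)

    fp_by_chrom: dict[str, np.ndarray] = {}
    for iv in footprints:
        fp_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    fp_by_chrom = {c: np.array(v) for c, v in fp_by_chrom.items()}

    coefs = np.zeros((len(regions), n_basis))
    counts = np.zeros(len(regions), dtype=int)
    n_overlapping = 0
    for i, r in regions.iterrows():
        pairs = fp_by_chrom.get(r.chrom)
        if pairs is None:
            continue
        sel = pairs[(pairs[:, 1] > r.win_start) & (pairs[:, 0] < r.win_end)]
        if not len(sel):
            continue
        indicator = np.zeros(WINDOW)
        for s, e in sel:
            indicator[max(s - r.win_start, 0) : max(min(e, r.win_end) - r.win_start, 0)] = 1.0
        coefs[i] = proj @ indicator
        counts[i] = len(sel)
        n_overlapping += len(sel)
    if n_overlapping < cfg.min_footprints or (counts > 0).sum() < cfg.min_regions_hit:
        return None
    out = pd.DataFrame(coefs, columns=[f"c{j}" for j in range(n_basis)])
    out["n_footprints"] = counts
    return out


@dataclass
class ScalarOnFunctionFit:
    tf: str
    intercept: float
    beta_coef: np.ndarray
    rsq: float
    f_ratio: float
    p: float
    n: int
    residual_var: float


def fit_scalar_on_function(
    y: np.ndarray, covariates: pd.DataFrame, tf: str = "", n_basis: int = N_BASIS
) -> ScalarOnFunctionFit:
    """OLS fit of the functional linear model via the basis Gram matrix.

    The integral term reduces to z_i = G c_i with G the basis Gram matrix
    and c_i the covariate coefficients, giving a plain linear model
    y = alpha_0 + z gamma with gamma the beta(t) coefficients.
    """
    y = np.asarray(y, dtype=float)
    C = covariates[[f"c{j}" for j in range(n_basis)]].to_numpy()
    n = len(y)
    if n < n_basis + 2:
        raise ValueError(f"need at least {n_basis + 2} regions, got {n}")
    _, G = _basis_and_gram(n_basis=n_basis)
    Z = C @ G
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for TF {tf!r}: covariates are collinear")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    rsq = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    df_num, df_den = n_basis, n - n_basis - 1
    if tss == 0 or rss <= 0:
        f_ratio = 0.0 if tss == 0 else np.inf
    else:
        f_ratio = ((tss - rss) / df_num) / (rss / df_den)
    p = float(stats.f.sf(f_ratio, df_num, df_den)) if np.isfinite(f_ratio) else 0.0
    return ScalarOnFunctionFit(
        tf=tf,
        intercept=float(coef[0]),
        beta_coef=coef[1:],
        rsq=rsq,
        f_ratio=float(f_ratio),
        p=p,
        n=n,
        residual_var=rss / max(df_den, 1),
    )


def predict_integral(fit: ScalarOnFunctionFit, covariates: pd.DataFrame) -> np.ndarray:
    """Fitted integral term for each region (without the intercept)."""
    C = covariates[[f"c{j}" for j in range(N_BASIS)]].to_numpy()
    _, G = _basis_and_gram()
    return C @ G @ fit.beta_coef


def rank_tf_predictors(fits: list[ScalarOnFunctionFit]) -> pd.DataFrame:
    """Rank TFs by R^2 (ties by F-ratio, then name)."""
    if not fits:
        raise ValueError("no fits to rank")
    df = pd.DataFrame(
        {
            "tf": [f.tf for f in fits],
            "n": [f.n for f in fits],
            "rsq": [f.rsq for f in fits],
            "f_ratio": [f.f_ratio for f in fits],
            "p": [f.p for f in fits],
        }
    )
    return df.sort_values(
        ["rsq", "f_ratio", "tf"], ascending=[False, False, True]
    ).reset_index(drop=True)
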
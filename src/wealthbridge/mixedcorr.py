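"""Mixed-type correlation matrix estimation.

Asset indicators come in four measurement types, so the pooled correlation
matrix mixes estimators by pair: polychoric for ordinal-ordinal (binary is a
two-category ordinal), polyserial for ordinal-continuous, Pearson for
continuous-continuous.  Both latent-variable estimators assume a standard
bivariate normal underlying each pair and are computed in two steps:
thresholds are fixed from the univariate margins, then the correlation
maximizes the likelihood with thresholds held fixed.  Counts are treated as
ordinal with their observed values as ordered categories.

The bivariate normal rectangle probabilities are evaluated through Owen's T
function, which is exact up to quadrature of a single smooth integrand
(absolute accuracy well below 1e-8 for |rho| <= 0.999).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import AssetDictionary, DegenerateVariableError, PanelDataset

logger = logging.getLogger("wealthbridge.mixedcorr")

RHO_BOUND = 0.999  # clamp for all latent correlation estimates
_RHO_XTOL = 1e-6
_EPS_LOG = 1e-12


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T route)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the classical Owen's T identity

        Phi2(h, k; rho) = (Phi(h) + Phi(k)) / 2
                          - T(h, a_h) - T(k, a_k) - beta,

    with a_h = (k - rho*h) / (h*sqrt(1-rho^2)) (and symmetrically a_k), and
    beta = 1/2 when h*k < 0 or when h*k = 0 with h + k < 0.  Inputs at exactly
    zero are nudged by a sign-preserving epsilon so the formula's limits are
    taken numerically; the induced error is below 1e-12.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)

    # infinite bounds reduce to univariate margins
    neg_inf = np.isneginf(h) | np.isneginf(k)
    pos_h = np.isposinf(h)
    pos_k = np.isposinf(k)
    out[neg_inf] = 0.0
    out[pos_h & ~neg_inf] = stats.norm.cdf(k[pos_h & ~neg_inf])
    out[pos_k & ~neg_inf & ~pos_h] = stats.norm.cdf(h[pos_k & ~neg_inf & ~pos_h])

    fin = ~(neg_inf | pos_h | pos_k)
    if fin.any():
        eps = 1e-14
        hf = np.where(np.abs(h[fin]) < eps, eps, h[fin])
        kf = np.where(np.abs(k[fin]) < eps, eps, k[fin])
        s = np.sqrt(1.0 - rho * rho)
        ah = (kf - rho * hf) / (hf * s)
        ak = (hf - rho * kf) / (kf * s)
        beta = np.where(hf * kf < 0, 0.5, 0.0)
        val = (
            0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf))
            - special.owens_t(hf, ah)
            - special.owens_t(kf, ak)
            - beta
        )
        out[fin] = np.clip(val, 0.0, 1.0)
    return out if out.shape else float(out)


def _rectangle_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of the discretized bivariate normal.

    ``tau_x`` / ``tau_y`` are the finite interior thresholds; the implied cell
    grid has (len(tau_x)+1) x (len(tau_y)+1) cells.
    """
    bx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    by = np.concatenate(([-np.inf], tau_y, [np.inf]))
    gx, gy = np.meshgrid(bx, by, indexing="ij")
    cdf = bvn_cdf(gx, gy, rho)
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(values, weights=None) -> np.ndarray:
    """Normal-quantile thresholds of an ordinal margin.

    tau_k = Phi^{-1}(weighted cumulative proportion through category k) for
    k = 1..K-1, where categories are the sorted distinct observed values.
    """
    values = np.asarray(pd.Series(values).dropna())
    if weights is None:
        weights = np.ones(len(values))
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(values):
            raise ValueError("weights length mismatch")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    cats = np.unique(values)
    if len(cats) < 2:
        raise DegenerateVariableError(
            "single observed category; thresholds undefined"
        )
    totals = np.array([weights[values == c].sum() for c in cats])
    cum = np.cumsum(totals)[:-1] / totals.sum()
    return stats.norm.ppf(cum)


def _contingency(x_codes, y_codes, weights, kx: int, ky: int) -> np.ndarray:
    table = np.zeros((kx, ky))
    np.add.at(table, (x_codes, y_codes), weights)
    return table


# ---------------------------------------------------------------------------
# polychoric
# ---------------------------------------------------------------------------

def polychoric_rho(x, y, weights=None, return_details: bool = False):
    """Two-step polychoric correlation of two ordinal samples.

    Thresholds are fixed at the marginal normal quantiles; rho then maximizes
    the multinomial likelihood whose cell probabilities are bivariate normal
    rectangle probabilities.  Any contingency table containing a zero cell
    gets 0.5 added to every cell before likelihood evaluation (continuity
    correction against boundary divergence).  The estimate is clamped to
    [-0.999, 0.999].  On optimizer failure the pair falls back to the Pearson
    correlation of the integer codes, recorded in the returned details.
    """
    x = pd.Series(x).reset_index(drop=True)
    y = pd.Series(y).reset_index(drop=True)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, dtype=float)[ok.to_numpy()]
    x_cats = np.unique(x)
    y_cats = np.unique(y)
    if len(x_cats) < 2 or len(y_cats) < 2:
        raise DegenerateVariableError("polychoric needs >= 2 categories per margin")
    x_codes = np.searchsorted(x_cats, x)
    y_codes = np.searchsorted(y_cats, y)
    table = _contingency(x_codes, y_codes, w, len(x_cats), len(y_cats))
    if (table == 0).any():
        table = table + 0.5
    tau_x = stats.norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / table.sum())
    tau_y = stats.norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / table.sum())

    def negll(rho: float) -> float:
        probs = _rectangle_probs(tau_x, tau_y, rho)
        return -float(np.sum(table * np.log(np.maximum(probs, _EPS_LOG))))

    res = optimize.minimize_scalar(
        negll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": _RHO_XTOL},
    )
    fallback = False
    if res.success:
        rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    else:  # pragma: no cover - scipy bounded rarely fails
        logger.warning("polychoric optimizer failed; Pearson fallback")
        rho = float(np.corrcoef(x_codes, y_codes)[0, 1])
        rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
        fallback = True
    if return_details:
        return rho, {"tau_x": tau_x, "tau_y": tau_y, "fallback": fallback}
    return rho


# ---------------------------------------------------------------------------
# polyserial
# ---------------------------------------------------------------------------

def polyserial_rho(x, y, weights=None) -> float:
    """Two-step polyserial correlation of an ordinal x with a continuous y.

    y is standardized; thresholds come from the x margin; rho maximizes the
    conditional likelihood  prod_i [ Phi(u_i,k) - Phi(u_i,k-1) ]  with
    u_{i,k} = (tau_k - rho*z_i) / sqrt(1 - rho^2).
    """
    x = pd.Series(x).reset_index(drop=True)
    y = pd.Series(y).reset_index(drop=True)
    ok = x.notna() & y.notna()
    x, y = x[ok], np.asarray(y[ok], dtype=float)
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, dtype=float)[ok.to_numpy()]
    mu = np.average(y, weights=w)
    sd = np.sqrt(np.average((y - mu) ** 2, weights=w))
    if sd <= 0:
        raise DegenerateVariableError("continuous variable has zero variance")
    z = (y - mu) / sd
    x_cats = np.unique(x)
    if len(x_cats) < 2:
        raise DegenerateVariableError("ordinal margin has a single category")
    codes = np.searchsorted(x_cats, x)
    tau = estimate_thresholds(x.to_numpy(), w)
    lo = np.concatenate(([-np.inf], tau))[codes]
    hi = np.concatenate((tau, [np.inf]))[codes]

    def negll(rho: float) -> float:
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        p = stats.norm.cdf((hi - rho * z) / s) - stats.norm.cdf((lo - rho * z) / s)
        return -float(np.sum(w * np.log(np.maximum(p, _EPS_LOG))))

    res = optimize.minimize_scalar(
        negll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": _RHO_XTOL},
    )
    return float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    return float(cov / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class MixedCorrelationMatrix:
    """Symmetric mixed-type correlation estimate over a set of assets."""

    assets: list[str]
    rho: np.ndarray
    method: pd.DataFrame  # per-pair estimator label
    thresholds: dict[str, np.ndarray]
    psd_adjusted: bool = False
    min_eigenvalue_original: float = 0.0
    excluded: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.assets, columns=self.assets)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def frame_from_csv(cls, path) -> pd.DataFrame:
        return pd.read_csv(path, index_col=0)

    def sidecar_json(self) -> dict:
        return {
            "method": {
                f"{a}|{b}": self.method.loc[a, b]
                for i, a in enumerate(self.assets)
                for b in self.assets[i + 1:]
            },
            "thresholds": {k: list(v) for k, v in self.thresholds.items()},
            "psd_adjusted": self.psd_adjusted,
            "min_eigenvalue_original": self.min_eigenvalue_original,
            "excluded": self.excluded,
        }


def nearest_psd_correlation(rho: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipping repair to the nearest PSD correlation-like matrix.

    Negative eigenvalues are clipped to zero, the matrix reconstructed and the
    diagonal rescaled back to 1.  Returns the repaired matrix and the smallest
    eigenvalue of the input.
    """
    vals, vecs = np.linalg.eigh((rho + rho.T) / 2.0)
    min_eig = float(vals.min())
    if min_eig >= -1e-10:
        return rho, min_eig
    fixed = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, min_eig


def mixed_corr_matrix(
    panel,
    dictionary: AssetDictionary,
    weights=None,
    assets=None,
    continuous_handling: str = "polyserial",
) -> MixedCorrelationMatrix:
    """Pooled mixed-type correlation matrix with per-pair method dispatch.

    ``panel`` may be a :class:`PanelDataset` (participant rows pooled across
    waves) or an already-encoded DataFrame of numeric codes.  Degenerate
    assets (a single observed value) are excluded with a log entry.  When
    ``continuous_handling="quintile"`` continuous assets are discretized into
    weighted quintiles and enter the polychoric path instead of the
    polyserial one.
    """
    if isinstance(panel, PanelDataset):
        assets = list(assets) if assets is not None else list(panel.asset_columns)
        codes = panel.encoded(dictionary, assets)
    else:
        codes = pd.DataFrame(panel)
        assets = list(assets) if assets is not None else list(codes.columns)
        codes = codes[assets]
    if weights is None:
        w = np.ones(len(codes))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(codes):
            raise ValueError("weights length must match pooled rows")

    kinds = {}
    for name in assets:
        t = dictionary[name].measurement_type
        kinds[name] = "continuous" if t == "continuous" else "ordinal"

    if continuous_handling == "quintile":
        for name in assets:
            if kinds[name] == "continuous":
                codes[name] = _weighted_quintile_codes(codes[name], w)
                kinds[name] = "ordinal"
    elif continuous_handling != "polyserial":
        raise ValueError("continuous_handling must be 'polyserial' or 'quintile'")

    excluded, keep = [], []
    for name in assets:
        if codes[name].dropna().nunique() < 2:
            logger.warning("excluding degenerate asset %r (single value)", name)
            excluded.append(name)
        else:
            keep.append(name)
    assets = keep
    if len(assets) < 2:
        raise DegenerateVariableError("fewer than 2 non-degenerate assets")

    p = len(assets)
    rho = np.eye(p)
    method = pd.DataFrame("", index=assets, columns=assets)
    thresholds: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for name in assets:
        if kinds[name] == "ordinal":
            thresholds[name] = estimate_thresholds(codes[name].to_numpy(), w)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = assets[i], assets[j]
            xa, xb = codes[a], codes[b]
            ka, kb = kinds[a], kinds[b]
            if ka == "ordinal" and kb == "ordinal":
                r, det = polychoric_rho(xa, xb, w, return_details=True)
                label = "polychoric"
                if det["fallback"]:
                    label = "pearson"
                    warnings.append(f"{a}|{b}: polychoric fallback to pearson")
            elif ka == "continuous" and kb == "continuous":
                ok = xa.notna() & xb.notna()
                r = _weighted_pearson(
                    xa[ok].to_numpy(), xb[ok].to_numpy(), w[ok.to_numpy()]
                )
                label = "pearson"
            else:
                if ka == "ordinal":
                    r = polyserial_rho(xa, xb, w)
                else:
                    r = polyserial_rho(xb, xa, w)
                label = "polyserial"
            rho[i, j] = rho[j, i] = float(np.clip(r, -RHO_BOUND, RHO_BOUND))
            method.iloc[i, j] = method.iloc[j, i] = label

    repaired, min_eig = nearest_psd_correlation(rho)
    adjusted = min_eig < -1e-10
    if adjusted:
        logger.info("PSD repair applied; smallest original eigenvalue %.3e", min_eig)
    return MixedCorrelationMatrix(
        assets=assets,
        rho=repaired if adjusted else rho,
        method=method,
        thresholds=thresholds,
        psd_adjusted=adjusted,
        min_eigenvalue_original=min_eig,
        excluded=excluded,
        warnings=warnings,
    )


def _weighted_quintile_codes(values: pd.Series, w: np.ndarray) -> pd.Series:
    ok = values.notna()
    v = values[ok].to_numpy(dtype=float)
    ww = w[ok.to_numpy()]
    order = np.argsort(v, kind="mergesort")
    cum = np.cumsum(ww[order]) / ww.sum()
    qcodes = np.minimum((cum * 5).astype(int), 4)
    out = pd.Series(np.nan, index=values.index)
    out.iloc[np.flatnonzero(ok.to_numpy())[order]] = qcodes
    return out
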
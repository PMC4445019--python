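"""Unidimensionality and local-dependence screening for ordinal item pools.

Conventional IRT calibration and CAT presuppose an (essentially)
unidimensional pool.  The screen implemented here works on the polychoric
correlation matrix of the responses:

1. pairwise two-step maximum-likelihood polychoric correlations, with
   thresholds fixed at the inverse-normal marginal category proportions;
2. a one-factor model fitted by unweighted least squares (ULS), with a
   discrepancy-based chi-square scaled by (n - 1) and the usual CFI / TLI /
   RMSEA indices against the independence baseline
   (acceptable fit: CFI/TLI >= 0.90, RMSEA <= 0.08; good: 0.95 / 0.06);
3. local item dependence (LID) flagged where the residual correlation
   (observed polychoric minus model-implied lambda_i * lambda_j) exceeds
   0.2 in absolute value;
4. an iterative prune loop that removes low-loading items (< 0.30) and the
   lower-loading member of each flagged LID pair, refitting between waves,
   until no removals are triggered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bankio import ResponseMatrix

__all__ = [
    "FitIndices", "ScreenConfig", "ScreenReport", "RemovalRecord",
    "PoolExhaustedError", "bivariate_normal_cdf", "polychoric_corr",
    "polychoric_matrix", "fit_unidimensional", "residual_lid_screen",
    "prune_pool",
]

_SQRT2PI_INV = 1.0 / np.sqrt(2.0 * np.pi)
_TAU_CLIP = 8.0  # |threshold| beyond which Phi is 0/1 to double precision


def bivariate_normal_cdf(h, k, rho):
    """Standard bivariate normal CDF via Owen's T function.

    Vectorised over ``h`` and ``k``; ``rho`` is scalar.  Accurate to ~1e-15
    away from |rho| = 1 (validated against scipy's multivariate normal).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -0.99999, 0.99999))
    # avoid exact zeros (the Owen decomposition divides by h and k);
    # the CDF is continuous so a signed nudge is exact to machine precision
    hs = np.where(np.abs(h) < 1e-14, 1e-14, h)
    ks = np.where(np.abs(k) < 1e-14, 1e-14, k)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (ks - rho * hs) / (hs * denom)
    a_k = (hs - rho * ks) / (ks * denom)
    beta = np.where(hs * ks < 0, 0.5, 0.0)
    out = (0.5 * (stats.norm.cdf(hs) + stats.norm.cdf(ks))
           - _owens_t(hs, a_h) - _owens_t(ks, a_k) - beta)
    return np.clip(out, 0.0, 1.0)


def _owens_t(h, a):
    from scipy.special import owens_t
    return owens_t(h, a)


def _thresholds_from_margins(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal thresholds from observed category proportions.

    Returns (unique observed category values, extended threshold vector
    including the -inf/+inf sentinels clipped to +-8).
    """
    x = x[~np.isnan(x)]
    values, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / counts.sum()
    tau = stats.norm.ppf(cum[:-1])
    tau = np.clip(tau, -_TAU_CLIP, _TAU_CLIP)
    return values, np.concatenate([[-_TAU_CLIP], tau, [_TAU_CLIP]])


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    vx, taux = _thresholds_from_margins(x)
    vy, tauy = _thresholds_from_margins(y)
    if len(vx) < 2 or len(vy) < 2:
        raise ValueError("polychoric correlation needs >= 2 observed categories")
    # contingency table
    ix = np.searchsorted(vx, x)
    iy = np.searchsorted(vy, y)
    table = np.zeros((len(vx), len(vy)))
    np.add.at(table, (ix - 0, iy - 0), 1)

    H, K = np.meshgrid(taux, tauy, indexing="ij")

    def nll(rho: float) -> float:
        big = bivariate_normal_cdf(H, K, rho)
        cell = big[1:, 1:] - big[:-1, 1:] - big[1:, :-1] + big[:-1, :-1]
        cell = np.maximum(cell, 1e-12)
        return -float(np.sum(table * np.log(cell)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(data: ResponseMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise polychoric correlation matrix of an ordinal response frame."""
    frame = data.responses if isinstance(data, ResponseMatrix) else data
    cols = list(frame.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 items")
    arr = frame.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        col = arr[:, j]
        if len(np.unique(col[~np.isnan(col)])) < 2:
            raise ValueError(f"item {c!r} has a single observed category")
    p = len(cols)
    R = np.eye(p)
    for i, j in itertools.combinations(range(p), 2):
        R[i, j] = R[j, i] = polychoric_corr(arr[:, i], arr[:, j])
    return pd.DataFrame(R, index=cols, columns=cols)


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    chi_square: float
    df: int

    def acceptable(self, cfi_min: float = 0.90, tli_min: float = 0.90,
                   rmsea_max: float = 0.08) -> bool:
        return (self.cfi >= cfi_min and self.tli >= tli_min
                and self.rmsea <= rmsea_max)


@dataclass
class FactorFit:
    loadings: pd.Series
    indices: FitIndices
    heywood_items: list[str]
    ridge_applied: bool


def _uls_loadings(R: np.ndarray) -> np.ndarray:
    """One-factor loadings minimising sum of squared off-diagonal residuals."""
    p = R.shape[0]
    evals, evecs = np.linalg.eigh(R)
    v = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    if v.sum() < 0:
        v = -v
    start = np.clip(v, -0.98, 0.98)
    mask = ~np.eye(p, dtype=bool)

    def objective(lam: np.ndarray):
        res = (R - np.outer(lam, lam))[mask]
        f = 0.5 * float(res @ res)
        model = np.outer(lam, lam)
        diff = np.where(mask, R - model, 0.0)
        grad = -2.0 * diff @ lam
        return f, grad

    sol = optimize.minimize(objective, start, jac=True, method="L-BFGS-B")
    return sol.x


def fit_unidimensional(corr: pd.DataFrame, n: int) -> FactorFit:
    """Fit a one-factor model by ULS and compute CFI/TLI/RMSEA.

    The discrepancy is the sum of squared off-diagonal residual correlations,
    scaled by (n - 1) into a chi-square-type statistic; the independence
    baseline (all off-diagonals zero) anchors the incremental indices.
    A non-positive-semidefinite input is ridge-repaired (logged on the
    result); Heywood loadings (|lambda| >= 1) are clamped to 0.999 and
    flagged.
    """
    cols = list(corr.columns)
    R = corr.to_numpy(dtype=float).copy()
    p = R.shape[0]
    ridge = False
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < 1e-8:
        R = R + (1e-6 - min_eig) * np.eye(p)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        ridge = True

    lam = _uls_loadings(R)
    heywood = [cols[i] for i in range(p) if abs(lam[i]) >= 1.0]
    lam = np.clip(lam, -0.999, 0.999)

    mask = ~np.eye(p, dtype=bool)
    res = (R - np.outer(lam, lam))[mask]
    f_model = 0.5 * float(res @ res)
    f_base = 0.5 * float(R[mask] @ R[mask])
    df_model = p * (p - 1) // 2 - p
    df_base = p * (p - 1) // 2
    chi2 = (n - 1) * f_model
    chi2_base = (n - 1) * f_base

    d_model = max(chi2 - df_model, 0.0)
    d_base = max(chi2_base - df_base, d_model, 1e-12)
    cfi = 1.0 - d_model / d_base
    if chi2_base > df_base and df_base > 0 and df_model > 0:
        ratio_base = chi2_base / df_base
        ratio_model = chi2 / df_model
        tli = (ratio_base - ratio_model) / (ratio_base - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = 1.0
    rmsea = float(np.sqrt(d_model / (df_model * max(n - 1, 1)))) if df_model > 0 else 0.0

    indices = FitIndices(cfi=float(cfi), tli=float(tli), rmsea=rmsea,
                         chi_square=float(chi2), df=df_model)
    return FactorFit(loadings=pd.Series(lam, index=cols), indices=indices,
                     heywood_items=heywood, ridge_applied=ridge)


def residual_lid_screen(corr: pd.DataFrame, loadings: pd.Series,
                        threshold: float = 0.2) -> list[tuple[str, str, float]]:
    """Flag item pairs whose residual correlation exceeds the LID criterion.

    Residual = observed polychoric minus model-implied lambda_i * lambda_j.
    Pairs with |residual| strictly greater than ``threshold`` (default 0.2)
    are returned sorted by decreasing magnitude.
    """
    cols = list(corr.columns)
    lam = loadings.reindex(cols).to_numpy()
    resid = corr.to_numpy() - np.outer(lam, lam)
    flagged = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        r = float(resid[i, j])
        if abs(r) > threshold:
            flagged.append((cols[i], cols[j], r))
    flagged.sort(key=lambda t: -abs(t[2]))
    return flagged


@dataclass(frozen=True)
class ScreenConfig:
    loading_floor: float = 0.30
    lid_threshold: float = 0.2
    cfi_min: float = 0.90
    tli_min: float = 0.90
    rmsea_max: float = 0.08
    pool_floor: int = 4
    max_waves: int = 20


@dataclass(frozen=True)
class RemovalRecord:
    item_id: str
    wave: int
    reason: str  # one of {"low_loading", "lid", "misfit"}


@dataclass
class ScreenReport:
    retained: list[str]
    removals: list[RemovalRecord]
    final_fit: FitIndices | None
    loadings: pd.Series | None
    lid_pairs: list[tuple[str, str, float]]
    waves: int
    fit_acceptable: bool

    def summary(self) -> str:
        lines = [f"waves: {self.waves}",
                 f"retained: {len(self.retained)} items",
                 f"removed: {len(self.removals)} items"]
        for rec in self.removals:
            lines.append(f"  wave {rec.wave}: {rec.item_id} ({rec.reason})")
        if self.final_fit:
            fi = self.final_fit
            lines.append(
                f"fit: CFI={fi.cfi:.3f} TLI={fi.tli:.3f} RMSEA={fi.rmsea:.3f} "
                f"chi2={fi.chi_square:.1f} df={fi.df}")
        return "\n".join(lines)


class PoolExhaustedError(RuntimeError):
    """Raised when pruning would shrink the pool below the configured floor."""

    def __init__(self, message: str, partial: ScreenReport):
        super().__init__(message)
        self.partial = partial


def prune_pool(data: ResponseMatrix, config: ScreenConfig | None = None) -> ScreenReport:
    """Iterative item-removal loop toward a unidimensional pool.

    Each wave refits the one-factor model, then removes (a) every item whose
    loading falls below the floor and (b) the lower-loading member of each
    flagged LID pair.  The loop stops when a wave triggers no removals; the
    audit trail records every removal with its wave and reason.
    """
    cfg = config or ScreenConfig()
    if len(data.item_ids) < cfg.pool_floor:
        raise ValueError(f"pool must start with >= {cfg.pool_floor} items")
    retained = list(data.item_ids)
    removals: list[RemovalRecord] = []
    fit = None
    lid_pairs: list[tuple[str, str, float]] = []
    wave = 0
    for wave in range(1, cfg.max_waves + 1):
        corr = polychoric_matrix(data.subset_items(retained))
        fit = fit_unidimensional(corr, n=data.n_persons)
        lid_pairs = residual_lid_screen(corr, fit.loadings, cfg.lid_threshold)

        to_remove: dict[str, str] = {}
        for iid, lam in fit.loadings.items():
            if lam < cfg.loading_floor:
                to_remove[iid] = "low_loading"
        for a, b, _r in lid_pairs:
            if a in to_remove or b in to_remove:
                continue  # already going; the pair may resolve itself
            drop = a if fit.loadings[a] <= fit.loadings[b] else b
            to_remove[drop] = "lid"

        if not to_remove:
            break
        if len(retained) - len(to_remove) < cfg.pool_floor:
            partial = ScreenReport(
                retained=retained, removals=removals, final_fit=fit.indices,
                loadings=fit.loadings, lid_pairs=lid_pairs, waves=wave,
                fit_acceptable=fit.indices.acceptable(cfg.cfi_min, cfg.tli_min,
                                                      cfg.rmsea_max))
            raise PoolExhaustedError(
                f"wave {wave} would reduce the pool below {cfg.pool_floor} items",
                partial)
        for iid, reason in to_remove.items():
            removals.append(RemovalRecord(iid, wave, reason))
            retained.remove(iid)

    assert fit is not None
    return ScreenReport(
        retained=retained, removals=removals, final_fit=fit.indices,
        loadings=fit.loadings, lid_pairs=lid_pairs, waves=wave,
        fit_acceptable=fit.indices.acceptable(cfg.cfi_min, cfg.tli_min,
                                              cfg.rmsea_max))
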
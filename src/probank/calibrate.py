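"""Marginal maximum-likelihood (MML-EM) calibration of the GRM.

The marginal likelihood integrates the person parameter out over a fixed
quadrature grid with a standard-normal population distribution (the usual
N(0, 1) identification).  The E-step computes each person's posterior
weights over the grid and accumulates expected category counts per item and
node; the M-step maximises each item's expected complete-data log-likelihood
with the thresholds parameterised as (first threshold + positive
increments), so the estimated category boundaries can never cross.

Standard errors come from the empirical cross-product (outer product of
per-person score vectors) of the marginal log-likelihood.

Item fit uses the summed-score S-X2 statistic: observed category
frequencies within each total-score group are compared with the
model-implied conditional frequencies obtained from the compound-binomial
(Lord-Wingersky) score distribution, with adjacent-cell collapsing to keep
expected counts at or above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bankio import ResponseMatrix
from .grm import ItemBank, ItemParameters, category_probabilities, default_grid

__all__ = ["CalibrationConfig", "CalibrationResult", "fit_grm", "s_x2_item_fit"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationConfig:
    n_quadrature: int = 49
    quad_range: tuple[float, float] = (-6.0, 6.0)
    tol: float = 1e-4            # max absolute parameter change
    max_cycles: int = 500
    min_category_count: int = 10  # sparser categories merge with a neighbour
    compute_se: bool = True


@dataclass
class ConvergenceRecord:
    cycles: int
    max_change: float
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class CalibrationResult:
    bank: ItemBank
    standard_errors: dict[str, np.ndarray]  # per item: (slope, thresholds...)
    log_likelihood: float
    convergence: ConvergenceRecord
    fit_table: pd.DataFrame | None = None
    collapse_log: list[str] = field(default_factory=list)
    category_maps: dict[str, dict[int, int]] = field(default_factory=dict)

    def recode(self, data: ResponseMatrix) -> ResponseMatrix:
        """Apply the calibration's category collapsing to raw responses."""
        frame = data.responses.copy()
        for col in frame.columns:
            remap = self.category_maps.get(col)
            if remap and any(k != v for k, v in remap.items()):
                frame[col] = frame[col].map(
                    lambda v: np.nan if pd.isna(v) else remap[int(v)])
        return ResponseMatrix(frame, data.covariates)


def _collapse_sparse(responses: pd.DataFrame, min_count: int
                     ) -> tuple[pd.DataFrame, list[str], dict[str, dict[int, int]]]:
    """Merge categories observed fewer than ``min_count`` times with a neighbour.

    Returns recoded responses (categories 1..m', consecutive), a human-readable
    log, and per-item original->recoded category maps.
    """
    out = responses.copy()
    logs: list[str] = []
    maps: dict[str, dict[int, int]] = {}
    for col in out.columns:
        x = out[col]
        counts = x.value_counts().sort_index()
        cats = [int(c) for c in counts.index]
        merged = {c: [c] for c in cats}
        order = sorted(merged)
        # repeatedly merge the sparsest offending category into its neighbour
        def total(c):
            return sum(counts[k] for k in merged[c])
        changed = True
        while changed and len(order) > 2:
            changed = False
            for c in sorted(order, key=total):
                if total(c) < min_count:
                    idx = order.index(c)
                    nb = order[idx - 1] if idx > 0 else order[idx + 1]
                    merged[nb].extend(merged.pop(c))
                    order.remove(c)
                    logs.append(f"{col}: merged category {c} into {nb} "
                                f"(count {counts[c]})")
                    changed = True
                    break
        remap: dict[int, int] = {}
        for new_code, c in enumerate(sorted(order), start=1):
            for orig in merged[c]:
                remap[orig] = new_code
        maps[col] = remap
        if any(k != v for k, v in remap.items()):
            out[col] = x.map(lambda v: np.nan if pd.isna(v) else remap[int(v)])
    return out, logs, maps


def _item_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Category probabilities on the grid: shape (m, Q)."""
    pstar = 1.0 / (1.0 + np.exp(-a * (nodes[None, :] - b[:, None])))
    upper = np.vstack([np.ones((1, nodes.size)), pstar])
    lower = np.vstack([pstar, np.zeros((1, nodes.size))])
    return np.clip(upper - lower, 1e-10, 1.0)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    """(a, b_1..b_{m-1}) -> unconstrained (log a, b_1, log diffs)."""
    d = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(d, 1e-6))])


def _unpack(eta: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(np.clip(eta[0], -5, 3)))
    b1 = eta[1]
    diffs = np.exp(np.clip(eta[2:], -10, 3))
    b = b1 + np.concatenate([[0.0], np.cumsum(diffs)])
    return a, b


def _mstep_objective(eta: np.ndarray, r: np.ndarray, nodes: np.ndarray):
    """Negative expected complete-data log-likelihood for one item + gradient.

    ``r`` is the (m, Q) table of expected category counts at each node.
    """
    a, b = _unpack(eta)
    m = r.shape[0]
    pstar = 1.0 / (1.0 + np.exp(-a * (nodes[None, :] - b[:, None])))  # (m-1, Q)
    upper = np.vstack([np.ones((1, nodes.size)), pstar])
    lower = np.vstack([pstar, np.zeros((1, nodes.size))])
    P = np.clip(upper - lower, 1e-10, 1.0)                            # (m, Q)
    f = -float(np.sum(r * np.log(P)))

    w = r / P                                                         # (m, Q)
    pq = pstar * (1.0 - pstar)                                        # (m-1, Q)
    # P_k = P*_{k-1} - P*_k, so boundary k enters P_k with -1 and P_{k+1} with +1:
    # dG/db_k = sum_q dP*_k/db_k * (w_{k+1} - w_k),  dP*_k/db_k = -a pq
    dG_db = np.sum((-a * pq) * (w[1:] - w[:-1]), axis=1)
    # dG/da = sum_q sum_k w_k (dP*_{k-1}/da - dP*_k/da), dP*_k/da = (x-b_k) pq
    dstar_da = (nodes[None, :] - b[:, None]) * pq                     # (m-1, Q)
    upper_da = np.vstack([np.zeros((1, nodes.size)), dstar_da])
    lower_da = np.vstack([dstar_da, np.zeros((1, nodes.size))])
    dG_da = float(np.sum(w * (upper_da - lower_da)))

    # chain rule to eta = (log a, b1, log diffs)
    g = np.empty_like(eta)
    g[0] = -dG_da * a
    g[1] = -float(dG_db.sum())
    diffs = np.diff(b)
    for i in range(len(diffs)):
        g[2 + i] = -float(dG_db[i + 1:].sum()) * diffs[i]
    return f, g


def _start_values(x: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    """Crude starts: slope 1, thresholds at logistic quantiles of the margins."""
    obs = x[x >= 0]
    props = np.array([(obs >= k).mean() for k in range(1, m)])
    props = np.clip(props, 0.02, 0.98)
    b = -np.log(props / (1 - props))
    b = np.sort(b)
    for i in range(1, b.size):
        b[i] = max(b[i], b[i - 1] + 1e-3)
    return 1.0, b


def fit_grm(data: ResponseMatrix, config: CalibrationConfig | None = None,
            metric_name: str = "calibrated") -> CalibrationResult:
    """Calibrate a GRM item bank by MML-EM with N(0, 1) identification.

    Missing responses are treated as ignorable (they simply contribute no
    likelihood term for that item).  Categories observed fewer than
    ``config.min_category_count`` times are merged with an adjacent category
    before estimation (logged on the result).  Non-convergence at the cycle
    cap yields a flagged result, not an exception.
    """
    cfg = config or CalibrationConfig()
    if data.n_persons < 100:
        log.warning("calibration sample n=%d < 100; estimates may be unstable",
                    data.n_persons)
    frame, collapse_log, cat_maps = _collapse_sparse(
        data.responses, cfg.min_category_count)
    item_ids = list(frame.columns)
    n, J = frame.shape
    # integer codes 0..m-1, -1 for missing
    X = np.full((n, J), -1, dtype=int)
    m_of = {}
    for j, col in enumerate(item_ids):
        v = frame[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        X[ok, j] = v[ok].astype(int) - 1
        m_of[col] = int(np.nanmax(v))

    grid = default_grid(cfg.n_quadrature, *cfg.quad_range)
    nodes, wq = grid.nodes, grid.weights

    a_est = np.ones(J)
    b_est: list[np.ndarray] = []
    for j, col in enumerate(item_ids):
        a0, b0 = _start_values(X[:, j], m_of[col])
        b_est.append(b0)

    trace: list[float] = []
    max_change = np.inf
    cycle = 0
    for cycle in range(1, cfg.max_cycles + 1):
        # E-step
        logL = np.zeros((n, nodes.size))
        tables = []
        for j in range(J):
            P = _item_prob_table(a_est[j], b_est[j], nodes)
            tables.append(P)
            resp = X[:, j]
            ok = resp >= 0
            logL[ok] += np.log(P[resp[ok], :])
        post = np.exp(logL - logL.max(axis=1, keepdims=True)) * wq[None, :]
        marg = post.sum(axis=1)
        ll = float(np.sum(np.log(marg) + logL.max(axis=1)))
        trace.append(ll)
        W = post / marg[:, None]

        # M-step
        max_change = 0.0
        for j in range(J):
            resp = X[:, j]
            m = m_of[item_ids[j]]
            r = np.zeros((m, nodes.size))
            for k in range(m):
                sel = resp == k
                if sel.any():
                    r[k] = W[sel].sum(axis=0)
            eta0 = _pack(a_est[j], b_est[j])
            sol = optimize.minimize(_mstep_objective, eta0, args=(r, nodes),
                                    jac=True, method="L-BFGS-B",
                                    options={"maxiter": 50})
            a_new, b_new = _unpack(sol.x)
            max_change = max(max_change, abs(a_new - a_est[j]),
                             float(np.max(np.abs(b_new - b_est[j]))))
            a_est[j], b_est[j] = a_new, b_new

        if max_change < cfg.tol:
            break

    converged = max_change < cfg.tol
    if not converged:
        log.warning("EM reached cycle cap %d (max change %.2e)",
                    cfg.max_cycles, max_change)

    items = tuple(
        ItemParameters(item_ids[j], float(a_est[j]), tuple(b_est[j]))
        for j in range(J))
    bank = ItemBank(items, metric_name=metric_name)

    ses: dict[str, np.ndarray] = {}
    if cfg.compute_se:
        ses = _empirical_ses(X, item_ids, a_est, b_est, nodes, wq)

    return CalibrationResult(
        bank=bank, standard_errors=ses,
        log_likelihood=trace[-1] if trace else float("nan"),
        convergence=ConvergenceRecord(cycles=cycle, max_change=float(max_change),
                                      converged=converged, loglik_trace=trace),
        collapse_log=collapse_log, category_maps=cat_maps)


def _empirical_ses(X, item_ids, a_est, b_est, nodes, wq) -> dict[str, np.ndarray]:
    """SEs from the empirical cross-product of per-person score vectors.

    Per-person gradients of the marginal log-likelihood are computed by
    central differences, exploiting the product structure: perturbing one
    item only rescales that item's contribution to the grid likelihood.
    """
    n, J = X.shape
    contrib = []   # per item: (n, Q) probability of the observed response
    for j in range(J):
        P = _item_prob_table(a_est[j], b_est[j], nodes)
        resp = X[:, j]
        C = np.ones((n, nodes.size))
        ok = resp >= 0
        C[ok] = P[resp[ok], :]
        contrib.append(C)
    L = np.ones((n, nodes.size))
    for C in contrib:
        L = L * C
    base = (L * wq[None, :]).sum(axis=1)

    h = 1e-4
    grads = []
    layout: list[tuple[str, int]] = []
    for j in range(J):
        params = np.concatenate([[a_est[j]], b_est[j]])
        for p_idx in range(params.size):
            g = np.zeros(n)
            vals = []
            for sgn in (+1, -1):
                pert = params.copy()
                pert[p_idx] += sgn * h
                Pp = _item_prob_table(pert[0], pert[1:], nodes)
                resp = X[:, j]
                Cp = np.ones((n, nodes.size))
                ok = resp >= 0
                Cp[ok] = Pp[resp[ok], :]
                Lp = L / np.maximum(contrib[j], 1e-300) * Cp
                vals.append((Lp * wq[None, :]).sum(axis=1))
            g = (np.log(vals[0]) - np.log(vals[1])) / (2 * h)
            grads.append(g)
            layout.append((item_ids[j], p_idx))
    G = np.stack(grads, axis=1)                  # (n, n_params)
    info = G.T @ G
    # guard against singular information (e.g. tiny n)
    try:
        cov = np.linalg.inv(info)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(layout), np.nan)
    out: dict[str, np.ndarray] = {}
    for (iid, _p), se in zip(layout, se_all):
        out.setdefault(iid, []).append(se)
    return {iid: np.asarray(v) for iid, v in out.items()}


# ---------------------------------------------------------------------------
# S-X2 item fit
# ---------------------------------------------------------------------------

def _score_distribution(tables: list[np.ndarray]) -> np.ndarray:
    """Lord-Wingersky recursion: distribution of the summed item score.

    Each table has shape (m_j, Q); item scores are 0..m_j-1.  Returns
    shape (S_max + 1, Q).
    """
    Q = tables[0].shape[1]
    f = np.ones((1, Q))
    for P in tables:
        m = P.shape[0]
        new = np.zeros((f.shape[0] + m - 1, Q))
        for k in range(m):
            new[k:k + f.shape[0]] += f * P[k][None, :]
        f = new
    return f


def s_x2_item_fit(result: CalibrationResult, data: ResponseMatrix,
                  config: CalibrationConfig | None = None) -> pd.DataFrame:
    """Orlando-Thissen S-X2 fit statistic for every calibrated item.

    Persons with any missing response are excluded (the statistic is defined
    on complete summed scores).  Within each total-score group, adjacent
    category cells are collapsed until every expected count is >= 1; score
    groups left with a single cell are dropped.  Items whose usable score
    range is too narrow are skipped with a log entry.
    """
    cfg = config or CalibrationConfig()
    bank = result.bank
    item_ids = list(bank.item_ids)
    frame = data.responses[item_ids].dropna()
    if result.category_maps:
        frame = frame.copy()
        for col in item_ids:
            remap = result.category_maps.get(col)
            if remap and any(k != v for k, v in remap.items()):
                frame[col] = frame[col].map(lambda v: remap[int(v)])
    n = len(frame)
    X = frame.to_numpy(dtype=int) - 1   # item scores 0..m-1

    grid = default_grid(cfg.n_quadrature, *cfg.quad_range)
    nodes, wq = grid.nodes, grid.weights
    tables = [
        _item_prob_table(it.slope, np.asarray(it.thresholds), nodes)
        for it in bank]

    total = X.sum(axis=1)
    f_all = _score_distribution(tables)                    # (S+1, Q)
    marg_all = f_all @ wq                                  # P(S = s)

    rows = []
    for j, item in enumerate(bank):
        m = tables[j].shape[0]
        others = [tables[t] for t in range(len(tables)) if t != j]
        f_rest = _score_distribution(others)               # (S-m+2, Q)
        S_max = f_all.shape[0] - 1
        # E[category k | total score s]
        E = np.zeros((S_max + 1, m))
        for k in range(m):
            num = np.zeros(S_max + 1)
            lo, hi = k, k + f_rest.shape[0] - 1
            num[lo:hi + 1] = (f_rest * tables[j][k][None, :]) @ wq
            with np.errstate(invalid="ignore", divide="ignore"):
                E[:, k] = np.where(marg_all > 1e-12, num / marg_all, 0.0)

        chi2 = 0.0
        cells = 0
        groups = 0
        for s in range(S_max + 1):
            n_s = int((total == s).sum())
            if n_s == 0:
                continue
            obs = np.array([int(((total == s) & (X[:, j] == k)).sum())
                            for k in range(m)], dtype=float)
            exp = n_s * E[s]
            # collapse adjacent cells until all expected >= 1
            o, e = list(obs), list(exp)
            while len(e) > 1 and min(e) < 1.0:
                i_min = int(np.argmin(e))
                nb = i_min - 1 if i_min > 0 else i_min + 1
                ev, ov = e.pop(i_min), o.pop(i_min)
                nb = nb if nb < i_min else nb - 1
                e[nb] += ev
                o[nb] += ov
            if len(e) < 2 or sum(e) <= 0:
                continue
            groups += 1
            cells += len(e)
            chi2 += float(sum((oo - ee) ** 2 / max(ee, 1e-12)
                              for oo, ee in zip(o, e)))
        n_params = m  # slope + (m-1) thresholds
        df = cells - groups - n_params
        if groups < 2 or df < 1:
            log.info("S-X2 skipped for %s: too few usable score groups",
                     item.item_id)
            rows.append({"item_id": item.item_id, "s_x2": np.nan,
                         "df": np.nan, "p": np.nan, "skipped": True})
            continue
        p = float(stats.chi2.sf(chi2, df))
        rows.append({"item_id": item.item_id, "s_x2": chi2, "df": df,
                     "p": p, "skipped": False})
    table = pd.DataFrame(rows).set_index("item_id")
    result.fit_table = table
    return table
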
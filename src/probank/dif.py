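"""Differential item functioning screen via ordinal logistic regression.

For each item and grouping variable, three nested cumulative-logit models of
the item response are compared:

    M1: response ~ trait
    M2: response ~ trait + group
    M3: response ~ trait + group + trait x group

Likelihood-ratio tests of M2 vs M1 (uniform DIF) and M3 vs M2 (non-uniform
DIF) are reported alongside the joint M3 vs M1 test.  An item is flagged
when the joint test is significant (default p < 0.01) AND the McFadden
pseudo-R-squared gain exceeds a salience threshold (default 0.02) — the
usual two-criterion rule for this family of screens, since at field-test
sample sizes trivially small DIF is otherwise significant.

Trait matching uses model-based EAP scores rather than raw sums.  Flagged
items are reported, never auto-removed; an optional purification loop
re-scores on the non-flagged items and repeats the screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .bankio import ResponseMatrix
from .grm import ItemBank, category_probabilities, default_grid

__all__ = ["DifConfig", "dif_screen", "dif_screen_all", "eap_traits"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifConfig:
    p_threshold: float = 0.01
    r2_threshold: float = 0.02
    min_group_size: int = 50
    purify: bool = False
    max_purify_iter: int = 3


def eap_traits(data: ResponseMatrix, bank: ItemBank) -> pd.Series:
    """EAP theta for every person, for trait matching.

    Vectorised over persons on the default quadrature grid; equivalent to
    calling :func:`probank.grm.eap_score` per person.
    """
    grid = default_grid()
    nodes, wq = grid.nodes, grid.weights
    n = data.n_persons
    logL = np.zeros((n, nodes.size))
    for it in bank:
        col = data.responses[it.item_id].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        P = np.log(np.maximum(category_probabilities(nodes, it), 1e-300))
        logL[ok] += P[col[ok].astype(int) - 1, :]
    post = np.exp(logL - logL.max(axis=1, keepdims=True)) * wq[None, :]
    post /= post.sum(axis=1, keepdims=True)
    out = post @ nodes
    return pd.Series(out, index=data.responses.index, name="theta")


def _fit_ordinal(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Cumulative-logit fit; returns (log-likelihood, n_model_params)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, X, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=200)
    return float(res.llf), X.shape[1]


def dif_screen(data: ResponseMatrix, trait: pd.Series, variable: str,
               config: DifConfig | None = None,
               items: list[str] | None = None) -> pd.DataFrame | None:
    """Screen every item for DIF on one grouping variable.

    Returns a table indexed by item with LR statistics, p-values, the
    McFadden pseudo-R-squared change, and the flag; returns None (with a log
    entry) when the variable is degenerate (fewer than two usable levels).
    """
    cfg = config or DifConfig()
    if data.covariates is None or variable not in data.covariates.columns:
        raise KeyError(f"covariate {variable!r} not present")
    group_raw = data.covariates[variable]
    levels = [lv for lv, cnt in group_raw.value_counts().items()
              if cnt >= cfg.min_group_size]
    if len(levels) < 2:
        log.info("DIF screen skipped for %r: fewer than 2 usable levels",
                 variable)
        return None
    keep = group_raw.isin(levels)
    item_ids = items or data.item_ids

    rows = []
    for iid in item_ids:
        y_full = data.responses[iid]
        ok = keep & y_full.notna() & trait.notna()
        y = y_full[ok].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            continue
        th = trait[ok].to_numpy()
        g = pd.get_dummies(group_raw[ok], drop_first=True).to_numpy(dtype=float)
        inter = th[:, None] * g

        ll1, k1 = _fit_ordinal(y, th[:, None])
        ll2, k2 = _fit_ordinal(y, np.column_stack([th, g]))
        ll3, k3 = _fit_ordinal(y, np.column_stack([th, g, inter]))
        # null (intercepts-only) log-likelihood for McFadden R2
        counts = np.bincount(y - y.min())
        p0 = counts[counts > 0] / counts.sum()
        ll0 = float(np.sum(counts[counts > 0] * np.log(p0)))

        lr_unif = max(2.0 * (ll2 - ll1), 0.0)
        lr_nonunif = max(2.0 * (ll3 - ll2), 0.0)
        lr_joint = max(2.0 * (ll3 - ll1), 0.0)
        df_g = g.shape[1]
        p_unif = float(stats.chi2.sf(lr_unif, df_g))
        p_nonunif = float(stats.chi2.sf(lr_nonunif, df_g))
        p_joint = float(stats.chi2.sf(lr_joint, 2 * df_g))
        r2_1 = 1.0 - ll1 / ll0
        r2_3 = 1.0 - ll3 / ll0
        dr2 = r2_3 - r2_1
        flag = bool(p_joint < cfg.p_threshold and dr2 >= cfg.r2_threshold)
        rows.append({
            "item_id": iid, "variable": variable,
            "lr_uniform": lr_unif, "p_uniform": p_unif,
            "lr_nonuniform": lr_nonunif, "p_nonuniform": p_nonunif,
            "lr_joint": lr_joint, "df_joint": 2 * df_g, "p_joint": p_joint,
            "pseudo_r2_change": dr2, "flag": flag,
        })
    return pd.DataFrame(rows).set_index("item_id")


def dif_screen_all(data: ResponseMatrix, bank: ItemBank,
                   variables: list[str] | None = None,
                   config: DifConfig | None = None) -> pd.DataFrame:
    """Screen all items over all (or the given) covariates.

    With ``config.purify`` set, items flagged in a pass are dropped from the
    trait-scoring bank and the screen repeats until no new flags or the
    iteration cap.
    """
    cfg = config or DifConfig()
    if data.covariates is None:
        raise ValueError("data has no covariates")
    variables = variables or [
        c for c in data.covariates.columns if c != "true_theta"]
    scoring_ids = list(bank.item_ids)
    for iteration in range(cfg.max_purify_iter if cfg.purify else 1):
        trait = eap_traits(data.subset_items(scoring_ids),
                           bank.subset(scoring_ids))
        pieces = []
        for var in variables:
            rep = dif_screen(data, trait, var, cfg)
            if rep is not None:
                pieces.append(rep.reset_index())
        report = pd.concat(pieces, ignore_index=True)
        flagged = sorted(set(report.loc[report["flag"], "item_id"]))
        if not cfg.purify:
            break
        cleaned = [i for i in scoring_ids if i not in flagged]
        if cleaned == scoring_ids or len(cleaned) < 2:
            break
        scoring_ids = cleaned
    return report.set_index(["item_id", "variable"])
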
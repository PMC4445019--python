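"""Stocking-Lord linking of a new calibration onto a reference metric.

When a new instrument shares anchor items with an established bank (e.g. a
PROMIS- or Neuro-QOL-style reference), the new metric can be aligned with
the reference by a linear transformation theta_ref = A * theta_new + B.
Stocking and Lord's method chooses (A, B) to minimise the integrated squared
difference between the anchor set's test characteristic curves (expected
summed scores) computed from the reference parameters and from the
transformed new parameters, over a weighted theta grid.

The transformation direction is one-way (new onto reference), matching how
disease-specific banks are placed on a general-population metric: slopes
divide by A, thresholds map b -> A*b + B, and person scores map
theta -> A*theta + B, leaving every category probability invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .grm import ItemBank, ItemParameters, category_probabilities

__all__ = ["LinkingConstants", "stocking_lord", "transform_bank",
           "transform_theta", "default_linking_grid"]


@dataclass(frozen=True)
class LinkingConstants:
    A: float
    B: float
    anchor_ids: tuple[str, ...]
    criterion: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")


def default_linking_grid(n_points: int = 161, lo: float = -4.0, hi: float = 4.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Theta grid weighted by the reference-population standard normal density."""
    nodes = np.linspace(lo, hi, n_points)
    w = stats.norm.pdf(nodes)
    return nodes, w / w.sum()


def _expected_score(items: list[ItemParameters], theta: np.ndarray) -> np.ndarray:
    """Anchor-set test characteristic curve with item scores 0..m-1."""
    total = np.zeros(theta.size)
    for it in items:
        probs = category_probabilities(theta, it)
        scores = np.arange(it.n_categories)
        total += scores @ probs
    return total


def stocking_lord(new_bank: ItemBank, ref_bank: ItemBank,
                  grid: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> LinkingConstants:
    """Estimate (A, B) aligning the new bank's anchors with the reference.

    Anchors are the items whose ids appear in both banks (>= 2 required, with
    matching category counts).  The criterion integrates the squared TCC
    difference over the weighted grid; optimisation is a derivative-free
    simplex search started from the identity (1, 0).
    """
    common = [iid for iid in new_bank.item_ids if iid in ref_bank.item_ids]
    if len(common) < 2:
        raise ValueError(f"need >= 2 anchor items, found {len(common)}")
    new_items = [new_bank.item(i) for i in common]
    ref_items = [ref_bank.item(i) for i in common]
    for ni, ri in zip(new_items, ref_items):
        if ni.n_categories != ri.n_categories:
            raise ValueError(
                f"anchor {ni.item_id!r}: category counts differ "
                f"({ni.n_categories} vs {ri.n_categories})")
    nodes, w = grid if grid is not None else default_linking_grid()
    tcc_ref = _expected_score(ref_items, nodes)

    def criterion(x: np.ndarray) -> float:
        A, B = np.exp(x[0]), x[1]
        transformed = [
            ItemParameters(it.item_id, it.slope / A,
                           tuple(A * b + B for b in it.thresholds))
            for it in new_items]
        tcc_new = _expected_score(transformed, nodes)
        return float(w @ (tcc_ref - tcc_new) ** 2)

    sol = optimize.minimize(criterion, np.array([0.0, 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12,
                                     "maxiter": 2000})
    A, B = float(np.exp(sol.x[0])), float(sol.x[1])
    return LinkingConstants(A=A, B=B, anchor_ids=tuple(common),
                            criterion=float(sol.fun), converged=bool(sol.success))


def transform_bank(bank: ItemBank, constants: LinkingConstants,
                   metric_name: str | None = None) -> ItemBank:
    """Place a bank on the reference metric: a -> a/A, b -> A*b + B."""
    A, B = constants.A, constants.B
    items = tuple(
        ItemParameters(it.item_id, it.slope / A,
                       tuple(A * b + B for b in it.thresholds))
        for it in bank)
    return replace(bank, items=items,
                   metric_name=metric_name or f"{bank.metric_name}->linked")


def transform_theta(theta, constants: LinkingConstants):
    """Map person scores onto the reference metric: theta -> A*theta + B."""
    return constants.A * np.asarray(theta, dtype=float) + constants.B
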
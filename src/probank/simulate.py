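"""Synthetic response-data generation for pipeline testing.

Field-test samples behind published PRO item banks are rarely public, so
this module generates data with the statistical structure the pipeline
assumes and lets every downstream screen be exercised against known truth:

* a heterogeneous latent trait (default theta ~ N(0, 1), n = 877 — a
  calibration-study-sized sample) responding to a 5-category GRM bank with
  PROMIS-like parameter ranges (slopes ~ logNormal(ln 1.7, 0.35),
  thresholds spread over [-2.5, 2.5]);
* six categorical person covariates of the kind DIF screens condition on
  (age group, sex, education, diagnosis, completeness of injury, time
  since injury), assigned independently of theta so that injected DIF is
  never confounded with impact;
* optional local-dependence (LID) contamination via a shared item-specific
  factor, so marginal item distributions stay near-model while conditional
  dependence at fixed theta is violated;
* optional uniform DIF via group-specific threshold shifts;
* two-population anchor designs with known linking constants for
  Stocking-Lord recovery studies.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bankio import ResponseMatrix
from .grm import ItemBank, ItemParameters, category_probabilities

__all__ = [
    "SimulationDesign", "DifSpec", "LidSpec",
    "make_bank", "default_design", "simulate_responses",
    "inject_lid", "inject_dif", "make_linking_design",
    "DEFAULT_COVARIATES",
]

# Binary grouping variables mirroring the covariates a spinal-cord-injury
# field study would stratify DIF analyses on.
DEFAULT_COVARIATES: dict[str, tuple[str, ...]] = {
    "age_group": ("younger", "older"),
    "sex": ("male", "female"),
    "education": ("hs_or_less", "beyond_hs"),
    "diagnosis": ("paraplegia", "tetraplegia"),
    "completeness": ("complete", "incomplete"),
    "time_since_injury": ("lt_1yr", "ge_1yr"),
}


@dataclass(frozen=True)
class DifSpec:
    """Uniform DIF: shift the item's thresholds for one covariate group."""

    item_id: str
    variable: str
    group: str
    threshold_shift: float = 0.0
    slope_ratio: float = 1.0


@dataclass(frozen=True)
class LidSpec:
    """Local dependence: a shared specific factor for one item pair.

    ``strength`` is the proportion of each paired item's latent input
    variance contributed by the shared specific factor, in [0, 1).
    """

    pair: tuple[str, str]
    strength: float

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("LID pair must be two distinct items")
        if not 0.0 <= self.strength < 1.0:
            raise ValueError(f"LID strength must be in [0, 1), got {self.strength}")


@dataclass(frozen=True)
class SimulationDesign:
    bank: ItemBank
    n_persons: int = 877
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    covariates: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    dif_specs: tuple[DifSpec, ...] = ()
    lid_specs: tuple[LidSpec, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def make_bank(n_items: int = 30, n_categories: int = 5, seed: int = 0,
              slope_logmean: float = float(np.log(1.7)),
              slope_logsd: float = 0.35,
              threshold_range: tuple[float, float] = (-2.5, 2.5),
              metric_name: str = "reference") -> ItemBank:
    """Random PROMIS-like GRM bank: logNormal slopes, sorted uniform thresholds."""
    rng = np.random.default_rng(seed)
    items = []
    lo, hi = threshold_range
    for j in range(n_items):
        slope = float(rng.lognormal(slope_logmean, slope_logsd))
        raw = np.sort(rng.uniform(lo, hi, size=n_categories - 1))
        # enforce a minimal inter-threshold gap so categories stay usable
        for i in range(1, raw.size):
            raw[i] = max(raw[i], raw[i - 1] + 0.15)
        items.append(ItemParameters(f"item{j + 1:03d}", slope, tuple(raw)))
    return ItemBank(tuple(items), metric_name=metric_name)


def default_design(seed: int = 0, n_items: int = 30) -> SimulationDesign:
    """Calibration-study-like default: n = 877 on a 5-category synthetic bank."""
    return SimulationDesign(bank=make_bank(n_items=n_items, seed=seed), seed=seed)


def _draw_categories(rng: np.random.Generator, item: ItemParameters,
                     theta: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw from the item's category probabilities."""
    probs = category_probabilities(theta, item)        # (m, n)
    cum = np.cumsum(probs, axis=0)
    u = rng.uniform(size=theta.size)
    return (u[None, :] > cum).sum(axis=0) + 1          # categories 1..m


def _make_covariates(rng: np.random.Generator, n: int,
                     covariates: Mapping[str, tuple[str, ...]]) -> pd.DataFrame:
    cols = {}
    for name, levels in covariates.items():
        cols[name] = rng.choice(levels, size=n)
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="person_id"))


def simulate_responses(design: SimulationDesign,
                       thetas: np.ndarray | None = None) -> ResponseMatrix:
    """Draw a ResponseMatrix from the design's GRM bank.

    Responses for each person are conditionally independent given theta
    except where ``lid_specs`` introduce a shared specific factor, and follow
    the bank parameters except where ``dif_specs`` shift them for a covariate
    group.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_persons
    if thetas is None:
        thetas = rng.normal(design.theta_mean, design.theta_sd, size=n)
    else:
        thetas = np.asarray(thetas, dtype=float)
        if thetas.size != n:
            raise ValueError("thetas length must equal n_persons")
    cov = _make_covariates(rng, n, design.covariates)

    # shared specific factors for LID pairs
    lid_of_item: dict[str, tuple[LidSpec, np.ndarray]] = {}
    for spec in design.lid_specs:
        for iid in spec.pair:
            if iid not in design.bank.item_ids:
                raise KeyError(f"LID item {iid!r} not in bank")
        if spec.strength == 0.0:
            continue  # exact no-op: leave the response stream untouched
        shared = rng.normal(size=n)
        for iid in spec.pair:
            lid_of_item[iid] = (spec, shared)

    dif_of_item: dict[str, DifSpec] = {}
    for spec in design.dif_specs:
        if spec.variable not in cov.columns:
            raise KeyError(f"DIF variable {spec.variable!r} not a design covariate")
        if spec.group not in design.covariates[spec.variable]:
            raise KeyError(
                f"DIF group {spec.group!r} not a level of {spec.variable!r}")
        if spec.threshold_shift == 0.0 and spec.slope_ratio == 1.0:
            continue  # exact no-op
        dif_of_item[spec.item_id] = spec

    data = {}
    for item in design.bank:
        eff_theta = thetas
        if item.item_id in lid_of_item:
            spec, shared = lid_of_item[item.item_id]
            s = spec.strength
            eff_theta = np.sqrt(1.0 - s) * thetas + np.sqrt(s) * shared
        if item.item_id in dif_of_item:
            spec = dif_of_item[item.item_id]
            focal = (cov[spec.variable] == spec.group).to_numpy()
            shifted = ItemParameters(
                item.item_id,
                item.slope * spec.slope_ratio,
                tuple(b + spec.threshold_shift for b in item.thresholds),
            )
            resp = np.empty(n, dtype=float)
            if (~focal).any():
                resp[~focal] = _draw_categories(rng, item, eff_theta[~focal])
            if focal.any():
                resp[focal] = _draw_categories(rng, shifted, eff_theta[focal])
        else:
            resp = _draw_categories(rng, item, eff_theta).astype(float)
        data[item.item_id] = resp

    frame = pd.DataFrame(data, index=cov.index)
    if design.missing_rate > 0:
        mask = rng.uniform(size=frame.shape) < design.missing_rate
        frame = frame.mask(mask)
    cov = cov.assign(true_theta=thetas)
    return ResponseMatrix(frame, cov)


def inject_lid(design: SimulationDesign, pair: tuple[str, str],
               strength: float) -> ResponseMatrix:
    """Simulate with a shared specific factor added to one item pair."""
    spec = LidSpec(pair=tuple(pair), strength=strength)
    return simulate_responses(replace(design, lid_specs=design.lid_specs + (spec,)))


def inject_dif(design: SimulationDesign, item_id: str, variable: str,
               group: str, shift: float, slope_ratio: float = 1.0) -> ResponseMatrix:
    """Simulate with uniform DIF (threshold shift) on one item for one group.

    Group theta distributions are kept identical, so a flagged item reflects
    DIF rather than impact.
    """
    spec = DifSpec(item_id=item_id, variable=variable, group=group,
                   threshold_shift=shift, slope_ratio=slope_ratio)
    return simulate_responses(replace(design, dif_specs=design.dif_specs + (spec,)))


def transform_item(item: ItemParameters, A: float, B: float) -> ItemParameters:
    """Express an item on a metric where theta_ref = A * theta_new + B."""
    return ItemParameters(item.item_id, item.slope * A,
                          tuple((b - B) / A for b in item.thresholds))


def make_linking_design(anchor_bank: ItemBank,
                        unique_items: Sequence[ItemParameters],
                        A: float, B: float,
                        n_per_group: int = 2000,
                        seed: int = 0) -> tuple[ResponseMatrix, ResponseMatrix, dict]:
    """Two-population anchor design with known linking constants.

    Population 1 responds to the anchor items (plus any reference-side
    uniques) on the reference metric.  Population 2 responds to the anchors
    expressed on a new metric related to the reference by
    ``theta_ref = A * theta_new + B`` plus the new-instrument unique items;
    both populations are N(0, 1) on their own metric.  The returned truth
    record carries (A, B) for recovery tests.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    if len(anchor_bank) < 1:
        raise ValueError("anchor set must be non-empty")
    new_items = tuple(transform_item(it, A, B) for it in anchor_bank) + tuple(
        transform_item(it, A, B) for it in unique_items)
    new_bank = ItemBank(new_items, metric_name="new")

    ref_design = SimulationDesign(bank=anchor_bank, n_persons=n_per_group,
                                  seed=seed)
    new_design = SimulationDesign(bank=new_bank, n_persons=n_per_group,
                                  seed=seed + 1)
    truth = {"A": A, "B": B, "anchor_ids": list(anchor_bank.item_ids)}
    return simulate_responses(ref_design), simulate_responses(new_design), truth
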
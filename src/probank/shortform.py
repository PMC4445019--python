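"""Fixed short-form construction by the quintile-location / max-slope rule.

Items are ranked into five quintiles by location (the mean of an item's
category thresholds) and, within each quintile, the one or two items with
the highest slope are chosen.  Taking one per quintile covers the trait
continuum; expanding the extreme quintiles first keeps measurement precision
at the tails, where fixed forms are weakest.  The default target is 8 items
and the selected size always lies in the conventional 7-10 band.

Selection here is purely algorithmic; the clinical-review pass that real
instrument development adds on top (wording, redundancy, relevance) is
supported only through the pin/ban override lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import ItemBank

__all__ = ["ShortFormConfig", "select_short_form"]


@dataclass(frozen=True)
class ShortFormConfig:
    target_size: int = 8
    min_size: int = 7
    max_size: int = 10
    max_per_quintile: int = 2
    pinned: tuple[str, ...] = ()
    banned: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.min_size <= self.target_size <= self.max_size:
            raise ValueError("need min_size <= target_size <= max_size")


def select_short_form(bank: ItemBank, config: ShortFormConfig | None = None
                      ) -> tuple[list[str], pd.DataFrame]:
    """Select a short form and return (item ids, audit table).

    The audit table lists every candidate item with its location, slope,
    quintile, and whether/why it was selected.  Quintile boundaries are by
    rank (equal counts, ties to the lower quintile).  Slope ties within a
    quintile go to the lower item id.

    Raises ``ValueError`` for banks under 10 items — pools that small are
    better treated as fixed scales administered in full.
    """
    cfg = config or ShortFormConfig()
    candidates = [it for it in bank if it.item_id not in cfg.banned]
    if len(bank) < 10:
        raise ValueError(
            f"bank has {len(bank)} items; short-form selection needs >= 10 — "
            "administer a pool this small as a fixed scale instead")

    locations = {it.item_id: float(np.mean(it.thresholds)) for it in candidates}
    # rank-based quintiles, stable sort so location ties keep id order
    order = sorted(candidates, key=lambda it: (locations[it.item_id], it.item_id))
    quintile_of: dict[str, int] = {}
    splits = np.array_split(np.arange(len(order)), 5)
    for q, idx in enumerate(splits, start=1):
        for i in idx:
            quintile_of[order[i].item_id] = q

    by_q: dict[int, list] = {q: [] for q in range(1, 6)}
    for it in candidates:
        by_q[quintile_of[it.item_id]].append(it)
    for q in by_q:  # highest slope first, id breaks ties
        by_q[q].sort(key=lambda it: (-it.slope, it.item_id))

    selected: list[str] = []
    reason: dict[str, str] = {}
    for iid in cfg.pinned:
        if iid in locations and iid not in selected:
            selected.append(iid)
            reason[iid] = "pinned"

    def take(q: int, why: str) -> bool:
        n_from_q = sum(1 for s in selected if quintile_of[s] == q)
        if n_from_q >= cfg.max_per_quintile:
            return False
        for it in by_q[q]:
            if it.item_id not in selected:
                selected.append(it.item_id)
                reason[it.item_id] = why
                return True
        return False

    # round 1: best item of each quintile
    for q in range(1, 6):
        if len(selected) >= cfg.max_size:
            break
        take(q, "quintile_best")
    # round 2: expand extreme quintiles inward toward the target size
    for q in (1, 5, 2, 4, 3):
        if len(selected) >= cfg.target_size:
            break
        take(q, "tail_expansion")

    rows = []
    for it in sorted(candidates, key=lambda i: i.item_id):
        iid = it.item_id
        rows.append({
            "item_id": iid, "location": locations[iid], "slope": it.slope,
            "quintile": quintile_of[iid], "selected": iid in selected,
            "reason": reason.get(iid, ""),
        })
    audit = pd.DataFrame(rows).set_index("item_id")
    return selected, audit
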
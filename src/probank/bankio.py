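"""Text I/O for item banks and response matrices.

Item-parameter files are tab-delimited with one record per item:
``item_id  slope  thresholds  n_categories  metric_name``, thresholds
comma-separated in ascending order.  Round trips are lossless to 6 decimals.

Response matrices travel as delimited text (persons x items, integer
categories, empty cell = missing) with an optional covariate sidecar table
keyed on ``person_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grm import ItemBank, ItemParameters, ScoringDirection

__all__ = ["ResponseMatrix", "read_bank", "write_bank",
           "read_responses", "write_responses"]


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with covariates.

    ``responses`` holds integer categories 1..m as a float frame so NaN can
    mark missing entries; ``covariates`` is indexed like ``responses``.
    """

    responses: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.responses = self.responses.astype(float)
        if self.covariates is not None and not self.covariates.index.equals(
            self.responses.index
        ):
            raise ValueError("covariates index must match responses index")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return list(self.responses.columns)

    def subset_items(self, item_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.responses[list(item_ids)].copy(),
                              None if self.covariates is None else self.covariates.copy())

    def pattern(self, row: int) -> dict[str, int]:
        """One person's responses as an item_id -> category dict (missing skipped)."""
        r = self.responses.iloc[row]
        return {c: int(v) for c, v in r.items() if not np.isnan(v)}


def write_bank(bank: ItemBank, path: str | Path) -> None:
    rows = []
    for it in bank:
        rows.append({
            "item_id": it.item_id,
            "slope": f"{it.slope:.6f}",
            "thresholds": ",".join(f"{b:.6f}" for b in it.thresholds),
            "n_categories": it.n_categories,
            "metric_name": bank.metric_name,
            "scoring_direction": bank.scoring_direction.value,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bank(path: str | Path) -> ItemBank:
    df = pd.read_csv(path, sep="\t", dtype={"item_id": str})
    items = []
    for _, row in df.iterrows():
        thresholds = tuple(float(x) for x in str(row["thresholds"]).split(","))
        item = ItemParameters(str(row["item_id"]), float(row["slope"]), thresholds)
        if item.n_categories != int(row["n_categories"]):
            raise ValueError(
                f"item {item.item_id!r}: n_categories {row['n_categories']} "
                f"inconsistent with {len(thresholds)} thresholds"
            )
        items.append(item)
    metric = str(df["metric_name"].iloc[0]) if "metric_name" in df else "reference"
    direction = ScoringDirection(str(df["scoring_direction"].iloc[0])) \
        if "scoring_direction" in df else ScoringDirection.positive
    return ItemBank(tuple(items), metric_name=metric, scoring_direction=direction)


def write_responses(data: ResponseMatrix, path: str | Path,
                    covariate_path: str | Path | None = None) -> None:
    out = data.responses.copy()
    out.index.name = "person_id"
    out.to_csv(path, sep="\t", float_format="%.0f")
    if covariate_path is not None and data.covariates is not None:
        cov = data.covariates.copy()
        cov.index.name = "person_id"
        cov.to_csv(covariate_path, sep="\t")


def read_responses(path: str | Path,
                   covariate_path: str | Path | None = None) -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col="person_id")
    cov = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep="\t", index_col="person_id")
    return ResponseMatrix(df, cov)
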
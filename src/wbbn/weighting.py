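"""Data-driven weights for attribute-value pairs.

Each discretized attribute-value pair (item) is counted against both class
labels; a dense global rank is assigned over all (item, label) counts; and a
weight in [0, 1] is derived for the positive (malignant) label from the
quantities of Bayes' theorem. Two schemes are available:

``joint``
    weight(item) = P(item AND class = positive) = count(item, pos) / N.
``posterior``
    weight(item) = P(class = positive | item) = count(item, pos) / count(item).

Record ("tuple") weights aggregate the weights of a record's attribute
items — arithmetic mean by default, sum as an option — and are the per-record
contribution used by every weighted-support computation downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataio import AttributeSchema, ItemDataset

WEIGHT_SCHEMES = ("joint", "posterior")
RECORD_SCHEMES = ("mean", "sum")


class EmptyDatasetError(ValueError):
    """Counts and weights are undefined on an empty dataset."""


@dataclass(frozen=True)
class WeightEntry:
    item: int
    count_yes: int
    count_no: int
    rank: int
    weight: float


@dataclass
class WeightTable:
    """Per attribute-item counts, global rank and weight.

    ``rank`` is the item's dense rank for the positive label within the
    joint ranking over all (item, label) pairs (1 = most frequent pair).
    """

    entries: dict[int, WeightEntry]
    total_records: int
    weight_scheme: str = "joint"
    record_weight_scheme: str = "mean"
    schema: AttributeSchema | None = None

    def weight(self, item: int) -> float:
        return self.entries[item].weight

    def record_weight(self, record: Iterable[int]) -> float:
        """Weight of one record from its attribute items (class items and
        items absent from the table contribute nothing)."""
        ws = [self.entries[i].weight for i in record if i in self.entries]
        if not ws:
            return 0.0
        if self.record_weight_scheme == "sum":
            return float(sum(ws))
        return float(sum(ws) / len(ws))

    def record_weights(self, ds: ItemDataset) -> np.ndarray:
        return np.array([self.record_weight(rec) for rec in ds.records], dtype=float)

    # -- serialization (Table-2-style layout) -------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for item in sorted(self.entries):
            e = self.entries[item]
            label = self.schema.item_label(item) if self.schema else str(item)
            rows.append(
                {
                    "attribute_value": label,
                    "item": e.item,
                    "count_yes": e.count_yes,
                    "count_no": e.count_no,
                    "rank": e.rank,
                    "weight": e.weight,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, total_records: int = 0) -> "WeightTable":
        df = pd.read_csv(path)
        entries = {
            int(r.item): WeightEntry(
                item=int(r.item),
                count_yes=int(r.count_yes),
                count_no=int(r.count_no),
                rank=int(r.rank),
                weight=float(r.weight),
            )
            for r in df.itertuples()
        }
        return cls(entries=entries, total_records=total_records)


def uniform_weights(ds: ItemDataset) -> WeightTable:
    """Weight table with every attribute item at weight 1 — collapses
    weighted support/confidence to their classical unweighted forms."""
    entries = {
        i: WeightEntry(item=i, count_yes=0, count_no=0, rank=1, weight=1.0)
        for i in ds.schema.attribute_items
    }
    return WeightTable(entries=entries, total_records=ds.n_records, schema=ds.schema)


def count_class_pairs(ds: ItemDataset) -> dict[int, tuple[int, int]]:
    """Exact co-occurrence counts of each attribute item with each class
    label: ``{item: (count_yes, count_no)}``."""
    if ds.n_records == 0:
        raise EmptyDatasetError("counts are undefined on an empty dataset")
    pos = ds.schema.class_positive_item
    counts = {i: [0, 0] for i in ds.schema.attribute_items}
    class_items = set(ds.schema.class_items)
    for rec in ds.records:
        is_yes = pos in rec
        for item in rec:
            if item not in class_items:
                counts[item][0 if is_yes else 1] += 1
    return {i: (c[0], c[1]) for i, c in counts.items()}


def assign_ranks(counts: Mapping[int, tuple[int, int]]) -> dict[tuple[int, str], int]:
    """Dense ranking over all (item, class-label) pairs of both labels:
    the largest count gets rank 1, equal counts share a rank, and ranks
    increase by one per distinct count value."""
    pairs = [((item, "yes"), c[0]) for item, c in counts.items()]
    pairs += [((item, "no"), c[1]) for item, c in counts.items()]
    distinct = sorted({c for _, c in pairs}, reverse=True)
    rank_of = {c: r for r, c in enumerate(distinct, start=1)}
    return {key: rank_of[c] for key, c in pairs}


def compute_weights(
    ds: ItemDataset,
    scheme: str = "joint",
    record_weight_scheme: str = "mean",
) -> WeightTable:
    """Count, rank and weight every attribute item of a missing-free
    dataset. See the module docstring for the two weight schemes."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    if record_weight_scheme not in RECORD_SCHEMES:
        raise ValueError(
            f"unknown record weight scheme {record_weight_scheme!r}; choose from {RECORD_SCHEMES}"
        )
    counts = count_class_pairs(ds)
    ranks = assign_ranks(counts)
    n = ds.n_records
    entries: dict[int, WeightEntry] = {}
    for item, (cy, cn) in counts.items():
        if scheme == "joint":
            w = cy / n
        else:
            w = cy / (cy + cn) if (cy + cn) else 0.0
        entries[item] = WeightEntry(
            item=item, count_yes=cy, count_no=cn, rank=ranks[(item, "yes")], weight=w
        )
    return WeightTable(
        entries=entries,
        total_records=n,
        weight_scheme=scheme,
        record_weight_scheme=record_weight_scheme,
        schema=ds.schema,
    )
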
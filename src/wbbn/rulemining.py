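"""Weighted association rule mining and strong-rule selection.

Weighted support of an itemset is the weight mass of the records containing
it over the total record-weight mass; weighted confidence is the usual ratio
of supports. Rules are mined in three modes:

``two_attribute``
    single attribute item -> single attribute item;
``multi_attribute``
    attribute itemset (up to ``max_antecedent_size`` items) -> single
    attribute item;
``class_label``
    attribute itemset -> single class item.

Mined rules are then scored with the weighted Bayes confidence
``WBC(A -> B) = WS(A u B) / WS(A)`` and the weighted Bayes lift
``WBL = WBC / WS(B)``; a rule is *strong* when WBC clears the confidence
threshold and WBL exceeds the lift threshold. Strong rules are what the
network-construction stage consumes.

Candidate generation is levelwise with Apriori pruning, which is sound here
because record weights are fixed per record, making weighted support
anti-monotone under itemset containment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ItemDataset
from .weighting import WeightTable

log = logging.getLogger(__name__)

MODES = ("two_attribute", "multi_attribute", "class_label")


class UndefinedSupportError(ZeroDivisionError):
    """Total record weight (or an antecedent's support) is zero."""


@dataclass(frozen=True)
class ThresholdConfig:
    min_support: float = 0.36
    min_confidence: float = 0.70
    min_lift: float = 1.0
    max_antecedent_size: int = 3

    def __post_init__(self):
        if not (0.0 <= self.min_support <= 1.0):
            raise ValueError("min_support must lie in [0, 1]")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must lie in [0, 1]")
        if self.min_lift < 0.0:
            raise ValueError("min_lift must be non-negative")
        if self.max_antecedent_size < 1:
            raise ValueError("max_antecedent_size must be >= 1")


@dataclass(frozen=True)
class WeightedRule:
    antecedent: frozenset[int]
    consequent: frozenset[int]
    ws: float
    wc: float
    wbc: float | None = None
    wbl: float | None = None
    strong: bool = False

    def key(self) -> tuple:
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        a = ",".join(map(str, sorted(self.antecedent)))
        c = ",".join(map(str, sorted(self.consequent)))
        return f"{{{a}}} -> {{{c}}} ws={self.ws:.4f} wc={self.wc:.4f}"


class WeightedTransactions:
    """Dataset + weight table cached as a boolean membership matrix and a
    per-record weight vector, with memoized weighted supports."""

    def __init__(self, ds: ItemDataset, wt: WeightTable):
        self.ds = ds
        self.matrix = ds.item_matrix()
        self.rw = wt.record_weights(ds)
        self.total = float(self.rw.sum())
        self._cache: dict[frozenset[int], float] = {}

    def support(self, itemset) -> float:
        key = frozenset(itemset)
        if not key:
            raise ValueError("support of the empty itemset is not defined")
        if self.total <= 0.0:
            raise UndefinedSupportError("total record weight is zero")
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        mask = np.logical_and.reduce([self.matrix[:, i] for i in key])
        val = float(self.rw[mask].sum() / self.total)
        self._cache[key] = val
        return val

    def confidence(self, antecedent, consequent) -> float:
        sa = self.support(antecedent)
        if sa <= 0.0:
            raise UndefinedSupportError("antecedent has zero weighted support")
        return self.support(frozenset(antecedent) | frozenset(consequent)) / sa


def weighted_support(itemset, ds: ItemDataset, wt: WeightTable) -> float:
    """WS(itemset): weight mass of the supporting records over the total
    weight mass; one quantity serves single-, multi- and class-item sets."""
    return WeightedTransactions(ds, wt).support(itemset)


def weighted_confidence(antecedent, consequent, ds: ItemDataset, wt: WeightTable) -> float:
    """WC(A -> B) = WS(A u B) / WS(A)."""
    return WeightedTransactions(ds, wt).confidence(antecedent, consequent)


def _frequent_itemsets(
    db: WeightedTransactions,
    items: list[int],
    owner: dict[int, str],
    max_size: int,
    min_support: float,
) -> dict[frozenset[int], float]:
    """Levelwise frequent attribute itemsets (at most one item per
    attribute, enforced through the owner map)."""
    frequent: dict[frozenset[int], float] = {}
    level = []
    for i in items:
        s = db.support([i])
        if s >= min_support:
            fs = frozenset([i])
            frequent[fs] = s
            level.append(fs)
    size = 1
    while level and size < max_size:
        nxt = []
        seen: set[frozenset[int]] = set()
        for base in level:
            owners = {owner[i] for i in base}
            top = max(base)
            for i in items:
                if i <= top or owner[i] in owners:
                    continue
                cand = base | {i}
                if cand in seen:
                    continue
                seen.add(cand)
                # Apriori: every (k-1)-subset must be frequent
                if any(cand - {j} not in frequent for j in cand):
                    continue
                s = db.support(cand)
                if s >= min_support:
                    frequent[cand] = s
                    nxt.append(cand)
        level = nxt
        size += 1
    return frequent


def mine_rules(
    ds: ItemDataset,
    wt: WeightTable,
    cfg: ThresholdConfig,
    mode: str = "class_label",
) -> list[WeightedRule]:
    """Mine all rules with WS >= min_support and WC >= min_confidence in the
    requested mode. Output order is deterministic (lexicographic on the
    sorted antecedent then consequent)."""
    return mine_rules_from_db(WeightedTransactions(ds, wt), ds.schema, cfg, mode)


def mine_rules_from_db(db, schema, cfg: ThresholdConfig, mode: str) -> list[WeightedRule]:
    """Mining core over any support provider exposing ``support``/``confidence``
    (sampled transactions or an exact planted joint distribution)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    owner = schema.owner_map()
    attr_items = [i for i in schema.attribute_items]

    rules: list[WeightedRule] = []

    def emit(ante: frozenset[int], cons: frozenset[int]):
        s = db.support(ante | cons)
        if s < cfg.min_support:
            return
        sa = db.support(ante)
        if sa <= 0.0:
            return
        wc = s / sa
        if wc >= cfg.min_confidence:
            rules.append(WeightedRule(antecedent=ante, consequent=cons, ws=s, wc=wc))

    if mode == "two_attribute":
        freq = _frequent_itemsets(db, attr_items, owner, 2, cfg.min_support)
        for pair in freq:
            if len(pair) != 2:
                continue
            a, b = sorted(pair)
            emit(frozenset([a]), frozenset([b]))
            emit(frozenset([b]), frozenset([a]))
    elif mode == "multi_attribute":
        freq = _frequent_itemsets(
            db, attr_items, owner, cfg.max_antecedent_size + 1, cfg.min_support
        )
        for iset in freq:
            if len(iset) < 2:
                continue
            for c in iset:
                ante = iset - {c}
                if len(ante) <= cfg.max_antecedent_size:
                    emit(ante, frozenset([c]))
    else:  # class_label
        freq = _frequent_itemsets(db, attr_items, owner, cfg.max_antecedent_size, cfg.min_support)
        for ante in freq:
            for c in schema.class_items:
                emit(ante, frozenset([c]))

    rules.sort(key=lambda r: r.key())
    return rules


def score_strong(
    rules: list[WeightedRule],
    ds: ItemDataset,
    wt: WeightTable,
    cfg: ThresholdConfig,
) -> list[WeightedRule]:
    """Attach WBC and WBL to each mined rule and flag the strong ones.

    WBC is the weighted-support estimate of P(consequent | antecedent) and
    equals the mining-stage weighted confidence; WBL divides it by the
    consequent's weighted support. Rules whose consequent has zero support
    are dropped with a warning (lift undefined). Output is sorted by
    (WBL, WBC) descending with a lexicographic itemset tie-break.
    """
    return score_strong_from_db(rules, WeightedTransactions(ds, wt), cfg)


def score_strong_from_db(rules, db, cfg: ThresholdConfig) -> list[WeightedRule]:
    out: list[WeightedRule] = []
    for r in rules:
        sc = db.support(r.consequent)
        if sc <= 0.0:
            log.warning("dropping rule %s: consequent support is zero, lift undefined", r)
            continue
        wbc = db.confidence(r.antecedent, r.consequent)
        wbl = wbc / sc
        strong = wbc >= cfg.min_confidence and wbl > cfg.min_lift
        out.append(replace(r, wbc=wbc, wbl=wbl, strong=strong))
    out.sort(key=lambda r: (-r.wbl, -r.wbc, r.key()))
    return out


# -- export -----------------------------------------------------------------


def rules_to_frame(rules: list[WeightedRule], schema=None) -> pd.DataFrame:
    def fmt(itemset):
        if schema is None:
            return " ".join(str(i) for i in sorted(itemset))
        return " & ".join(schema.item_label(i) for i in sorted(itemset))

    return pd.DataFrame(
        [
            {
                "antecedent": fmt(r.antecedent),
                "consequent": fmt(r.consequent),
                "antecedent_items": " ".join(map(str, sorted(r.antecedent))),
                "consequent_items": " ".join(map(str, sorted(r.consequent))),
                "ws": r.ws,
                "wc": r.wc,
                "wbc": r.wbc,
                "wbl": r.wbl,
                "strong": r.strong,
            }
            for r in rules
        ]
    )


def rules_to_json(rules: list[WeightedRule], path: str | Path) -> None:
    doc = [
        {
            "antecedent": sorted(r.antecedent),
            "consequent": sorted(r.consequent),
            "ws": r.ws,
            "wc": r.wc,
            "wbc": r.wbc,
            "wbl": r.wbl,
            "strong": r.strong,
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(doc, indent=2))
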
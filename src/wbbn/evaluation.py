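"""Holdout evaluation of the weighted Bayesian belief network pipeline.

``run_pipeline`` executes the full method on one configuration: weights ->
weighted rule mining -> strong-rule selection by weighted Bayes confidence
and lift -> K2 structure learning over the strong-rule attributes -> smoothed
parameter learning -> posterior classification of the held-out records.
Everything data driven (weights, rules, structure, parameters) is computed
on the training partition only; ``paper_mode`` switches weight computation
to the full dataset to mimic workflows that weight before splitting.

``threshold_sweep`` replays the pipeline over a grid of minimum support and
confidence thresholds crossed with train/test ratios and seeds, reporting
rule counts, strong-rule counts and accuracy per cell.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ItemDataset
from .network import build_node_order, k2_learn, learn_cpts
from .rulemining import ThresholdConfig, mine_rules, score_strong
from .weighting import compute_weights

log = logging.getLogger(__name__)

DEFAULT_GRID = ((0.36, 0.70), (0.40, 0.80), (0.26, 0.60), (0.10, 0.50))
DEFAULT_TRAIN_FRACS = (1.0, 0.8, 0.7, 0.6)
PIPELINE_MODES = ("multi_attribute", "class_label")


def split(
    ds: ItemDataset,
    train_frac: float,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[ItemDataset, ItemDataset]:
    """Holdout split, stratified by class label by default.

    ``train_frac == 1`` returns the full dataset as both partitions (the
    train-on-all / test-on-all configuration); otherwise the partitions are
    disjoint and reproducible for a fixed seed.
    """
    if not (0.0 < train_frac <= 1.0):
        raise ValueError("train_frac must lie in (0, 1]")
    if train_frac == 1.0:
        return ds, ds
    rng = np.random.default_rng(seed)
    n = ds.n_records
    if stratified:
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(ds.class_item(i), []).append(i)
        train_idx: list[int] = []
        for cls in sorted(groups):
            idx = np.array(groups[cls])
            rng.shuffle(idx)
            k = int(round(train_frac * len(idx)))
            train_idx.extend(idx[:k].tolist())
    else:
        idx = rng.permutation(n)
        train_idx = idx[: int(round(train_frac * n))].tolist()
    train_set = set(train_idx)
    test_idx = [i for i in range(n) if i not in train_set]
    mk = lambda ix: ItemDataset(
        schema=ds.schema,
        records=[ds.records[i] for i in ix],
        missing=[ds.missing[i] for i in ix],
    )
    return mk(sorted(train_idx)), mk(test_idx)


def accuracy(predictions: Sequence, truths: Sequence) -> float:
    """Fraction of exact matches."""
    if len(truths) == 0:
        raise ValueError("accuracy is undefined on an empty test set")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    return float(sum(p == t for p, t in zip(predictions, truths)) / len(truths))


@dataclass
class EvaluationRow:
    min_support: float
    min_confidence: float
    min_lift: float
    train_frac: float
    test_frac: float
    n_train: int
    n_test: int
    n_rules: int
    n_strong_rules: int
    accuracy: float
    seed: int
    warning: str = ""


@dataclass
class PipelineResult:
    row: EvaluationRow
    network: object | None
    strong_rules: list
    rules: list
    weights: object


def run_pipeline(
    ds: ItemDataset,
    cfg: ThresholdConfig,
    train_frac: float = 0.7,
    seed: int = 0,
    alpha: float = 0.5,
    max_parents: int = 3,
    weight_scheme: str = "joint",
    record_weight_scheme: str = "mean",
    paper_mode: bool = False,
    unrestricted_k2: bool = False,
    stratified: bool = True,
    modes: Sequence[str] = PIPELINE_MODES,
) -> PipelineResult:
    """One full train/evaluate cycle; see the module docstring.

    When no strong rule survives the thresholds there is no network to
    build; the majority training class is predicted for every test record
    and the row carries a warning.
    """
    train, test = split(ds, train_frac, seed=seed, stratified=stratified)
    wt = compute_weights(
        ds if paper_mode else train,
        scheme=weight_scheme,
        record_weight_scheme=record_weight_scheme,
    )

    rules = []
    seen = set()
    for mode in modes:
        for r in mine_rules(train, wt, cfg, mode=mode):
            if r.key() not in seen:
                seen.add(r.key())
                rules.append(r)
    scored = score_strong(rules, train, wt, cfg)
    strong = [r for r in scored if r.strong]

    schema = ds.schema
    cls_attr = schema.class_attribute
    truth = [cls_attr.items.index(test.class_item(i)) for i in range(test.n_records)]
    warning = ""
    bn = None
    if not strong:
        warning = "no strong rules at these thresholds; majority-class fallback"
        log.warning(warning)
        counts = np.bincount(
            [cls_attr.items.index(train.class_item(i)) for i in range(train.n_records)],
            minlength=cls_attr.arity,
        )
        majority = int(np.argmax(counts))
        preds = [majority] * test.n_records
    else:
        order = build_node_order(strong, wt, schema)
        candidate_edges = None
        if not unrestricted_k2:
            owner = schema.owner_map()
            candidate_edges = set()
            for r in strong:
                nodes = sorted({owner[i] for i in r.antecedent | r.consequent})
                for a_i in range(len(nodes)):
                    for b_i in range(a_i + 1, len(nodes)):
                        candidate_edges.add(frozenset((nodes[a_i], nodes[b_i])))
        train_df = train.to_value_frame()[order]
        arities = {a.name: a.arity for a in schema.attributes}
        arities[cls_attr.name] = cls_attr.arity
        dag = k2_learn(
            train_df,
            order,
            max_parents=max_parents,
            candidate_edges=candidate_edges,
            arities=arities,
        )
        bn = learn_cpts(
            train_df,
            dag,
            alpha=alpha,
            arities=arities,
            node_order=order,
            class_node=cls_attr.name,
        )
        test_df = test.to_value_frame()
        preds = []
        for _, rec in test_df.iterrows():
            ev = {k: int(v) for k, v in rec.items() if k != cls_attr.name}
            preds.append(bn.predict(ev)[0])

    row = EvaluationRow(
        min_support=cfg.min_support,
        min_confidence=cfg.min_confidence,
        min_lift=cfg.min_lift,
        train_frac=train_frac,
        test_frac=1.0 if train_frac == 1.0 else 1.0 - train_frac,
        n_train=train.n_records,
        n_test=test.n_records,
        n_rules=len(scored),
        n_strong_rules=len(strong),
        accuracy=accuracy(preds, truth),
        seed=seed,
        warning=warning,
    )
    return PipelineResult(row=row, network=bn, strong_rules=strong, rules=scored, weights=wt)


def threshold_sweep(
    ds: ItemDataset,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    train_fracs: Sequence[float] = DEFAULT_TRAIN_FRACS,
    seeds: Sequence[int] = (0,),
    min_lift: float = 1.0,
    max_antecedent_size: int = 3,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Grid of (min_support, min_confidence) x train_frac x seed, one
    evaluation row per cell."""
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for min_support, min_confidence in grid:
        cfg = ThresholdConfig(
            min_support=min_support,
            min_confidence=min_confidence,
            min_lift=min_lift,
            max_antecedent_size=max_antecedent_size,
        )
        for frac in train_fracs:
            for seed in seeds:
                res = run_pipeline(ds, cfg, train_frac=frac, seed=seed, **pipeline_kwargs)
                rows.append(asdict(res.row))
    return pd.DataFrame(rows)
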
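"""Independent brute-force oracles used to check the implementation.

Everything here recomputes quantities by direct enumeration or linear
scanning, deliberately avoiding the library's own candidate generation,
caching and pruning code paths.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from wbbn.dataio import ItemDataset, synthetic_schema
from wbbn.weighting import WeightEntry, WeightTable


def build_ds(n_attrs: int, rows) -> ItemDataset:
    """Dataset from rows of bin indices: (v1, ..., vn, class_value)."""
    schema = synthetic_schema(n_attrs)
    records = []
    for row in rows:
        items = [schema.attributes[i].items[v] for i, v in enumerate(row[:-1])]
        items.append(schema.class_attribute.items[row[-1]])
        records.append(frozenset(items))
    return ItemDataset(schema=schema, records=records)


def random_ds(rng: np.random.Generator, n_attrs: int, n_records: int) -> ItemDataset:
    rows = [
        tuple(rng.integers(0, 2, size=n_attrs + 1).tolist()) for _ in range(n_records)
    ]
    return build_ds(n_attrs, rows)


def random_weight_table(rng: np.random.Generator, ds: ItemDataset) -> WeightTable:
    entries = {
        i: WeightEntry(item=i, count_yes=0, count_no=0, rank=1,
                       weight=float(rng.uniform(0.01, 1.0)))
        for i in ds.schema.attribute_items
    }
    return WeightTable(entries=entries, total_records=ds.n_records, schema=ds.schema)


def brute_record_weights(ds: ItemDataset, wt: WeightTable) -> list[float]:
    out = []
    attr_items = set(ds.schema.attribute_items)
    for rec in ds.records:
        ws = [wt.entries[i].weight for i in rec if i in attr_items]
        if wt.record_weight_scheme == "sum":
            out.append(sum(ws))
        else:
            out.append(sum(ws) / len(ws) if ws else 0.0)
    return out


def brute_support(itemset, ds: ItemDataset, wt: WeightTable) -> float:
    rw = brute_record_weights(ds, wt)
    key = frozenset(itemset)
    num = sum(w for rec, w in zip(ds.records, rw) if key <= rec)
    return num / sum(rw)


def brute_rules(ds: ItemDataset, wt: WeightTable, cfg, mode: str) -> set[tuple]:
    """Exhaustive enumeration over every admissible antecedent/consequent
    pair; returns the set of rule keys passing the support and confidence
    thresholds."""
    schema = ds.schema
    owner = schema.owner_map()
    attr_items = list(schema.attribute_items)

    def sup(s):
        return brute_support(s, ds, wt)

    out: set[tuple] = set()

    def check(ante: tuple, cons: tuple):
        s = sup(set(ante) | set(cons))
        if s < cfg.min_support:
            return
        sa = sup(set(ante))
        if sa > 0 and s / sa >= cfg.min_confidence:
            out.add((tuple(sorted(ante)), tuple(sorted(cons))))

    def valid(itemset) -> bool:
        return len({owner[i] for i in itemset}) == len(itemset)

    if mode == "two_attribute":
        for a in attr_items:
            for b in attr_items:
                if a != b and owner[a] != owner[b]:
                    check((a,), (b,))
    elif mode == "multi_attribute":
        for size in range(2, cfg.max_antecedent_size + 2):
            for iset in combinations(attr_items, size):
                if not valid(iset):
                    continue
                for c in iset:
                    ante = tuple(i for i in iset if i != c)
                    if len(ante) <= cfg.max_antecedent_size:
                        check(ante, (c,))
    elif mode == "class_label":
        for size in range(1, cfg.max_antecedent_size + 1):
            for ante in combinations(attr_items, size):
                if not valid(ante):
                    continue
                for c in schema.class_items:
                    check(ante, (c,))
    else:
        raise ValueError(mode)
    return out


def random_bayesnet(rng: np.random.Generator, n_nodes: int):
    """Random binary DAG (each node gets up to two earlier parents) with
    Dirichlet-sampled CPTs, as a plain dict for the brute-force oracle."""
    from wbbn.network import BayesNet

    nodes = [f"n{i}" for i in range(n_nodes - 1)] + ["class"]
    parents = {}
    cpts = {}
    for pos, node in enumerate(nodes):
        k = int(rng.integers(0, min(2, pos) + 1))
        ps = tuple(rng.choice(pos, size=k, replace=False).tolist()) if k else ()
        ps = tuple(nodes[i] for i in sorted(ps))
        parents[node] = ps
        table = rng.dirichlet([1.0, 1.0], size=2 ** len(ps)).reshape(
            tuple(2 for _ in ps) + (2,)
        )
        cpts[node] = table
    return BayesNet(
        nodes=nodes,
        arities={n: 2 for n in nodes},
        parents=parents,
        cpts=cpts,
        node_order=nodes,
        class_node="class",
        class_majority=0,
    )


def brute_posterior(bn, evidence: dict) -> np.ndarray:
    """Class posterior from the explicit full joint table, built by
    multiplying broadcast CPT factors (no reuse of the model's chain-rule
    evaluator)."""
    nodes = bn.nodes
    axes = {n: i for i, n in enumerate(nodes)}
    joint = np.ones(tuple(bn.arities[n] for n in nodes))
    for node in nodes:
        fam = tuple(bn.parents[node]) + (node,)
        table = bn.cpts[node]
        # expand the factor onto the full axis layout
        shape = [1] * len(nodes)
        order = sorted(range(len(fam)), key=lambda i: axes[fam[i]])
        table = np.transpose(table, order)
        for f in fam:
            shape[axes[f]] = bn.arities[f]
        joint = joint * table.reshape(shape)
    # condition on evidence, marginalize everything but the class node
    idx = [slice(None)] * len(nodes)
    for n, v in evidence.items():
        if n in axes and n != bn.class_node:
            idx[axes[n]] = v
    sub = joint[tuple(idx)]
    keep = [n for n in nodes if n not in evidence or n == bn.class_node]
    class_axis = keep.index(bn.class_node)
    other = tuple(i for i in range(len(keep)) if i != class_axis)
    scores = sub.sum(axis=other) if other else sub
    return scores / scores.sum()
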
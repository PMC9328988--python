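"""Synthetic discretized clinical datasets with known ground truth.

Datasets are drawn by ancestral sampling from a planted Bayesian network
over binary attributes plus a binary class node, then encoded with the
standard contiguous item layout (attribute k on items 2k+1/2k+2, the class
on the final pair) so they round-trip through the ``.num`` reader/writer.

Because the planted joint distribution is known exactly, the module can also
enumerate it (up to 12 binary nodes) and compute the analytic strong-rule
set under uniform record weights — the oracle the sampled-data miner must
approach as the record count grows.

The default spec mirrors the shape of the Wisconsin breast-cancer data:
nine binary-discretized attributes, a ~35% positive-class prior, roughly
700 records, with planted attribute-attribute and attribute-class
dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .dataio import AttributeSchema, ItemDataset, synthetic_schema
from .network import BayesNet
from .rulemining import (
    ThresholdConfig,
    WeightedRule,
    mine_rules_from_db,
    score_strong_from_db,
)

MAX_ENUM_NODES = 12


class SpecError(ValueError):
    """The generator specification is internally inconsistent."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Planted ground truth for one synthetic dataset.

    ``dag`` lists directed edges over node names ``att1..attN`` and
    ``class``; ``cpts`` maps each node to a table of shape
    ``(*parent_arities, 2)`` with parents ordered as in ``parents_of``.
    Nodes without an entry get their default: the class its prior, an
    attribute a fair coin (only valid for parentless nodes).
    """

    n_attributes: int = 9
    class_prior: float = 0.35
    dag: tuple[tuple[str, str], ...] = ()
    cpts: Mapping[str, np.ndarray] | None = None
    n_records: int = 683
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def node_names(self) -> list[str]:
        return [f"att{k + 1}" for k in range(self.n_attributes)] + ["class"]

    def parents_of(self, node: str) -> tuple[str, ...]:
        names = self.node_names
        return tuple(p for p in names if (p, node) in set(self.dag))

    def schema(self) -> AttributeSchema:
        return synthetic_schema(self.n_attributes)

    def validate(self) -> None:
        if not (0.0 < self.class_prior < 1.0):
            raise SpecError("class_prior must lie strictly inside (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SpecError("missing_rate must lie in [0, 1)")
        names = set(self.node_names)
        g = nx.DiGraph(self.dag)
        if not set(g.nodes) <= names:
            raise SpecError(f"dag names unknown nodes: {set(g.nodes) - names}")
        if g.edges and not nx.is_directed_acyclic_graph(g):
            raise SpecError("planted dag contains a cycle")
        for node, table in (self.cpts or {}).items():
            t = np.asarray(table, dtype=float)
            want = tuple(2 for _ in self.parents_of(node)) + (2,)
            if t.shape != want:
                raise SpecError(f"cpt of {node!r} has shape {t.shape}, expected {want}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise SpecError(f"cpt of {node!r} is not normalized")

    def to_network(self) -> BayesNet:
        """The planted model as a :class:`BayesNet` (exact parameters)."""
        self.validate()
        names = self.node_names
        cpts: dict[str, np.ndarray] = {}
        parents: dict[str, tuple[str, ...]] = {}
        for node in names:
            ps = self.parents_of(node)
            parents[node] = ps
            if self.cpts and node in self.cpts:
                cpts[node] = np.asarray(self.cpts[node], dtype=float)
            elif ps:
                raise SpecError(f"node {node!r} has parents but no cpt")
            elif node == "class":
                cpts[node] = np.array([1.0 - self.class_prior, self.class_prior])
            else:
                cpts[node] = np.array([0.5, 0.5])
        order = list(nx.topological_sort(nx.DiGraph(self.dag).to_directed())) if self.dag else []
        order = [n for n in order if n in names] + [n for n in names if n not in order]
        return BayesNet(
            nodes=names,
            arities={n: 2 for n in names},
            parents=parents,
            cpts=cpts,
            node_order=order,
            class_node="class",
            class_majority=int(self.class_prior > 0.5),
            alpha=0.5,
        )


def generate(spec: GeneratorSpec) -> ItemDataset:
    """Ancestral sampling from the planted network, encoded as items.

    Missing cells (attribute items removed, record flagged) are injected
    independently per attribute cell at ``missing_rate``. Reproducible for
    a fixed seed.
    """
    bn = spec.to_network()
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema()
    topo = list(nx.topological_sort(bn.to_networkx()))
    n = spec.n_records
    values: dict[str, np.ndarray] = {}
    for node in topo:
        ps = bn.parents[node]
        table = bn.cpts[node]
        if ps:
            # P(node=1 | parent configuration) looked up per record
            idx = tuple(values[p] for p in ps)
            p1 = table[idx][..., 1]
        else:
            p1 = np.full(n, table[1])
        values[node] = (rng.random(n) < p1).astype(np.int64)

    attr_names = [a.name for a in schema.attributes]
    miss_mask = (
        rng.random((n, len(attr_names))) < spec.missing_rate
        if spec.missing_rate > 0
        else np.zeros((n, len(attr_names)), dtype=bool)
    )
    records, flags = [], []
    for r in range(n):
        items = []
        miss = False
        for j, (attr, name) in enumerate(zip(schema.attributes, attr_names)):
            if miss_mask[r, j]:
                miss = True
                continue
            items.append(attr.items[values[name][r]])
        cls = schema.class_attribute
        items.append(cls.items[values["class"][r]])
        records.append(frozenset(items))
        flags.append(miss)
    return ItemDataset(schema=schema, records=records, missing=flags)


class ExactJointDB:
    """Support provider over the planted joint distribution itself.

    Uniform record weights are implied: the weighted support of an itemset
    is exactly its probability mass under the planted network.
    """

    def __init__(self, spec: GeneratorSpec):
        n_nodes = spec.n_attributes + 1
        if n_nodes > MAX_ENUM_NODES:
            raise SpecError(
                f"{n_nodes} nodes exceed the {MAX_ENUM_NODES}-node enumeration limit"
            )
        bn = spec.to_network()
        schema = spec.schema()
        names = spec.node_names
        attr_of = {name: a for name, a in zip(names[:-1], schema.attributes)}
        self._mass: list[tuple[frozenset[int], float]] = []
        for combo in np.ndindex(*(2,) * n_nodes):
            assignment = dict(zip(names, (int(v) for v in combo)))
            p = bn.joint_probability(assignment)
            items = [attr_of[nm].items[assignment[nm]] for nm in names[:-1]]
            items.append(schema.class_attribute.items[assignment["class"]])
            self._mass.append((frozenset(items), p))
        self._cache: dict[frozenset[int], float] = {}

    def support(self, itemset) -> float:
        key = frozenset(itemset)
        hit = self._cache.get(key)
        if hit is None:
            hit = sum(p for rec, p in self._mass if key <= rec)
            self._cache[key] = hit
        return hit

    def confidence(self, antecedent, consequent) -> float:
        sa = self.support(antecedent)
        if sa <= 0.0:
            raise ZeroDivisionError("antecedent has zero probability mass")
        return self.support(frozenset(antecedent) | frozenset(consequent)) / sa


def expected_strong_rules(
    spec: GeneratorSpec,
    cfg: ThresholdConfig,
    mode: str = "class_label",
) -> list[WeightedRule]:
    """Analytic rule set from the planted joint (uniform record weights):
    exact supports, confidences and lifts, thresholded per ``cfg``. Returns
    the scored rules; filter on ``strong`` for the strong-rule oracle."""
    db = ExactJointDB(spec)
    schema = spec.schema()
    rules = mine_rules_from_db(db, schema, cfg, mode)
    return score_strong_from_db(rules, db, cfg)


# -- canned specifications -----------------------------------------------------


def independent_spec(
    n_attributes: int = 9,
    class_prior: float = 0.35,
    n_records: int = 10_000,
    seed: int = 0,
) -> GeneratorSpec:
    """All attributes fair coins, mutually independent and independent of
    the class: every association lift is exactly 1 in the population."""
    return GeneratorSpec(
        n_attributes=n_attributes,
        class_prior=class_prior,
        n_records=n_records,
        seed=seed,
    )


def chain_spec(n_records: int = 2000, seed: int = 0) -> GeneratorSpec:
    """Planted chain att1 -> att2 -> class with strong dependencies."""
    return GeneratorSpec(
        n_attributes=2,
        class_prior=0.5,
        dag=(("att1", "att2"), ("att2", "class")),
        cpts={
            "att1": np.array([0.5, 0.5]),
            "att2": np.array([[0.9, 0.1], [0.1, 0.9]]),
            "class": np.array([[0.9, 0.1], [0.1, 0.9]]),
        },
        n_records=n_records,
        seed=seed,
    )


def separable_spec(n_records: int = 683, seed: int = 0) -> GeneratorSpec:
    """Nearly separable classes: three attributes echo the class label with
    a 5% flip rate each (Bayes error about 0.007, below 0.02); the other six
    attributes are independent noise."""
    flip = np.array([[0.95, 0.05], [0.05, 0.95]])
    return GeneratorSpec(
        n_attributes=9,
        class_prior=0.5,
        dag=(("class", "att1"), ("class", "att2"), ("class", "att3")),
        cpts={"att1": flip, "att2": flip, "att3": flip},
        n_records=n_records,
        seed=seed,
    )


def default_spec(n_records: int = 683, seed: int = 0) -> GeneratorSpec:
    """Breast-cancer-shaped default: nine binary attributes, 35% positive
    prior, two attribute-class dependencies of different strengths plus one
    attribute-attribute dependency."""
    return GeneratorSpec(
        n_attributes=9,
        class_prior=0.35,
        dag=(("class", "att1"), ("class", "att2"), ("att1", "att4")),
        cpts={
            "att1": np.array([[0.85, 0.15], [0.10, 0.90]]),
            "att2": np.array([[0.75, 0.25], [0.20, 0.80]]),
            "att4": np.array([[0.80, 0.20], [0.30, 0.70]]),
        },
        n_records=n_records,
        seed=seed,
    )


CANNED_SPECS = {
    "default": default_spec,
    "independent": independent_spec,
    "separable": separable_spec,
    "chain": chain_spec,
}
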
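"""Bayesian-network construction over the strong-rule attributes.

Structure is learned with the K2 greedy search under a fixed node ordering:
for each node, earlier-ordered candidate parents are added one at a time as
long as the Cooper-Herskovits marginal-likelihood score improves and the
parent budget is not exhausted. The ordering is data driven: attributes are
sorted by the total weight of their items appearing in strong rules, with
the class node last, so the most disease-informative attributes become
ancestors.

Parameters are Dirichlet-smoothed relative frequencies with a per-cell
pseudo-count alpha (default 0.5); a parent configuration never observed in
the data yields the uniform distribution. The joint factorizes as
P(x1..xn) = prod_i P(xi | Pa(xi)) and classification is exact posterior
inference by enumeration over the unobserved nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataio import AttributeSchema, ItemDataset
from .rulemining import WeightedRule
from .weighting import WeightTable

CPT_TOL = 1e-9


def _as_frame(data, arities: Mapping[str, int] | None) -> tuple[pd.DataFrame, dict[str, int]]:
    if isinstance(data, ItemDataset):
        df = data.to_value_frame()
        ar = {a.name: a.arity for a in data.schema.attributes}
        ar[data.schema.class_attribute.name] = data.schema.class_attribute.arity
        return df, ar
    if arities is None:
        raise ValueError("arities are required when data is a plain DataFrame")
    return data, dict(arities)


@dataclass
class BayesNet:
    """Directed acyclic model with smoothed conditional probability tables.

    ``cpts[node]`` has shape ``(*parent_arities, arity)`` with parents in
    the order given by ``parents[node]``; every slice over the last axis is
    a normalized distribution.
    """

    nodes: list[str]
    arities: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    node_order: list[str]
    class_node: str = "class"
    class_majority: int = 0
    alpha: float = 0.5

    def __post_init__(self):
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent map contains a cycle")
        for node in self.nodes:
            t = self.cpts[node]
            if not np.allclose(t.sum(axis=-1), 1.0, atol=CPT_TOL):
                raise ValueError(f"CPT of {node!r} is not normalized")

    def edges(self) -> list[tuple[str, str]]:
        return [(p, n) for n in self.nodes for p in self.parents.get(n, ())]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    # -- inference -----------------------------------------------------------
    def joint_probability(self, assignment: Mapping[str, int]) -> float:
        """Chain-rule product of CPT entries for a full assignment."""
        missing = [n for n in self.nodes if n not in assignment]
        if missing:
            raise ValueError(f"assignment lacks nodes: {missing}")
        p = 1.0
        for node in self.nodes:
            idx = tuple(assignment[pa] for pa in self.parents.get(node, ()))
            p *= float(self.cpts[node][idx + (assignment[node],)])
        return p

    def posterior(self, evidence: Mapping[str, int]) -> np.ndarray:
        """Exact class posterior by summing the joint over unobserved nodes;
        evidence on nodes absent from the model is ignored."""
        ev = {k: v for k, v in evidence.items() if k in self.arities and k != self.class_node}
        hidden = [n for n in self.nodes if n not in ev and n != self.class_node]
        r = self.arities[self.class_node]
        scores = np.zeros(r)
        for c in range(r):
            total = 0.0
            for combo in product(*(range(self.arities[h]) for h in hidden)):
                assignment = {**ev, self.class_node: c, **dict(zip(hidden, combo))}
                total += self.joint_probability(assignment)
            scores[c] = total
        z = scores.sum()
        return scores / z

    def predict(self, evidence: Mapping[str, int]) -> tuple[int, float]:
        """Most probable class value and its posterior; exact ties resolve
        toward the majority training class."""
        post = self.posterior(evidence)
        best = int(np.argmax(post))
        if np.isclose(post[best], post[self.class_majority]):
            best = self.class_majority
        return best, float(post[best])

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "arities": self.arities,
            "parents": {k: list(v) for k, v in self.parents.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "node_order": self.node_order,
            "class_node": self.class_node,
            "class_majority": self.class_majority,
            "alpha": self.alpha,
        }

    def to_json(self, path: str | Path, header: dict | None = None) -> None:
        doc = self.to_dict()
        if header:
            doc["_meta"] = header
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "BayesNet":
        return cls(
            nodes=list(doc["nodes"]),
            arities={k: int(v) for k, v in doc["arities"].items()},
            parents={k: tuple(v) for k, v in doc["parents"].items()},
            cpts={k: np.asarray(v, dtype=float) for k, v in doc["cpts"].items()},
            node_order=list(doc["node_order"]),
            class_node=doc.get("class_node", "class"),
            class_majority=int(doc.get("class_majority", 0)),
            alpha=float(doc.get("alpha", 0.5)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesNet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_xmlbif(self, path: str | Path) -> None:
        """Export in the XMLBIF dialect for standard network viewers."""
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<BIF VERSION="0.3"><NETWORK><NAME>wbbn</NAME>',
        ]
        for node in self.nodes:
            lines.append('<VARIABLE TYPE="nature">')
            lines.append(f"  <NAME>{escape(node)}</NAME>")
            for v in range(self.arities[node]):
                lines.append(f"  <OUTCOME>v{v}</OUTCOME>")
            lines.append("</VARIABLE>")
        for node in self.nodes:
            lines.append("<DEFINITION>")
            lines.append(f"  <FOR>{escape(node)}</FOR>")
            for pa in self.parents.get(node, ()):
                lines.append(f"  <GIVEN>{escape(pa)}</GIVEN>")
            flat = self.cpts[node].reshape(-1)
            lines.append("  <TABLE>" + " ".join(f"{x:.12g}" for x in flat) + "</TABLE>")
            lines.append("</DEFINITION>")
        lines.append("</NETWORK></BIF>")
        Path(path).write_text("\n".join(lines) + "\n")


# -- node ordering ------------------------------------------------------------


def build_node_order(
    strong_rules: Sequence[WeightedRule],
    wt: WeightTable,
    schema: AttributeSchema,
) -> list[str]:
    """Attributes appearing in strong rules ordered by descending total item
    weight (each distinct item counted once), alphabetical tie-break, class
    node last."""
    if not strong_rules:
        raise ValueError("no strong rules: there is no network to build")
    owner = schema.owner_map()
    class_name = schema.class_attribute.name
    items_by_node: dict[str, set[int]] = {}
    for rule in strong_rules:
        for item in rule.antecedent | rule.consequent:
            items_by_node.setdefault(owner[item], set()).add(item)
    attrs = [n for n in items_by_node if n != class_name]
    totals = {
        n: sum(wt.weight(i) for i in items_by_node[n] if i in wt.entries) for n in attrs
    }
    ordered = sorted(attrs, key=lambda n: (-totals[n], n))
    return ordered + [class_name]


# -- structure learning --------------------------------------------------------


def _family_counts(
    df: pd.DataFrame, node: str, parents: Sequence[str], arities: Mapping[str, int]
) -> np.ndarray:
    """Counts N[j, k] of node value k under parent configuration j."""
    r = arities[node]
    child = df[node].to_numpy()
    if parents:
        dims = [arities[p] for p in parents]
        idx = np.ravel_multi_index([df[p].to_numpy() for p in parents], dims)
        q = int(np.prod(dims))
    else:
        idx = np.zeros(len(df), dtype=np.int64)
        q = 1
    return np.bincount(idx * r + child, minlength=q * r).reshape(q, r)


def family_score(
    df: pd.DataFrame, node: str, parents: Sequence[str], arities: Mapping[str, int]
) -> float:
    """Cooper-Herskovits log marginal likelihood of one node's family under
    a uniform Dirichlet(1) parameter prior."""
    counts = _family_counts(df, node, parents, arities)
    r = arities[node]
    nj = counts.sum(axis=1)
    return float(
        np.sum(gammaln(r) - gammaln(nj + r)) + np.sum(gammaln(counts + 1.0))
    )


def k2_learn(
    data,
    order: Sequence[str],
    max_parents: int = 3,
    candidate_edges: Iterable[frozenset] | None = None,
    arities: Mapping[str, int] | None = None,
) -> dict[str, tuple[str, ...]]:
    """Greedy K2 search: returns the learned parent map.

    ``candidate_edges`` (unordered node pairs) restricts which earlier-
    ordered nodes may become parents — by default the pairs co-occurring in
    strong rules; ``None`` or an empty set means unrestricted.
    """
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    df, ar = _as_frame(data, arities)
    missing = [n for n in order if n not in df.columns]
    if missing:
        raise ValueError(f"order names nodes absent from the data: {missing}")
    allowed = {frozenset(e) for e in candidate_edges} if candidate_edges else None

    parents: dict[str, tuple[str, ...]] = {}
    for pos, node in enumerate(order):
        preds = list(order[:pos])
        if allowed is not None:
            preds = [p for p in preds if frozenset((p, node)) in allowed]
        chosen: list[str] = []
        best = family_score(df, node, chosen, ar)
        while len(chosen) < max_parents:
            gain_p, gain_s = None, best
            for p in preds:
                if p in chosen:
                    continue
                s = family_score(df, node, chosen + [p], ar)
                if s > gain_s:
                    gain_p, gain_s = p, s
            if gain_p is None:
                break
            chosen.append(gain_p)
            best = gain_s
        parents[node] = tuple(chosen)
    return parents


def structure_score(data, parents: Mapping[str, Sequence[str]], arities=None) -> float:
    """Total Cooper-Herskovits log score of a DAG (sum of family scores)."""
    df, ar = _as_frame(data, arities)
    return sum(family_score(df, n, tuple(ps), ar) for n, ps in parents.items())


# -- parameter learning --------------------------------------------------------


def learn_cpts(
    data,
    parents: Mapping[str, Sequence[str]],
    alpha: float = 0.5,
    arities: Mapping[str, int] | None = None,
    node_order: Sequence[str] | None = None,
    class_node: str = "class",
) -> BayesNet:
    """Dirichlet-smoothed conditional probability tables.

    ``P(v | pa) = (count(v, pa) + alpha) / (count(pa) + alpha * k)`` where k
    is the node's arity; an unobserved parent configuration therefore gives
    the uniform 1/k.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    df, ar = _as_frame(data, arities)
    nodes = list(parents.keys())
    cpts: dict[str, np.ndarray] = {}
    for node in nodes:
        ps = tuple(parents[node])
        r = ar[node]
        counts = _family_counts(df, node, ps, ar).astype(float)
        table = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
        dims = tuple(ar[p] for p in ps) + (r,)
        cpts[node] = table.reshape(dims)
    if class_node in df.columns:
        majority = int(df[class_node].value_counts().idxmax())
    else:
        majority = 0
    return BayesNet(
        nodes=nodes,
        arities={n: ar[n] for n in nodes},
        parents={n: tuple(parents[n]) for n in nodes},
        cpts=cpts,
        node_order=list(node_order) if node_order is not None else nodes,
        class_node=class_node,
        class_majority=majority,
        alpha=alpha,
    )
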
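from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_posterior, random_bayesnet, random_ds, random_weight_table

from wbbn.network import (
    BayesNet,
    build_node_order,
    family_score,
    k2_learn,
    learn_cpts,
    structure_score,
)
from wbbn.rulemining import WeightedRule
from wbbn.synthetic import chain_spec, generate, independent_spec
from wbbn.weighting import compute_weights


def _rule(ante, cons):
    return WeightedRule(frozenset(ante), frozenset(cons), ws=0.5, wc=0.9,
                        wbc=0.9, wbl=1.5, strong=True)


class TestNodeOrder:
    def test_sorted_by_descending_item_weight_class_last(self, toy_ds):
        wt = compute_weights(toy_ds)
        # toy: weight(item2) = 0.3 for att1; att2 items 3/4 weigh 0.1/0.2
        rules = [_rule({2}, {6}), _rule({4}, {6})]
        order = build_node_order(rules, wt, toy_ds.schema)
        assert order == ["att1", "att2", "class"]

    def test_alphabetical_tie_break(self, toy_ds):
        from test_weighting import _table_with

        wt = _table_with(toy_ds, {2: 0.3, 4: 0.3})
        rules = [_rule({4}, {6}), _rule({2}, {6})]
        assert build_node_order(rules, wt, toy_ds.schema) == ["att1", "att2", "class"]

    def test_empty_rule_list_is_an_error(self, toy_ds):
        with pytest.raises(ValueError):
            build_node_order([], compute_weights(toy_ds), toy_ds.schema)

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(8)
        ds = random_ds(rng, 5, 40)
        wt = random_weight_table(rng, ds)
        items = ds.schema.attribute_items
        rules = [_rule({items[i]}, {ds.schema.class_positive_item}) for i in (0, 2, 4, 6, 8)]
        order = build_node_order(rules, wt, ds.schema)
        totals = {
            ds.schema.item_owner(items[i]).name: wt.weight(items[i])
            for i in (0, 2, 4, 6, 8)
        }
        expect = sorted(totals, key=lambda n: (-totals[n], n)) + ["class"]
        assert order == expect


class TestK2:
    def test_independent_attributes_give_empty_graph(self):
        ds = generate(independent_spec(n_attributes=4, n_records=4000, seed=3))
        order = [a.name for a in ds.schema.attributes] + ["class"]
        dag = k2_learn(ds, order, max_parents=3)
        assert all(ps == () for ps in dag.values())

    def test_planted_chain_recovered(self):
        ds = generate(chain_spec(n_records=2000, seed=0))
        dag = k2_learn(ds, ["att1", "att2", "class"], max_parents=2)
        assert dag["att2"] == ("att1",)
        assert dag["class"] == ("att2",)

    def test_greedy_equals_exhaustive_on_three_nodes(self):
        ds = generate(chain_spec(n_records=1000, seed=5))
        df = ds.to_value_frame()
        arities = {c: 2 for c in df.columns}
        order = ["att1", "att2", "class"]
        dag = k2_learn(df, order, max_parents=2, arities=arities)
        for pos, node in enumerate(order):
            best, best_s = None, -np.inf
            for k in range(min(2, pos) + 1):
                for ps in combinations(order[:pos], k):
                    s = family_score(df, node, ps, arities)
                    if s > best_s:
                        best, best_s = set(ps), s
            assert set(dag[node]) == best

    def test_score_at_least_empty_graph(self):
        rng = np.random.default_rng(12)
        ds = random_ds(rng, 4, 150)
        order = [a.name for a in ds.schema.attributes] + ["class"]
        dag = k2_learn(ds, order, max_parents=3)
        df = ds.to_value_frame()
        ar = {c: 2 for c in df.columns}
        assert structure_score(df, dag, ar) >= structure_score(
            df, {n: () for n in order}, ar
        )

    def test_candidate_edge_restriction_respected(self):
        ds = generate(chain_spec(n_records=1500, seed=2))
        allowed = {frozenset(("att2", "class"))}
        dag = k2_learn(ds, ["att1", "att2", "class"], candidate_edges=allowed)
        assert dag["att2"] == ()  # att1-att2 not allowed
        assert dag["class"] == ("att2",)

    def test_order_missing_node_is_an_error(self, toy_ds):
        with pytest.raises(ValueError):
            k2_learn(toy_ds, ["att1", "nosuch"], max_parents=1)


class TestCpts:
    def test_smoothing_arithmetic(self):
        df = pd.DataFrame({"p": [0, 0, 0, 0], "c": [0, 0, 0, 1]})
        bn = learn_cpts(df, {"p": (), "c": ("p",)}, alpha=0.5,
                        arities={"p": 2, "c": 2}, class_node="c")
        # 3 of value 0, 1 of value 1 under parent config p=0
        assert bn.cpts["c"][0, 0] == pytest.approx((3 + 0.5) / (4 + 1))
        assert bn.cpts["c"][0, 1] == pytest.approx((1 + 0.5) / (4 + 1))

    def test_unseen_parent_configuration_is_uniform(self):
        df = pd.DataFrame({"p": [0, 0], "c": [0, 1]})
        bn = learn_cpts(df, {"p": (), "c": ("p",)}, alpha=0.5,
                        arities={"p": 2, "c": 2}, class_node="c")
        assert bn.cpts["c"][1] == pytest.approx([0.5, 0.5])

    def test_nonpositive_alpha_rejected(self, toy_ds):
        with pytest.raises(ValueError):
            learn_cpts(toy_ds, {"att1": (), "att2": (), "class": ()}, alpha=0.0)

    def test_cpt_rows_normalized_for_learned_networks(self):
        rng = np.random.default_rng(31)
        ds = random_ds(rng, 5, 200)
        order = [a.name for a in ds.schema.attributes] + ["class"]
        dag = k2_learn(ds, order, max_parents=3)
        bn = learn_cpts(ds, dag, alpha=0.5)
        for t in bn.cpts.values():
            assert np.allclose(t.sum(axis=-1), 1.0, atol=1e-9)

    def test_recovery_error_decreases_with_n(self):
        spec0 = chain_spec(seed=7)
        truth = spec0.to_network()
        errs = []
        for n in (200, 1000, 5000):
            errors = []
            for seed in range(3):
                from dataclasses import replace

                ds = generate(replace(spec0, n_records=n, seed=seed))
                bn = learn_cpts(ds, truth.parents, alpha=0.5)
                errors.append(
                    max(
                        np.max(np.abs(bn.cpts[v] - truth.cpts[v]))
                        for v in truth.nodes
                    )
                )
            errs.append(np.mean(errors))
        assert errs[0] > errs[2]
        assert errs[1] > errs[2]


class TestInference:
    def test_edgeless_fair_network_joint_is_quarter(self):
        bn = BayesNet(
            nodes=["a", "class"],
            arities={"a": 2, "class": 2},
            parents={"a": (), "class": ()},
            cpts={"a": np.array([0.5, 0.5]), "class": np.array([0.5, 0.5])},
            node_order=["a", "class"],
        )
        for va, vc in product(range(2), range(2)):
            assert bn.joint_probability({"a": va, "class": vc}) == pytest.approx(0.25)

    def test_joint_sums_to_one(self):
        rng = np.random.default_rng(44)
        bn = random_bayesnet(rng, 6)
        total = sum(
            bn.joint_probability(dict(zip(bn.nodes, combo)))
            for combo in product(*(range(2) for _ in bn.nodes))
        )
        assert total == pytest.approx(1.0)

    def test_incomplete_assignment_is_an_error(self):
        rng = np.random.default_rng(45)
        bn = random_bayesnet(rng, 4)
        with pytest.raises(ValueError):
            bn.joint_probability({bn.nodes[0]: 0})

    def test_posterior_normalized_and_matches_bruteforce(self):
        rng = np.random.default_rng(46)
        for _ in range(10):
            bn = random_bayesnet(rng, int(rng.integers(3, 8)))
            ev_nodes = [n for n in bn.nodes[:-1] if rng.random() < 0.6]
            ev = {n: int(rng.integers(0, 2)) for n in ev_nodes}
            post = bn.posterior(ev)
            assert post.sum() == pytest.approx(1.0)
            assert np.allclose(post, brute_posterior(bn, ev), atol=1e-12)

    def test_disconnected_class_posterior_is_smoothed_prior(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "class": [1, 1, 1, 0]})
        bn = learn_cpts(df, {"a": (), "class": ()}, alpha=0.5,
                        arities={"a": 2, "class": 2})
        post = bn.posterior({"a": 0})
        assert post[1] == pytest.approx((3 + 0.5) / (4 + 1))

    def test_near_deterministic_rule_predicts_positive(self):
        rng = np.random.default_rng(47)
        rows = []
        for _ in range(500):
            c = rng.random() < 0.5
            a = c if rng.random() < 0.98 else not c
            rows.append({"a": int(a), "class": int(c)})
        df = pd.DataFrame(rows)
        bn = learn_cpts(df, {"a": (), "class": ("a",)}, alpha=0.5,
                        arities={"a": 2, "class": 2})
        val, post = bn.predict({"a": 1})
        assert val == 1 and post > 0.95

    def test_evidence_outside_model_is_ignored(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1], "class": [0, 1, 0, 1]})
        bn = learn_cpts(df, {"a": (), "class": ("a",)}, alpha=0.5,
                        arities={"a": 2, "class": 2})
        assert np.allclose(bn.posterior({"a": 1, "zz": 5}), bn.posterior({"a": 1}))


class TestSerialization:
    def test_json_round_trip_preserves_inference(self, tmp_path):
        rng = np.random.default_rng(50)
        bn = random_bayesnet(rng, 5)
        p = tmp_path / "net.json"
        bn.to_json(p)
        back = BayesNet.from_json(p)
        ev = {bn.nodes[0]: 1}
        assert np.allclose(back.posterior(ev), bn.posterior(ev))
        assert back.parents == bn.parents

    def test_xmlbif_export_is_wellformed(self, tmp_path):
        from xml.etree import ElementTree

        rng = np.random.default_rng(51)
        bn = random_bayesnet(rng, 4)
        p = tmp_path / "net.xml"
        bn.to_xmlbif(p)
        root = ElementTree.parse(p).getroot()
        assert root.tag == "BIF"
        assert len(root.findall(".//VARIABLE")) == 4
        assert len(root.findall(".//DEFINITION")) == 4
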
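"""Route/complementation logic: prediction, concordance, rescue, inference."""
import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbotrait import load_fixture
from carbotrait import pathway_logic as pl
from carbotrait.datamodel import (GeneState, GeneStateMatrix, PathwayModel,
                                  Phenotype, PhenotypeMatrix)


def genes_of(states, strains, gene_ids):
    return GeneStateMatrix(pd.DataFrame(states, index=strains,
                                        columns=gene_ids))


def rule(sugar, *routes):
    return PathwayModel(sugar=sugar, routes=tuple(
        tuple(frozenset(g) for g in route) for route in routes))


class TestPredict:
    def test_arabinose_named_strains(self, table1):
        g = load_fixture("arabinose_states")
        model = load_fixture("rules/arabinose")
        pred = {e.strain: e.predicted for e in pl.predict(g, model)}
        for s in ("AWRI_B429", "IOEB_S450", "ATCC_BAA-1163", "IOEB_0607"):
            assert pred[s] is Phenotype.NEGATIVE
        assert pred["AWRI_B419"] is Phenotype.POSITIVE  # araD1 rescue
        assert pred["VF"] is Phenotype.POSITIVE  # intact triad

    def test_blocking_group_reported(self):
        g = genes_of([["P", "I"]], ["s"], ["araA", "araB"])
        model = rule("arabinose", [["araA"], ["araB"]])
        ev = pl.predict(g, model)[0]
        assert ev.predicted is Phenotype.NEGATIVE
        assert ev.blocking[0] == frozenset({"araA"})

    def test_empty_routes_and_empty_route(self):
        g = genes_of([["P"]], ["s"], ["x"])
        assert pl.predict(g, rule("s"))[0].predicted is Phenotype.NEGATIVE
        always = PathwayModel(sugar="s", routes=((),))
        assert pl.predict(g, always)[0].predicted is Phenotype.POSITIVE

    def test_unknown_gene_in_model(self):
        g = genes_of([["I"]], ["s"], ["x"])
        with pytest.raises(KeyError, match="ghost"):
            pl.predict(g, rule("s", [["ghost"]]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("APSI"), min_size=3, max_size=3),
           st.integers(0, 2))
    def test_monotone_upgrades_never_lose_a_positive(self, states, which):
        # upgrading any gene state toward INTACT never flips POSITIVE->NEGATIVE
        model = rule("s", [["g0", "g1"], ["g2"]])
        g1 = genes_of([states], ["s"], ["g0", "g1", "g2"])
        before = pl.predict(g1, model)[0].predicted
        upgraded = list(states)
        upgraded[which] = "I"
        g2 = genes_of([upgraded], ["s"], ["g0", "g1", "g2"])
        after = pl.predict(g2, model)[0].predicted
        assert not (before is Phenotype.POSITIVE
                    and after is Phenotype.NEGATIVE)

    def test_order_independent_over_strains(self):
        states = [["I", "P"], ["P", "I"], ["A", "A"]]
        g = genes_of(states, ["a", "b", "c"], ["x", "y"])
        g_rev = genes_of(states[::-1], ["c", "b", "a"], ["x", "y"])
        model = rule("s", [["x", "y"]])
        by_strain = {e.strain: e.predicted for e in pl.predict(g, model)}
        by_strain_rev = {e.strain: e.predicted
                         for e in pl.predict(g_rev, model)}
        assert by_strain == by_strain_rev


class TestConcordance:
    def test_ribose_rule_is_fully_concordant(self, table1):
        g = load_fixture("ribose_states")
        model = load_fixture("rules/ribose")
        rep = pl.concordance(pl.predict(g, model), table1, "ribose")
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (37, 0, 0, 4)
        assert rep.accuracy == 1.0
        # the four ribT-truncated strains are true negatives
        neg = {e.strain for e in pl.predict(g, model)
               if e.predicted is Phenotype.NEGATIVE}
        assert neg == {"IOEB_1491", "IOEB_B10", "S25", "S19"}
        # IOEB_C23 is rescued by its strain-specific permease
        c23 = next(e for e in pl.predict(g, model) if e.strain == "IOEB_C23")
        assert c23.predicted is Phenotype.POSITIVE

    def test_fructose_rule_explains_15_of_19(self, table1):
        g = load_fixture("fructose_states")
        model = load_fixture("rules/fructose")
        rep = pl.concordance(pl.predict(g, model), table1, "fructose")
        assert (rep.tp, rep.fn) == (15, 4)
        assert {s for s, kind in rep.discordant if kind == "FN"} == \
            {"S11", "IOEB_L40.4", "AWRI_B129", "PSU-1"}

    def test_zero_route_rule_predicts_all_negative(self, table1):
        g = load_fixture("ribose_states")
        rep = pl.concordance(pl.predict(g, rule("ribose")), table1, "ribose")
        assert rep.tp == 0 and rep.fp == 0 and rep.fn == 37

    def test_perfect_toy(self):
        g = genes_of([["I"], ["I"], ["P"], ["A"]], list("abcd"), ["x"])
        p = PhenotypeMatrix(pd.DataFrame([[1], [1], [0], [0]],
                                         index=list("abcd"), columns=["s"]))
        rep = pl.concordance(pl.predict(g, rule("s", [["x"]])), p, "s")
        assert rep.accuracy == 1.0 and not rep.discordant


class TestComplementation:
    def test_trehalose_rescues(self, table1):
        g = load_fixture("trehalose_states")
        events, unexplained = pl.detect_complementation(
            g, table1, "trehalose", [["treC", "treC1"]])
        assert {e.strain for e in events} == {"ATCC_BAA-1163", "S13",
                                              "AWRI_B419"}
        assert all(e.rescuers == ("treC1",) for e in events)
        assert not unexplained

    def test_all_functional_yields_no_event(self, table1):
        g = load_fixture("trehalose_states")
        events, _ = pl.detect_complementation(g, table1, "trehalose",
                                              [["treP", "treC1"]])
        assert events == []

    def test_unexplained_positive_flagged(self, table1):
        g = load_fixture("maltose_states")
        # malA truncated in IOEB_0502, no declared rescuer, phenotype positive
        events, unexplained = pl.detect_complementation(
            g, table1, "maltose", [["malA"]])
        assert "IOEB_0502" in unexplained and not events


class TestInferRules:
    def _truth_table_dataset(self):
        # 8 strains covering every functional combination of 3 genes;
        # phenotype = (g1 and g2) or g3
        combos = list(itertools.product("IP", repeat=3))
        strains = [f"s{i}" for i in range(8)]
        g = genes_of([list(c) for c in combos], strains, ["g1", "g2", "g3"])
        phen = [[int((a == "I" and b == "I") or c == "I")]
                for a, b, c in combos]
        p = PhenotypeMatrix(pd.DataFrame(phen, index=strains, columns=["s"]))
        return g, p

    def test_exact_rule_recovered_from_truth_table(self):
        g, p = self._truth_table_dataset()
        out = pl.infer_rules(g, p, "s", ["g1", "g2", "g3"], max_routes=2,
                             max_groups_per_route=2, max_group_size=1)
        true = rule("s", [["g1"], ["g2"]], [["g3"]])
        assert out.best_accuracy == 1.0
        assert [m.routes for m in out.rules] == [true.routes]
        assert not out.low_confidence

    def test_brute_force_oracle_agrees_on_best_accuracy(self):
        # independent oracle: score every rule by direct per-strain evaluation
        g, p = self._truth_table_dataset()
        genes = ["g1", "g2", "g3"]
        func = {gn: [g.state(s, gn) is GeneState.INTACT
                     for s in g.strain_ids] for gn in genes}
        obs = [bool(v) for v in p.values["s"]]

        def acc(routes):
            hits = 0
            for i in range(len(obs)):
                pred = any(all(any(func[gn][i] for gn in grp) for grp in rt)
                           for rt in routes)
                hits += pred == obs[i]
            return hits / len(obs)

        groups = [frozenset({gn}) for gn in genes]
        routes = [()] + [tuple(c) for k in (1, 2)
                         for c in itertools.combinations(groups, k)]
        best = max(acc(list(combo)) for r in (0, 1, 2)
                   for combo in itertools.combinations(routes, r))
        out = pl.infer_rules(g, p, "s", genes, max_routes=2,
                             max_groups_per_route=2, max_group_size=1)
        assert out.best_accuracy == best == 1.0

    def test_all_positive_gives_unique_empty_route_rule(self):
        g = genes_of([["I"], ["P"]], ["a", "b"], ["x"])
        p = PhenotypeMatrix(pd.DataFrame([[1], [1]], index=["a", "b"],
                                         columns=["s"]))
        out = pl.infer_rules(g, p, "s", ["x"])
        assert len(out.rules) == 1
        assert out.rules[0].routes == ((),)  # the always-true rule

    def test_independent_phenotype_flagged_low_confidence(self):
        g = genes_of([["I"], ["I"], ["P"], ["P"]], list("abcd"), ["x"])
        p = PhenotypeMatrix(pd.DataFrame([[1], [0], [1], [0]],
                                         index=list("abcd"), columns=["s"]))
        out = pl.infer_rules(g, p, "s", ["x"])
        assert out.low_confidence
        assert out.best_accuracy == out.majority_accuracy == 0.5

    def test_enumeration_guard(self):
        strains = [f"s{i}" for i in range(4)]
        g = genes_of([["I"] * 20] * 4, strains,
                     [f"g{i}" for i in range(20)])
        p = PhenotypeMatrix(pd.DataFrame([[1]] * 4, index=strains,
                                         columns=["s"]))
        with pytest.raises(ValueError, match="tighten the bounds"):
            pl.infer_rules(g, p, "s", [f"g{i}" for i in range(20)],
                           max_routes=3, max_groups_per_route=3,
                           max_group_size=2)

    def test_no_candidates_rejected(self, table1):
        g = load_fixture("ribose_states")
        with pytest.raises(ValueError, match="candidate"):
            pl.infer_rules(g, table1, "ribose", [])

    def test_minimality_and_accuracy_helpers(self):
        g, p = self._truth_table_dataset()
        true = rule("s", [["g1"], ["g2"]], [["g3"]])
        padded = rule("s", [["g1"], ["g2"]], [["g3"]], [["g1"], ["g3"]])
        assert pl.training_accuracy(g, p, true) == 1.0
        assert pl.training_accuracy(g, p, padded) == 1.0
        assert pl.is_minimal(g, p, true)
        assert not pl.is_minimal(g, p, padded)
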
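"""MICA, GraSM and DiShIn shared information content."""

import itertools

import numpy as np
import pytest

from dishin import (
    ICTable,
    dca_dishin,
    grasm_dca,
    path_difference,
    share_dishin,
    share_grasm,
    share_mica,
    shared_information,
    transitive_closure_paths,
)
from dishin.errors import NotAnAncestorError, ZeroFrequencyError

from conftest import build_engine, oracle_dishin, random_instance

METALS_PD = [
    ("platinum", "palladium", "precious", 0),
    ("platinum", "palladium", "metal", 0),
    ("platinum", "gold", "precious", 0),
    ("platinum", "gold", "metal", 1),
    ("silver", "gold", "precious", 0),
    ("silver", "gold", "coinage", 0),
    ("silver", "gold", "metal", 0),
]


class TestPathDifference:
    @pytest.mark.parametrize("c1,c2,a,expected", METALS_PD)
    def test_metals_worked_values(self, metals, c1, c2, a, expected):
        _, paths, _ = metals
        assert path_difference(paths, c1, c2, a) == expected

    def test_self_comparison_is_zero(self, metals):
        bundle, paths, _ = metals
        for a in bundle.dag.ancestors("gold"):
            assert path_difference(paths, "gold", "gold", a) == 0

    def test_non_common_ancestor_rejected(self, metals):
        _, paths, _ = metals
        with pytest.raises(NotAnAncestorError):
            path_difference(paths, "platinum", "gold", "coinage")


class TestShareMica:
    def test_copper_gold_mica_is_coinage(self, metals):
        bundle, paths, ic = metals
        result = share_mica(ic, paths.common_ancestors("copper", "gold"))
        assert result.dca == ("coinage",)
        assert result.value == ic["coinage"]

    def test_self_share_is_own_ic(self, metals):
        _, paths, ic = metals
        result = share_mica(ic, paths.common_ancestors("gold", "gold"))
        assert result.dca == ("gold",)
        assert result.value == ic["gold"]

    def test_empty_common_ancestors(self, metals):
        _, _, ic = metals
        result = share_mica(ic, set())
        assert result.value == 0.0 and result.dca == ()

    def test_ic_tie_breaks_lexicographically(self):
        ic = ICTable(ic={"b": 1.0, "a": 1.0, "z": 0.5})
        assert share_mica(ic, {"a", "b", "z"}).dca == ("a",)


class TestDcaDishin:
    def test_platinum_gold(self, metals):
        _, paths, ic = metals
        assert set(dca_dishin(ic, paths, "platinum", "gold")) == {"precious", "metal"}

    def test_platinum_palladium(self, metals):
        _, paths, ic = metals
        assert dca_dishin(ic, paths, "platinum", "palladium") == ("precious",)

    def test_silver_gold_picks_higher_ic_parallel_parent(self, metals):
        _, paths, ic = metals
        winner = "coinage" if ic["coinage"] > ic["precious"] else "precious"
        assert dca_dishin(ic, paths, "silver", "gold") == (winner,)

    def test_self_comparison_singleton(self, metals):
        _, paths, ic = metals
        assert dca_dishin(ic, paths, "gold", "gold") == ("gold",)

    def test_ordered_by_descending_ic(self, metals):
        _, paths, ic = metals
        dca = dca_dishin(ic, paths, "platinum", "gold")
        assert [ic[a] for a in dca] == sorted((ic[a] for a in dca), reverse=True)


class TestShareDishin:
    def test_hydroxylase_value(self, hydroxylase, hydroxylase_leaves):
        bundle, paths, ic = hydroxylase
        l1, l2 = hydroxylase_leaves
        result = share_dishin(ic, paths, l1, l2)
        assert result.value == pytest.approx(0.6671, abs=1e-12)
        assert result.dca == ("steroid-hydroxylase-activity",)

    def test_fixture_ics_give_mean_of_dca(self, metals):
        """With IC(precious)=0.9, IC(metal)=0.3 the platinum/gold share is 0.6."""
        _, paths, _ = metals
        ic = ICTable(
            ic={"precious": 0.9, "metal": 0.3, "coinage": 0.8,
                "platinum": 1.5, "gold": 1.5}
        )
        assert share_dishin(ic, paths, "platinum", "gold").value == pytest.approx(
            0.6, abs=1e-12
        )

    def test_self_share(self, metals):
        _, paths, ic = metals
        assert share_dishin(ic, paths, "gold", "gold").value == ic["gold"]

    def test_query_concept_without_ic_rejected(self, metals):
        bundle, paths, _ = metals
        ic = ICTable(ic={"metal": 0.0})
        with pytest.raises(ZeroFrequencyError):
            share_dishin(ic, paths, "gold", "silver")


class TestGrasm:
    def test_metals_dca_sets(self, metals):
        bundle, paths, ic = metals
        dag = bundle.dag
        assert set(grasm_dca(ic, paths, dag, "silver", "gold")) == {"precious", "coinage"}
        assert grasm_dca(ic, paths, dag, "platinum", "palladium") == ("precious",)

    def test_hydroxylase_two_disjunctive_ancestors(self, hydroxylase, hydroxylase_leaves):
        bundle, paths, ic = hydroxylase
        l1, l2 = hydroxylase_leaves
        assert set(grasm_dca(ic, paths, bundle.dag, l1, l2)) == {
            "steroid-hydroxylase-activity",
            "oxidoreductase-activity-on-paired-donors-with-o2",
        }
        assert share_grasm(ic, paths, bundle.dag, l1, l2).value == pytest.approx(
            (0.6671 + 0.3846) / 2, abs=1e-12
        )

    def test_silver_gold_share_averages_parallel_parents(self, metals):
        bundle, paths, ic = metals
        result = share_grasm(ic, paths, bundle.dag, "silver", "gold")
        assert result.value == pytest.approx(
            (ic["precious"] + ic["coinage"]) / 2, abs=1e-12
        )

    def test_tree_dag_degenerates_to_mica(self):
        dag, corpus = random_instance(5, n=14, density=1.0, n_entities=12)
        ic, paths = build_engine(dag, corpus)
        concepts = sorted(c for c in dag if c in ic)
        for c1, c2 in itertools.combinations(concepts, 2):
            mica = share_mica(ic, paths.common_ancestors(c1, c2))
            grasm = share_grasm(ic, paths, dag, c1, c2)
            assert grasm.value == pytest.approx(mica.value, abs=1e-12)
            assert grasm.dca == mica.dca

    def test_self_share(self, metals):
        bundle, paths, ic = metals
        result = share_grasm(ic, paths, bundle.dag, "gold", "gold")
        assert result.dca == ("gold",)
        assert result.value == ic["gold"]


class TestProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_share_never_exceeds_mica_and_is_symmetric(self, seed):
        dag, corpus = random_instance(seed, n=10, density=1.8, n_entities=10)
        ic, paths = build_engine(dag, corpus)
        concepts = sorted(c for c in dag if c in ic)
        for c1, c2 in itertools.combinations(concepts, 2):
            mica = shared_information("mica", ic, paths, dag, c1, c2)
            for method in ("dishin", "grasm"):
                fwd = shared_information(method, ic, paths, dag, c1, c2)
                rev = shared_information(method, ic, paths, dag, c2, c1)
                assert fwd.value == pytest.approx(rev.value, abs=1e-12)
                assert fwd.value <= mica.value + 1e-12
                if len(fwd.dca) == 1:
                    assert fwd.value == pytest.approx(mica.value, abs=1e-12)
                assert mica.dca[0] in fwd.dca

    @pytest.mark.parametrize("seed", range(4))
    def test_dishin_matches_enumeration_oracle(self, seed):
        dag, corpus = random_instance(seed + 50, n=11, density=1.7, n_entities=10)
        ic, paths = build_engine(dag, corpus)
        concepts = sorted(c for c in dag if c in ic)
        for c1, c2 in itertools.combinations(concepts, 2):
            assert share_dishin(ic, paths, c1, c2).value == pytest.approx(
                oracle_dishin(ic, dag, c1, c2), abs=1e-12
            )

    def test_metals_ordering_under_random_ics(self, metals):
        """Share(silver,gold) >= Share(platinum,palladium) > Share(platinum,gold)
        for any IC assignment with IC(precious), IC(coinage) > IC(metal) > 0."""
        _, paths, _ = metals
        rng = np.random.default_rng(20110831)
        for _ in range(100):
            metal = rng.uniform(0.05, 1.0)
            precious = metal + rng.uniform(0.01, 2.0)
            coinage = metal + rng.uniform(0.01, 2.0)
            leaves = max(precious, coinage) + 1.0
            ic = ICTable(ic={
                "metal": metal, "precious": precious, "coinage": coinage,
                "platinum": leaves, "palladium": leaves,
                "silver": leaves, "gold": leaves,
            })
            s_ag_au = share_dishin(ic, paths, "silver", "gold").value
            s_pt_pd = share_dishin(ic, paths, "platinum", "palladium").value
            s_pt_au = share_dishin(ic, paths, "platinum", "gold").value
            assert s_ag_au >= s_pt_pd > s_pt_au
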
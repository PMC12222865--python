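"""Community merging and MIP/MRO scoring contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from syncomkit import community as cm, gem, minimal_media as mm
from syncomkit.synthetic_data import CrossFeedSpec, expected_mip, make_crossfeeding_panel


@pytest.fixture
def mutual_pair():
    """A needs x (secreted by B), B needs y (secreted by A), both need c."""
    spec = CrossFeedSpec(2, [("B", "A", "x"), ("A", "B", "y")],
                         strain_ids=("A", "B"))
    return spec, make_crossfeeding_panel(spec)


class TestMerge:
    def test_structure_doubles_reactions_plus_pool(self, chain_model):
        a, b = chain_model.copy(), chain_model.copy()
        a.id, b.id = "A", "B"
        comm = cm.merge_community([a, b], "interacting")
        n = len(chain_model.reactions)
        # per-member copies plus one shared pool exchange per env metabolite
        assert len(comm.merged.reactions) == 2 * n + 1
        assert comm.env_groups == {"c_e": ["EX__c_e"]}

    def test_private_pools_in_non_interacting_regime(self, chain_model):
        a, b = chain_model.copy(), chain_model.copy()
        a.id, b.id = "A", "B"
        comm = cm.merge_community([a, b], "non_interacting")
        assert sorted(comm.env_groups["c_e"]) == ["EX__A__c_e", "EX__B__c_e"]

    def test_duplicate_member_ids_rejected(self, chain_model):
        with pytest.raises(cm.MergeError, match="duplicate"):
            cm.merge_community([chain_model, chain_model.copy()])

    def test_unknown_regime_rejected(self, chain_model):
        a, b = chain_model.copy(), chain_model.copy()
        a.id, b.id = "A", "B"
        with pytest.raises(ValueError, match="regime"):
            cm.merge_community([a, b], "telepathic")

    def test_cross_feeding_only_in_interacting_regime(self, mutual_pair):
        """On carbon alone the pair grows only when secretions are shared."""
        _, models = mutual_pair
        thresholds = {"A": 1.0, "B": 1.0}
        inter = cm.merge_community(list(models.values()), "interacting")
        non = cm.merge_community(list(models.values()), "non_interacting")
        med_i = cm.community_minimal_medium(inter, thresholds)
        med_n = cm.community_minimal_medium(non, thresholds)
        assert med_i.metabolite_ids == {"c1_e"}
        assert med_n.metabolite_ids == {"c1_e", "x_e", "y_e"}


class TestMIP:
    def test_mutual_exchange_pair_spares_two_nutrients(self, mutual_pair):
        spec, models = mutual_pair
        assert cm.mip_score(list(models.values())) == 2
        assert expected_mip(spec, ["A", "B"]) == 2

    def test_self_sufficient_copies_share_nothing(self, chain_model):
        a, b = chain_model.copy(), chain_model.copy()
        a.id, b.id = "A", "B"
        assert cm.mip_score([a, b]) == 0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_chain_of_k_exchanges(self, k):
        """A donor chain with k engineered one-way exchanges has MIP k."""
        n = k + 1
        triples = [(f"S{i+1}", f"S{i+2}", f"aa{i}") for i in range(k)]
        spec = CrossFeedSpec(n, triples)
        models = make_crossfeeding_panel(spec)
        got = cm.mip_score([models[s] for s in spec.strain_ids])
        assert got == k == expected_mip(spec, spec.strain_ids)

    def test_member_that_cannot_grow_is_named(self, chain_model, c_or_d_model):
        dead = chain_model.copy()
        dead.id = "dead"
        dead.reactions.T_c.upper_bound = 0
        with pytest.raises(mm.GrowthError, match="dead"):
            cm.mip_score([dead, c_or_d_model])


class TestMRO:
    def test_identical_members_full_overlap(self, c_and_n_model):
        a, b = c_and_n_model.copy(), c_and_n_model.copy()
        a.id, b.id = "A", "B"
        assert cm.mro_score([a, b]) == pytest.approx(1.0)

    def test_disjoint_media_no_overlap(self, chain_model):
        a = chain_model.copy()
        a.id = "A"
        b = chain_model.copy()
        b.id = "B"
        # rename B's carbon so the two minimal media are disjoint
        b.metabolites.c_e.id = "d_e"
        b.repair()
        assert cm.mro_score([a, b]) == pytest.approx(0.0)

    def test_hand_computed_half(self, mutual_pair):
        # M_A = {c, x}, M_B = {c, y}: intersection 1, mean size 2
        _, models = mutual_pair
        assert cm.mro_score(list(models.values())) == pytest.approx(0.5)

    def test_alternate_media_averaging(self, c_or_d_model):
        a, b = c_or_d_model.copy(), c_or_d_model.copy()
        a.id, b.id = "A", "B"
        # single lexicographic media are both {c} -> MRO 1; averaging over
        # the 2x2 alternate combinations gives mean intersection 0.5
        assert cm.mro_score([a, b]) == pytest.approx(1.0)
        assert cm.mro_score([a, b], n_alternates=4) == pytest.approx(0.5)


class TestEnumeration:
    def test_six_strains_two_to_six(self):
        subsets = cm.enumerate_communities(list("ABCDEF"), 2, 6)
        assert len(subsets) == 57

    def test_three_strains(self):
        assert len(cm.enumerate_communities(list("ABC"), 2, 3)) == 4

    def test_large_pairwise_count(self):
        ids = [f"s{i:03d}" for i in range(224)]
        pairs = cm.enumerate_communities(ids, 2, 2)
        assert len(pairs) == math.comb(224, 2) == 24976

    def test_deterministic_lexicographic_order(self):
        subsets = cm.enumerate_communities(["b", "a", "c"], 2, 3)
        assert subsets[0] == ("a", "b")
        assert subsets == cm.enumerate_communities(["c", "b", "a"], 2, 3)

    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            cm.enumerate_communities(list("ABC"), 3, 2)
        with pytest.raises(ValueError):
            cm.enumerate_communities(list("ABC"), 1, 3)


class TestScoreAll:
    def test_missing_model_fails_before_solving(self, chain_model):
        with pytest.raises(KeyError, match="ghost"):
            cm.score_all({"A": chain_model}, [("A", "ghost")])

    def test_order_invariance_and_columns(self, mutual_pair):
        _, models = mutual_pair
        t1 = cm.score_all(models, [("A", "B")])
        t2 = cm.score_all(models, [("B", "A")])
        assert t1.loc[0, "mip"] == t2.loc[0, "mip"] == 2
        assert t1.loc[0, "mro"] == t2.loc[0, "mro"]
        assert t1.loc[0, "members"] == t2.loc[0, "members"] == "A;B"

    def test_independent_panel_all_zero_mip(self, chain_model):
        models = {}
        for name in "ABC":
            m = chain_model.copy()
            m.id = name
            models[name] = m
        table = cm.score_all(models, cm.enumerate_communities(list("ABC"), 2, 3))
        assert (table["mip"] == 0).all()


class TestDropout:
    def test_dropping_sole_donor_collapses_mip(self):
        spec = CrossFeedSpec(3, [("S1", "S2", "x"), ("S1", "S3", "y")])
        models = make_crossfeeding_panel(spec)
        scan = cm.dropout_scan(models, ["S1", "S2", "S3"])
        assert len(scan) == 4
        full = scan.loc[0]
        assert full["mip"] == 2
        no_donor = scan[scan["dropped"] == "S1"].iloc[0]
        assert no_donor["mip"] == 0 and no_donor["delta_mip"] == -2
        # dropping a recipient removes only its own exchange
        no_s2 = scan[scan["dropped"] == "S2"].iloc[0]
        assert no_s2["mip"] == 1

    def test_redundant_member_changes_nothing(self, chain_model):
        models = {}
        for name in "ABC":
            m = chain_model.copy()
            m.id = name
            models[name] = m
        scan = cm.dropout_scan(models, ["A", "B", "C"])
        assert (scan["delta_mip"] == 0).all()

    def test_needs_at_least_three_members(self, mutual_pair):
        _, models = mutual_pair
        with pytest.raises(ValueError):
            cm.dropout_scan(models, ["A", "B"])


class TestRanking:
    def test_mip_priority_then_mro_then_members(self):
        scores = pd.DataFrame({
            "members": ["A;B", "C;D", "E;F", "A;C"],
            "size": [2, 2, 2, 2],
            "mip": [4, 1, 4, 4],
            "mro": [0.77, 0.50, 0.84, 0.77],
        })
        ranked = cm.rank_communities(scores)
        assert ranked["members"].tolist() == ["A;B", "A;C", "E;F", "C;D"]

    def test_size_range_filter(self):
        scores = pd.DataFrame({
            "members": ["A;B", "A;B;C"], "size": [2, 3],
            "mip": [1, 0], "mro": [0.5, 0.5],
        })
        ranked = cm.rank_communities(scores, size_range=(3, 3))
        assert ranked["members"].tolist() == ["A;B;C"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cm.rank_communities(pd.DataFrame())


def test_scores_invariants_on_random_panels():
    """MIP is a non-negative integer and MRO in [0,1] on generated panels."""
    rng = np.random.default_rng(42)
    for _ in range(3):
        n = int(rng.integers(2, 5))
        triples = []
        for k in range(int(rng.integers(0, 4))):
            d, r = rng.choice(n, 2, replace=False)
            triples.append((f"S{d+1}", f"S{r+1}", f"m{k}"))
        spec = CrossFeedSpec(n, triples)
        models = make_crossfeeding_panel(spec)
        scores = cm.score_community(list(models.values()))
        assert scores.mip >= 0 and isinstance(scores.mip, int)
        assert 0.0 <= scores.mro <= 1.0
        assert scores.mip == expected_mip(spec, spec.strain_ids)
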
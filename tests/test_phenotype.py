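"""Niche indices: Levins width, Pianka overlap, NSR/BSR classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncomkit import phenotype as ph


def panel_of(rows, threshold=50.0, strains=None, resources=None):
    strains = strains or [f"S{i+1}" for i in range(len(rows))]
    resources = resources or [f"r{j+1}" for j in range(len(rows[0]))]
    df = pd.DataFrame(rows, index=strains, columns=resources)
    return ph.panel_from_frame(df, threshold)


class TestLoadPanel:
    def test_threshold_masks(self):
        p = panel_of([[60, 60, 10], [0, 0, 100]])
        assert p["S1"].mask.tolist() == [True, True, False]
        assert p["S2"].mask.tolist() == [False, False, True]

    def test_threshold_is_strict(self):
        # a signal exactly at the cutoff does not count as utilization
        p = panel_of([[50, 60, 0]])
        assert p["S1"].mask.tolist() == [False, True, False]

    def test_zero_row_warns_and_is_retained(self):
        with pytest.warns(UserWarning, match="no resource"):
            p = panel_of([[0, 0, 0], [60, 60, 60]])
        assert not p["S1"].mask.any()
        assert p["S1"].proportions.sum() == 0.0

    @pytest.mark.parametrize(
        "df,msg",
        [
            (pd.DataFrame(), "empty"),
            (pd.DataFrame([[1, "oops"]], index=["A"], columns=["r1", "r2"]),
             "non-numeric"),
            (pd.DataFrame([[1, 2], [3, 4]], index=["A", "A"], columns=["r1", "r2"]),
             "duplicated strain"),
            (pd.DataFrame([[1, 2]], index=["A"], columns=["r", "r"]),
             "duplicated resource"),
        ],
    )
    def test_malformed_tables_rejected(self, df, msg):
        with pytest.raises(ph.PanelError, match=msg):
            ph.panel_from_frame(df, 50)

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "panel.csv"
        pd.DataFrame([[60, 10], [70, 80]], index=["A", "B"],
                     columns=["r1", "r2"]).to_csv(path)
        p = ph.load_panel(path, threshold=50)
        assert p.strains == ("A", "B")
        assert p["A"].n_utilized == 1


class TestNicheWidth:
    def test_uniform_signal_gives_count(self):
        for k in (1, 3, 7):
            p = panel_of([[100] * k + [0] * (8 - k)])
            assert ph.niche_width(p["S1"]) == pytest.approx(k)

    def test_hand_computed_width(self):
        # P = (0.5, 0.3, 0.2): W = 1/(0.25+0.09+0.04) = 1/0.38
        prof = ph.UtilizationProfile.from_signal("x", ["a", "b", "c"],
                                                 [0.5, 0.3, 0.2], threshold=0)
        assert ph.niche_width(prof) == pytest.approx(1 / 0.38)
        assert ph.niche_width(prof) == pytest.approx(2.6316, abs=1e-4)

    def test_no_utilized_resource_is_an_error_not_zero(self):
        with pytest.warns(UserWarning):
            p = panel_of([[0, 0]])
        with pytest.raises(ph.UndefinedIndexError):
            ph.niche_width(p["S1"])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        signal=st.lists(st.floats(51, 1e4), min_size=1, max_size=20),
        scale=st.floats(0.51, 100),
    )
    def test_scale_invariance_and_bounds(self, signal, scale):
        a = ph.UtilizationProfile.from_signal("a", [f"r{i}" for i in range(len(signal))],
                                              signal, threshold=50)
        b = ph.UtilizationProfile.from_signal("b", a.resource_ids,
                                              np.asarray(signal) * scale,
                                              threshold=50 * scale)
        wa, wb = ph.niche_width(a), ph.niche_width(b)
        assert wa == pytest.approx(wb, rel=1e-9)
        assert 1.0 - 1e-9 <= wa <= ph.simplified_width(a) + 1e-9


class TestSimplifiedWidth:
    def test_counts_mask(self):
        p = panel_of([[60, 0, 60, 60]])
        assert ph.simplified_width(p["S1"]) == 3

    def test_zero_profile_counts_zero(self):
        with pytest.warns(UserWarning):
            p = panel_of([[0, 0, 0], [99, 99, 99]])
        assert ph.simplified_width(p["S1"]) == 0

    def test_thresholded_count_on_58_resources(self):
        rng = np.random.default_rng(0)
        signal = np.concatenate([rng.uniform(51, 300, 20), rng.uniform(0, 50, 38)])
        prof = ph.UtilizationProfile.from_signal(
            "s", [f"r{i}" for i in range(58)], rng.permutation(signal))
        assert ph.simplified_width(prof) == 20


class TestPiankaOverlap:
    def test_identical_profiles_overlap_one(self):
        p = panel_of([[60, 80, 0], [60, 80, 0]])
        assert ph.pianka_overlap(p["S1"], p["S2"]) == pytest.approx(1.0)

    def test_disjoint_profiles_overlap_zero(self):
        p = panel_of([[60, 0, 0], [0, 0, 90]])
        assert ph.pianka_overlap(p["S1"], p["S2"]) == 0.0

    def test_hand_computed_half(self):
        a = ph.UtilizationProfile.from_signal("a", list("xyz"), [0.5, 0.5, 0], 0)
        b = ph.UtilizationProfile.from_signal("b", list("xyz"), [0, 0.5, 0.5], 0)
        assert ph.pianka_overlap(a, b) == pytest.approx(0.5)

    def test_zero_norm_profile_errors(self):
        with pytest.warns(UserWarning):
            p = panel_of([[0, 0], [60, 60]])
        with pytest.raises(ph.UndefinedIndexError):
            ph.pianka_overlap(p["S1"], p["S2"])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=15),
           st.lists(st.floats(0, 1000), min_size=2, max_size=15),
           st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, s1, s2, seed):
        n = min(len(s1), len(s2))
        rng = np.random.default_rng(seed)
        sig1 = np.asarray(s1[:n]) + rng.uniform(51, 60, n)  # ensure nonzero
        sig2 = np.asarray(s2[:n]) + rng.uniform(51, 60, n)
        res = [f"r{i}" for i in range(n)]
        a = ph.UtilizationProfile.from_signal("a", res, sig1)
        b = ph.UtilizationProfile.from_signal("b", res, sig2)
        o1, o2 = ph.pianka_overlap(a, b), ph.pianka_overlap(b, a)
        assert o1 == o2
        assert 0.0 <= o1 <= 1.0


class TestAverageOverlap:
    def test_two_strain_panel_equals_pairwise(self):
        p = panel_of([[60, 80, 0], [70, 0, 90]])
        assert ph.average_overlap(p, "S1") == pytest.approx(
            ph.pianka_overlap(p["S1"], p["S2"]))

    def test_mean_over_partners(self):
        # build a panel then verify the mean matches the pairwise values
        p = panel_of([[100, 100, 0, 0], [100, 100, 100, 100], [0, 0, 100, 100]])
        o12 = ph.pianka_overlap(p["S1"], p["S2"])
        o13 = ph.pianka_overlap(p["S1"], p["S3"])
        assert ph.average_overlap(p, "S1") == pytest.approx((o12 + o13) / 2)

    def test_unknown_strain_errors(self):
        p = panel_of([[60, 0], [0, 60]])
        with pytest.raises(KeyError, match="nope"):
            ph.average_overlap(p, "nope")


class TestClassification:
    def test_tail_thresholds_inclusive(self):
        assert ph.classify_nsr_bsr([3, 15, 40]) == ["NSR", "intermediate", "BSR"]
        assert ph.classify_nsr_bsr([7, 29]) == ["NSR", "BSR"]
        assert ph.classify_nsr_bsr([8, 28]) == ["intermediate", "intermediate"]

    def test_bad_configuration(self):
        with pytest.raises(ValueError):
            ph.classify_nsr_bsr([5], low=10, high=10)


class TestSiderophoreIndex:
    @pytest.mark.parametrize("a_s,a_r,expected", [(0.6, 0.6, 0.0), (0.0, 0.6, 1.0),
                                                  (0.3, 0.6, 0.5)])
    def test_values(self, a_s, a_r, expected):
        assert ph.cas_siderophore_index(a_s, a_r) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ph.cas_siderophore_index(0.5, 0.0)
        with pytest.raises(ValueError):
            ph.cas_siderophore_index(-0.1, 0.5)


def test_profile_table_columns_and_classes():
    p = panel_of([[100] * 3 + [0] * 30, [100] * 30 + [0] * 3])
    t = ph.profile_table(p)
    assert list(t.columns) == ["niche_width", "simplified_width",
                               "average_overlap", "class"]
    assert t.loc["S1", "class"] == "NSR"
    assert t.loc["S2", "class"] == "BSR"
    assert t.loc["S1", "niche_width"] == pytest.approx(3)
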
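"""Regulation calls, response sets, Grubbs test, profiles, marker scoring."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alomypipe import diffexp, simdata
from alomypipe.diffexp import (
    build_response_sets,
    classify_profile,
    concordance_counts,
    grubbs_critical,
    grubbs_outlier,
    marker_concordance,
    regulation_call,
)

DESIGN = simdata.default_design(10_000)


class TestRegulationCall:
    @pytest.mark.parametrize(
        "a,b,call",
        [
            (4.0, 1.9, "up"),  # fold 2.11, max 4.0 >= 1.8
            (1.0, 0.4, "stable"),  # fold 2.5 but max 1.0 < 1.8
            (1.9, 4.0, "down"),
            (3.0, 2.0, "stable"),  # fold 1.5
            (2.0, 0.0, "up"),  # zero denominator -> epsilon
            (0.0, 0.0, "stable"),
        ],
    )
    def test_rule_applications(self, a, b, call):
        assert regulation_call(a, b).call == call

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            regulation_call(-1.0, 2.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(0, 50, allow_nan=False),
        st.floats(0, 50, allow_nan=False),
    )
    def test_antisymmetry_under_swap(self, a, b):
        fwd = regulation_call(a, b).call
        rev = regulation_call(b, a).call
        assert {"up": "down", "down": "up", "stable": "stable"}[fwd] == rev

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(1.8, 50),
        st.floats(1.8, 50),
        st.floats(1, 10),
    )
    def test_scale_invariance_above_threshold(self, a, b, c):
        assert regulation_call(a, b).call == regulation_call(a * c, b * c).call


class TestResponseSets:
    def make_rpkm(self, rows):
        cols = [m.name for m in DESIGN]
        return pd.DataFrame(rows, columns=cols)

    def test_r_only_up_absent_from_common(self):
        base = {m.name: 10.0 for m in DESIGN}
        base["R_24HAT"] = 40.0  # up in R only at one time-point
        rpkm = pd.DataFrame([base], index=["c1"])
        rs = build_response_sets(rpkm, DESIGN)
        assert rs.R_only_up == {"c1"} and "c1" not in rs.common_up

    def test_empty_matrix_gives_empty_sets(self):
        rpkm = pd.DataFrame(columns=[m.name for m in DESIGN])
        rs = build_response_sets(rpkm, DESIGN)
        assert rs.common_up == set() and rs.S_only_down == set()

    def test_missing_ut_rejected(self):
        rpkm = pd.DataFrame(
            [[1.0] * 12],
            columns=[m.name for m in DESIGN if m.time_point != "UT"],
            index=["c"],
        )
        with pytest.raises(ValueError):
            build_response_sets(rpkm, DESIGN)

    def test_flagged_time_point_excluded(self):
        base = {m.name: 10.0 for m in DESIGN}
        base["R_48HAT"] = 100.0
        rpkm = pd.DataFrame([base], index=["c1"])
        rs = build_response_sets(rpkm, DESIGN, qc_flags=("R_48HAT",))
        assert "48HAT" not in rs.retained_time_points
        assert rs.R_only_up == set()

    def test_venn_partition_consistency(self):
        rng = np.random.default_rng(2)
        rpkm = pd.DataFrame(
            rng.lognormal(2, 1.2, size=(300, 14)),
            columns=[m.name for m in DESIGN],
            index=[f"c{i}" for i in range(300)],
        )
        rs = build_response_sets(rpkm, DESIGN)
        union = rs.any_up("R") | rs.any_up("S")
        assert len(rs.common_up) + len(rs.R_only_up) + len(rs.S_only_up) == len(union)
        assert not rs.common_up & rs.R_only_up
        assert not rs.common_up & rs.S_only_up

    def test_all_treated_subset_of_each_time_point(self):
        rng = np.random.default_rng(3)
        rpkm = pd.DataFrame(
            rng.lognormal(2, 1.2, size=(200, 14)),
            columns=[m.name for m in DESIGN],
            index=[f"c{i}" for i in range(200)],
        )
        rs = build_response_sets(rpkm, DESIGN)
        for t in rs.retained_time_points:
            assert rs.all_treated_up["R"] <= rs.up["R"][t]


class TestGrubbs:
    def test_zero_sd_is_no_outlier(self):
        with pytest.warns(UserWarning):
            res = grubbs_outlier([5, 5, 5, 5])
        assert not res.is_outlier

    def test_gross_outlier_flagged(self):
        res = grubbs_outlier([1, 2, 3, 100], alpha=0.05)
        assert res.is_outlier and res.index == 3

    def test_order_invariance(self):
        a = grubbs_outlier([1, 2, 3, 100])
        b = grubbs_outlier([100, 3, 1, 2])
        assert a.is_outlier == b.is_outlier
        assert a.statistic == pytest.approx(b.statistic)

    def test_critical_value_matches_published_table(self):
        # published two-sided critical value for n=10, alpha=0.05
        assert grubbs_critical(10, 0.05) == pytest.approx(2.29, abs=0.01)

    def test_statistic_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 100.0])
        res = grubbs_outlier(x)
        g = np.abs(x - x.mean()).max() / x.std(ddof=1)
        assert res.statistic == pytest.approx(g)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            grubbs_outlier([1, 2])


class TestClassifyProfile:
    def series(self, ut, treated):
        d = {"UT": ut}
        d.update(dict(zip(simdata.TREATED_TIME_POINTS, treated)))
        return d

    @pytest.mark.parametrize(
        "ut,treated,label",
        [
            (1.0, (2.5, 3, 4, 4, 5, 6), "UP_ALL"),
            (10.0, (10, 10, 11, 9, 10, 10), "STABLE"),
            (8.0, (2, 2, 2, 2, 2, 2), "DOWN_ALL"),
            (4.0, (9, 9, 9, 9, 1.5, 1.5), "UP_THEN_DOWN(36HAT)"),
            (8.0, (2, 2, 2, 20, 20, 20), "DOWN_THEN_UP(24HAT)"),
            (5.0, (5, 5, 12, 5, 5, 5), "PEAK(24HAT)"),
        ],
    )
    def test_rule_labels(self, ut, treated, label):
        assert classify_profile(self.series(ut, treated)) == label

    def test_missing_ut_unknown(self):
        assert classify_profile({"6HAT": 2.0}) == "UNKNOWN"


class TestMarkerConcordance:
    def make_rpkm(self):
        cols = [m.name for m in DESIGN]
        data = {
            "up_both": {c: (40.0 if not c.endswith("UT") else 10.0) for c in cols},
            "up_r_only": {
                c: (40.0 if c.startswith("R") and not c.endswith("UT") else 10.0)
                for c in cols
            },
            "flat": {c: 10.0 for c in cols},
        }
        return pd.DataFrame(data).T

    def test_agreement_classes(self):
        rpkm = self.make_rpkm()
        table = pd.DataFrame(
            {
                "marker_id": ["m1", "m2", "m3", "m4"],
                "group": [1, 1, 2, 2],
                "direction": ["up", "up", "up", "up"],
                "contig_id": ["up_both", "up_r_only", "flat", ""],
            }
        )
        conc = marker_concordance(rpkm, table, "73HAT")
        assert list(conc["status"]) == [
            "agree_both",
            "agree_one",
            "disagree",
            "no_homolog",
        ]
        counts = concordance_counts(conc)
        assert counts.loc[1, "agree_both"] == 1
        assert counts.loc[2, "no_homolog"] == 1

    def test_all_markers_without_homologs(self):
        rpkm = self.make_rpkm()
        table = pd.DataFrame(
            {
                "marker_id": ["m1", "m2"],
                "group": [1, 2],
                "direction": ["up", "down"],
                "contig_id": ["", ""],
            }
        )
        conc = marker_concordance(rpkm, table, "73HAT")
        assert (conc["status"] == "no_homolog").all()

    def test_planted_matching_directions_agree_both(self):
        """Markers pointing at strongly regulated contigs with the matching
        reference direction agree in both pools at the late time-point."""
        rpkm = self.make_rpkm()
        table = pd.DataFrame(
            {
                "marker_id": ["m1"],
                "group": [1],
                "direction": ["up"],
                "contig_id": ["up_both"],
            }
        )
        conc = marker_concordance(rpkm, table, "73HAT")
        assert (conc["status"] == "agree_both").all()
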
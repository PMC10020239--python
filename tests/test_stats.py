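"""ANOVA, significance stars, and population summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from toroquant.stats_report import (
    compare_groups,
    one_way_anova,
    render_report_markdown,
    significance_stars,
    summarize_population,
)
from toroquant.imaging_io import results_table


class TestOneWayAnova:
    def test_hand_computed_example(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, df (1, 4)
        F, p = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert F == pytest.approx(1.5)
        assert p == pytest.approx(float(sps.f.sf(1.5, 1, 4)))

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, n) for m, n in ((0, 12), (0.5, 9), (1.2, 15))]
        F, p = one_way_anova(groups)
        F_sp, p_sp = sps.f_oneway(*groups)
        assert F == pytest.approx(F_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-12)

    def test_two_identical_groups_give_zero_F(self):
        F, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert F == 0.0

    def test_identical_data_flagged(self):
        F, p = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert F == 0.0 and p == 1.0

    def test_zero_within_variance_unequal_means(self):
        F, p = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(F) and p == 0.0

    def test_permuting_within_groups_leaves_F_unchanged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        F1, _ = one_way_anova([a, b])
        F2, _ = one_way_anova([rng.permutation(a), rng.permutation(b)])
        assert F1 == pytest.approx(F2)

    def test_F_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.7, 1.3, 11)
        F, p_f = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
    )
    def test_F_invariant_under_common_affine_transform(self, shift, scale):
        a = np.array([0.1, 0.9, 1.7, 0.4])
        b = np.array([1.1, 2.0, 0.6])
        F1, _ = one_way_anova([a, b])
        F2, _ = one_way_anova([a * scale + shift, b * scale + shift])
        assert F1 == pytest.approx(F2, rel=1e-6)

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [5]])


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.2, "ns"),
            (0.06, "ns"),
            (0.03, "*"),
            (0.005, "**"),
            (0.0005, "***"),
            (0.00005, "****"),
            # boundaries go to the more significant bin
            (0.05, "*"),
            (0.01, "**"),
            (0.001, "***"),
            (0.0001, "****"),
        ],
    )
    def test_star_bins(self, p, stars):
        assert significance_stars(p) == stars

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(-0.1)
        with pytest.raises(ValueError):
            significance_stars(1.5)

    def test_compare_groups_reports_stars(self):
        rng = np.random.default_rng(3)
        cmp = compare_groups(
            {"a": rng.normal(0, 1, 30), "b": rng.normal(2, 1, 30)}
        )
        assert cmp.stars == "****"
        assert cmp.n == [30, 30]


class TestSummarizePopulation:
    def test_single_cell_flags_undefined_sd(self):
        table = results_table(
            [{"cell_id": 1, "strain_label": "wt", "compaction_ratio": 1.8}]
        )
        summary = summarize_population(table)
        row = summary[summary["metric"] == "compaction_ratio"].iloc[0]
        assert row["n"] == 1
        assert "undefined" in row["flags"]

    def test_identical_tables_give_identical_reports(self):
        rng = np.random.default_rng(4)
        rows = [
            {
                "cell_id": i,
                "strain_label": "wt",
                "compaction_ratio": float(rng.normal(1.8, 0.1)),
                "asymmetricity_mukb": float(rng.uniform(0, 1)),
            }
            for i in range(10)
        ]
        t = results_table(rows)
        r1 = render_report_markdown(summarize_population(t))
        r2 = render_report_markdown(summarize_population(t.copy()))
        assert r1 == r2

    def test_discarded_cells_are_dropped(self):
        table = results_table(
            [
                {"cell_id": 1, "strain_label": "wt", "compaction_ratio": 1.8,
                 "discarded": False},
                {"cell_id": 2, "strain_label": "wt", "compaction_ratio": 99.0,
                 "discarded": True},
            ]
        )
        summary = summarize_population(table)
        row = summary[summary["metric"] == "compaction_ratio"].iloc[0]
        assert row["n"] == 1 and row["center"] == pytest.approx(1.8)

    def test_figures_written_per_metric(self, tmp_path):
        from toroquant.stats_report import render_report_figures

        rng = np.random.default_rng(6)
        rows = [
            {
                "cell_id": i,
                "strain_label": lab,
                "compaction_ratio": float(rng.normal(mu, 0.05)),
            }
            for lab, mu in (("wt", 1.8), ("eq", 1.2))
            for i in range(8)
        ]
        written = render_report_figures(results_table(rows), tmp_path)
        assert [p.name for p in written] == ["compaction_ratio.png"]
        assert (tmp_path / "compaction_ratio.png").stat().st_size > 0

    def test_medians_used_for_asymmetricity(self):
        table = results_table(
            [
                {"cell_id": i, "strain_label": "wt", "asymmetricity_dna": v}
                for i, v in enumerate([0.1, 0.2, 0.9])
            ]
        )
        summary = summarize_population(table)
        row = summary[summary["metric"] == "asymmetricity_dna"].iloc[0]
        assert row["center"] == pytest.approx(0.2)
        assert row["center_stat"] == "median"
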
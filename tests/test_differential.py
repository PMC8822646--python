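"""Fold-change ranking, DEG counting and the two-sample tests."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

import ipfkinome as ik
from ipfkinome.panel import ValidationError


class TestLog2Ratios:
    def test_closed_form_cases(self, tiny_expr, tiny_sheet):
        v = tiny_expr.values.copy()
        case = tiny_sheet.ipf_samples
        ref = tiny_sheet.control_samples
        v.loc["KA", case] = 8.0
        v.loc["KA", ref] = 2.0
        v.loc["KB"] = 5.0
        table = ik.rank_upregulated(ik.ExpressionMatrix(v), tiny_sheet,
                                    "IPF", "control", epsilon=0.0)
        assert table.loc["KA", "log2_ratio"] == pytest.approx(2.0)
        assert bool(table.loc["KA", "passes_twofold"])
        assert table.loc["KB", "log2_ratio"] == pytest.approx(0.0)
        assert not bool(table.loc["KB", "passes_twofold"])

    def test_matches_brute_force_table(self, rng):
        genes = [f"g{i}" for i in range(50)]
        case = [f"a{i}" for i in range(5)]
        ref = [f"b{i}" for i in range(4)]
        rows = []
        for pid, grp, ids in (("PA", "IPF", case), ("PB", "control", ref)):
            for s in ids:
                rows.append({"sample_id": s, "patient_id": pid, "group": grp,
                             "ashcroft_score": 7 if grp == "IPF" else None,
                             "segment_label": "x"})
        sheet = ik.SampleSheet(pd.DataFrame(rows).set_index("sample_id"))
        expr = ik.ExpressionMatrix(pd.DataFrame(
            rng.lognormal(2, 1, (50, 9)), index=genes, columns=case + ref))
        eps = 0.1
        table = ik.rank_upregulated(expr, sheet, "IPF", "control", epsilon=eps)
        expected = {}
        for g in genes:  # independent per-gene recomputation
            cm = sum(expr.values.loc[g, s] for s in case) / len(case)
            rm = sum(expr.values.loc[g, s] for s in ref) / len(ref)
            expected[g] = np.log2((cm + eps) / (rm + eps))
        for g in genes:
            assert table.loc[g, "log2_ratio"] == pytest.approx(
                expected[g], rel=1e-12)
        top10 = set(sorted(expected, key=expected.get, reverse=True)[:10])
        assert set(ik.rank_upregulated(expr, sheet, "IPF", "control",
                                       epsilon=eps, top=10).index) == top10

    def test_swapping_groups_negates_ratios(self, tiny_expr, tiny_sheet):
        v = tiny_expr.values + 1.0  # keep means away from zero for eps=0
        expr = ik.ExpressionMatrix(v)
        fwd = ik.rank_upregulated(expr, tiny_sheet, "IPF", "control",
                                  epsilon=0.0)["log2_ratio"]
        rev = ik.rank_upregulated(expr, tiny_sheet, "control", "IPF",
                                  epsilon=0.0)["log2_ratio"]
        np.testing.assert_allclose(fwd.sort_index(), -rev.sort_index(),
                                   rtol=1e-12)

    def test_zero_reference_with_eps_zero_is_unranked(self, tiny_expr,
                                                      tiny_sheet):
        v = tiny_expr.values.copy()
        v.loc["KC", tiny_sheet.control_samples] = 0.0
        table = ik.rank_upregulated(ik.ExpressionMatrix(v), tiny_sheet,
                                    "IPF", "control", epsilon=0.0)
        assert np.isnan(table.loc["KC", "log2_ratio"])
        assert table.index[-1] == "KC"  # NaN-ratio genes sort last

    def test_selector_validation(self, tiny_expr, tiny_sheet):
        with pytest.raises(ValidationError, match="overlap"):
            ik.rank_upregulated(tiny_expr, tiny_sheet, "IPF", "IPF")
        with pytest.raises(KeyError):
            ik.rank_upregulated(tiny_expr, tiny_sheet, "nobody", "control")

    def test_per_patient_case_selector(self, tiny_expr, tiny_sheet):
        table = ik.rank_upregulated(tiny_expr, tiny_sheet, "P2", "control")
        direct = ik.log2_ratios(tiny_expr, tiny_sheet.samples_of("P2"),
                                tiny_sheet.control_samples)
        np.testing.assert_allclose(table["log2_ratio"].sort_index(),
                                   direct["log2_ratio"].sort_index(),
                                   rtol=1e-12)


class TestCountDegs:
    def test_planted_threefold_in_severe_stratum_only(self):
        """12 genes induced 3-fold in the severe stratum are counted there
        and nowhere else."""
        config = dataclasses.replace(
            ik.default_study_config(seed=5),
            n_induced=12, n_suppressed=0, log2_effect=float(np.log2(3)),
            patient_sd=0.02, segment_sd=0.02, ipf_dispersion_multiplier=1.0,
            nb_dispersion=1e5, mapped_total_range=(20_000_000, 40_000_000))
        ds = ik.simulate_dataset(config)
        expr = ik.compute_rpkm(ds.counts, ds.panel)
        assert ik.count_degs(expr, ds.sheet, "severe", "both") == 12
        assert ik.count_degs(expr, ds.sheet, "severe", "up") == 12
        assert ik.count_degs(expr, ds.sheet, "moderate", "both") == 0

    def test_stratum_identical_to_controls_counts_zero(self, tiny_expr,
                                                       tiny_sheet):
        v = tiny_expr.values.copy()
        moderate = tiny_sheet.moderate_samples()
        ctl = tiny_sheet.control_samples
        v[moderate] = v[ctl[:len(moderate)]].to_numpy()
        # make the group means literally equal
        for g in v.index:
            v.loc[g, moderate] = v.loc[g, ctl].mean()
        expr = ik.ExpressionMatrix(v)
        assert ik.count_degs(expr, tiny_sheet, "moderate", "both") == 0

    def test_up_plus_down_equals_both(self, small_dataset):
        expr = ik.compute_rpkm(small_dataset.counts, small_dataset.panel)
        sheet = small_dataset.sheet
        for stratum in ("severe", "moderate"):
            up = ik.count_degs(expr, sheet, stratum, "up")
            down = ik.count_degs(expr, sheet, stratum, "down")
            both = ik.count_degs(expr, sheet, stratum, "both")
            assert up + down == both

    def test_matches_ranking_rows_beyond_twofold(self, small_dataset):
        """Cross-module consistency with the ranking table."""
        expr = ik.compute_rpkm(small_dataset.counts, small_dataset.panel)
        sheet = small_dataset.sheet
        table = ik.rank_upregulated(expr, sheet, sheet.severe_samples(),
                                    "control")
        expected = int((table["log2_ratio"].abs() > 1).sum())
        assert ik.count_degs(expr, sheet, "severe", "both") == expected


class TestTwoSampleTest:
    def test_equal_groups_give_t0_p1(self):
        expr = ik.ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"],
            columns=list("abcdef")))
        res = ik.two_sample_test(expr, ["a", "b", "c"], ["d", "e", "f"],
                                 mode="student")
        assert res.loc["g", "statistic"] == pytest.approx(0.0)
        assert res.loc["g", "p_value"] == pytest.approx(1.0)

    def test_student_matches_textbook_formula(self):
        a = np.array([4.1, 5.3, 6.0])
        b = np.array([2.0, 2.9, 3.5])
        expr = ik.ExpressionMatrix(pd.DataFrame(
            [np.concatenate([a, b])], index=["g"], columns=list("uvwxyz")))
        res = ik.two_sample_test(expr, list("uvw"), list("xyz"),
                                 mode="student")
        # pooled-variance t computed from first principles
        sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.loc["g", "statistic"] == pytest.approx(t, abs=1e-10)

    def test_paired_without_map_and_unequal_sizes_rejected(self, tiny_expr,
                                                           tiny_sheet):
        with pytest.raises(ValidationError, match="pairing"):
            ik.two_sample_test(tiny_expr, tiny_sheet.ipf_samples,
                               tiny_sheet.control_samples, mode="paired")

    def test_paired_matches_one_sample_t_on_differences(self, rng):
        cols = [f"s{i}" for i in range(8)]
        expr = ik.ExpressionMatrix(pd.DataFrame(
            rng.lognormal(1, 0.5, (5, 8)),
            index=[f"g{i}" for i in range(5)], columns=cols))
        pairing = list(zip(cols[:4], cols[4:]))
        res = ik.two_sample_test(expr, cols[:4], cols[4:], mode="paired",
                                 pairing=pairing)
        for g in expr.genes:  # closed form on the paired differences
            d = (expr.values.loc[g, cols[:4]].to_numpy()
                 - expr.values.loc[g, cols[4:]].to_numpy())
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert res.loc[g, "statistic"] == pytest.approx(t, abs=1e-10)

    def test_bh_adjustment_matches_statsmodels(self, rng, tiny_expr,
                                               tiny_sheet):
        from statsmodels.stats.multitest import multipletests
        table = ik.rank_upregulated(tiny_expr, tiny_sheet, "IPF", "control",
                                    adjust=True)
        _, expected, _, _ = multipletests(table["p_value"], method="fdr_bh")
        np.testing.assert_allclose(table["p_adjusted"], expected, rtol=1e-9)
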
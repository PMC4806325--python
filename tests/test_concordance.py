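"""Lin's CCC, Dixon's Q, cut-off summaries, bootstrap comparison, heat map."""

import numpy as np
import pandas as pd
import pytest

from radiomics_repro.concordance import (CCCRecord, ConcordanceError,
                                         all_pairs, ccc_matrix, compare_ccc,
                                         cross_kernel_pairs, dixon_q,
                                         export_heatmap, heatmap_frame,
                                         identical_setting_pairs, lin_ccc,
                                         records_to_frame, summarize_cutoffs)
from radiomics_repro.features.registry import load_registry


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert lin_ccc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_shifted_line_hand_value(self):
        # sx2 = sy2 = 2/3, sxy = 2/3, gap^2 = 1 -> 2*(2/3)/(4/3+1) = 4/7
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_anticoncordant_reversal(self):
        assert lin_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_identical_constants_give_one(self):
        assert lin_ccc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan]
        y = [2.0, 3.0, 4.0, 9.0]
        assert lin_ccc(x, y) == pytest.approx(4.0 / 7.0, abs=1e-12)
        with pytest.raises(ConcordanceError, match=">= 3"):
            lin_ccc([1.0, np.nan, 3.0], [2.0, 3.0, 4.0])

    def test_bounded_by_pearson(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 15)
            y = 0.5 * x + rng.normal(0, 0.5, 15) + rng.uniform(-1, 1)
            pearson = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(pearson) + 1e-12

    def test_mean_shift_decreases_ccc(self):
        x = np.array([1.0, 2.0, 4.0, 6.0, 9.0])
        cccs = [lin_ccc(x, x + c) for c in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(cccs, cccs[1:]))


class TestDixonQ:
    def test_hand_example_significant(self):
        res = dixon_q([0.1, 0.15, 0.2, 0.9], alpha=0.05)
        assert res.q == pytest.approx(0.875, abs=1e-12)  # 0.7 / 0.8
        assert res.suspect_index == 3
        assert res.significant  # Q05(4) = 0.829

    def test_all_equal_no_outlier(self):
        res = dixon_q([2.0, 2.0, 2.0, 2.0])
        assert res.q is None and res.significant is False

    def test_symmetric_three_not_significant(self):
        res = dixon_q([1.0, 2.0, 3.0], alpha=0.05)
        assert res.q == pytest.approx(0.5, abs=1e-12)
        assert not res.significant  # Q05(3) = 0.970

    def test_low_suspect(self):
        res = dixon_q([-5.0, 1.0, 1.1, 1.2])
        assert res.suspect_index == 0
        assert res.significant

    def test_na_beyond_table(self, rng):
        res = dixon_q(rng.normal(size=31))
        assert res.significant is None

    def test_too_small_errors(self):
        with pytest.raises(ConcordanceError):
            dixon_q([1.0, 2.0])


class TestPairEnumeration:
    def test_six_identical_setting_pairs(self):
        pairs = identical_setting_pairs()
        assert len(pairs) == 6
        assert pairs[0] == "1.25L vs 1.25L"

    def test_three_cross_kernel_pairs(self):
        pairs = cross_kernel_pairs()
        assert pairs == ["1.25L vs 1.25S", "2.5L vs 2.5S", "5L vs 5S"]


def _feature_table(rng, n_subjects=8, duplicate_scan=False):
    """Tidy synthetic feature table covering all 89 features and 6 settings."""
    registry = load_registry()
    settings = ["1.25L", "1.25S", "2.5L", "2.5S", "5L", "5S"]
    rows = []
    for si, subject in enumerate(f"S{i:02d}" for i in range(n_subjects)):
        base = rng.normal(0, 1, size=len(registry.names))
        for scan in (1, 2):
            for setting in settings:
                noise = np.zeros(len(base)) if (duplicate_scan and scan == 2) \
                    else rng.normal(0, 0.05, size=len(base))
                vals = base + (0 if (duplicate_scan and scan == 2) else noise)
                for j, name in enumerate(registry.names):
                    rows.append({"subject": subject, "scan": scan,
                                 "setting": setting, "feature": name,
                                 "value": vals[j] if not duplicate_scan else base[j]})
    return pd.DataFrame(rows)


class TestCCCMatrix:
    def test_duplicate_scans_give_unit_ccc(self, rng):
        table = _feature_table(rng, n_subjects=5, duplicate_scan=True)
        records = ccc_matrix(table, pairs=identical_setting_pairs())
        assert len(records) == 89 * 6
        for r in records:
            assert r.ccc == pytest.approx(1.0, abs=1e-12)

    def test_unknown_pair_label_rejected(self, rng):
        table = _feature_table(rng, n_subjects=4)
        with pytest.raises(ConcordanceError, match="unknown pair"):
            ccc_matrix(table, pairs=["1.25L vs 5S"])

    def test_dixon_screen_reports_both(self, rng):
        table = _feature_table(rng, n_subjects=10)
        # inject an outlying subject into one feature at one setting pair
        sel = ((table.subject == "S00") & (table.scan == 2)
               & (table.setting == "1.25L") & (table.feature == "Volume"))
        table.loc[sel, "value"] += 50.0
        records = ccc_matrix(table, pairs=["1.25L vs 1.25L"],
                             outlier_policy="dixon-screen")
        rec = next(r for r in records if r.feature == "Volume")
        assert rec.outliers == ("S00",)
        assert rec.n_screened == 9
        assert rec.ccc_screened > rec.ccc


class TestSummarize:
    def _records(self, cccs_by_pair):
        registry = load_registry()
        records = []
        for pair, cccs in cccs_by_pair.items():
            for name, c in zip(registry.names, cccs):
                records.append(CCCRecord(feature=name,
                                         feature_class=registry.class_of(name),
                                         pair=pair, n=10, ccc=c))
        return records

    def test_all_perfect(self):
        recs = self._records({"1.25L vs 1.25L": [1.0] * 89})
        table = summarize_cutoffs(recs)
        row = table.iloc[0]
        assert (row["count_0.85"], row["pct_0.85"]) == (89, 100)
        assert (row["count_0.95"], row["pct_0.95"]) == (89, 100)

    def test_split_counts_and_percentage(self):
        cccs = [0.86] * 49 + [0.84] * 40
        recs = self._records({"5L vs 5L": cccs})
        row = summarize_cutoffs(recs).iloc[0]
        assert row["count_0.85"] == 49
        assert row["pct_0.85"] == 55  # round(100 * 49 / 89)

    def test_counts_non_increasing_in_cutoff(self, rng):
        cccs = rng.uniform(0.5, 1.0, size=89)
        recs = self._records({"2.5S vs 2.5S": list(cccs)})
        row = summarize_cutoffs(recs).iloc[0]
        assert row["count_0.85"] >= row["count_0.9"] >= row["count_0.95"]

    def test_na_counts_as_non_reproducible(self):
        cccs = [1.0] * 88 + [float("nan")]
        recs = self._records({"5S vs 5S": cccs})
        row = summarize_cutoffs(recs).iloc[0]
        assert row["count_0.85"] == 88

    def test_missing_feature_errors(self):
        recs = self._records({"5S vs 5S": [1.0] * 89})[:-1]
        with pytest.raises(ConcordanceError, match="missing features"):
            summarize_cutoffs(recs)


class TestCompareCCC:
    def test_identical_inputs_p_near_one(self, rng):
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 0.2, 20)
        p = compare_ccc(x, y, x, y, n_boot=500, seed=3)
        assert p > 0.5

    def test_detects_noisier_2d_analog(self, rng):
        """A clearly noisier variant of the same feature: p < 0.05 at n=30."""
        t = rng.normal(0, 1, 30)
        x3, y3 = t + rng.normal(0, 0.1, 30), t + rng.normal(0, 0.1, 30)
        x2, y2 = t + rng.normal(0, 0.8, 30), t + rng.normal(0, 0.8, 30)
        p = compare_ccc(x3, y3, x2, y2, n_boot=2000, seed=4)
        assert p < 0.05

    def test_seeded_determinism(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0, 0.3, 12)
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0, 0.6, 12)
        p1 = compare_ccc(x, y, a, b, n_boot=400, seed=9)
        p2 = compare_ccc(x, y, a, b, n_boot=400, seed=9)
        assert p1 == p2

    def test_too_few_subjects(self):
        with pytest.raises(ConcordanceError):
            compare_ccc([1, 2, 3], [1, 2, 3], [1, 2, 3], [3, 2, 1])


class TestHeatmap:
    def test_full_matrix_shape_and_order(self, rng, tmp_path):
        table = _feature_table(rng, n_subjects=5)
        records = ccc_matrix(table)
        matrix = export_heatmap(records, tmp_path / "heatmap.csv",
                                figure_path=tmp_path / "heatmap.png")
        assert matrix.shape == (89, 9)
        assert list(matrix.columns) == all_pairs()
        assert list(matrix.index) == load_registry().names
        assert (tmp_path / "heatmap.png").exists()

    def test_not_available_serializes_empty(self, tmp_path):
        registry = load_registry()
        records = []
        for name in registry.names:
            records.append(CCCRecord(feature=name,
                                     feature_class=registry.class_of(name),
                                     pair="5L vs 5L", n=10,
                                     ccc=float("nan") if name == "Uni" else 0.5))
        export_heatmap(records, tmp_path / "h.csv")
        text = (tmp_path / "h.csv").read_text().splitlines()
        uni_row = next(l for l in text if l.startswith("Uni,"))
        assert uni_row == "Uni,"  # empty cell, not 0
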
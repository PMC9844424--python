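"""Agreement statistics against independent oracles, fold splitting,
area summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dixonfat import stats
from dixonfat.core import FourClassLabelMap, RegionPair


class TestDice:
    def test_identical_nonempty(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert stats.dice(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert stats.dice(a, b) == 0.0

    def test_both_empty_convention(self):
        assert stats.dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_hand_counted_example(self):
        a = np.zeros((3, 3), bool)
        b = np.zeros((3, 3), bool)
        a[0, :3] = True  # |A| = 3
        b[0, 1:] = True
        b[1, 0] = True  # |B| = 3, overlap = 2
        assert stats.dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_brute_force_oracle(self, rng):
        for _ in range(200):
            a = rng.random((6, 6)) > 0.5
            b = rng.random((6, 6)) > 0.5
            inter = sum(
                1 for i in range(6) for j in range(6) if a[i, j] and b[i, j])
            expect = 1.0 if a.sum() + b.sum() == 0 else 2 * inter / (a.sum() + b.sum())
            assert stats.dice(a, b) == pytest.approx(expect, abs=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert stats.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert stats.pearson(x, -x) == pytest.approx(-1.0)

    def test_against_scipy(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert stats.pearson(x, y) == pytest.approx(
                sps.pearsonr(x, y).statistic, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.pearson(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = stats.bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_hand_computed(self):
        ba = stats.bland_altman(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert ba.bias == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(2.0 - 1.96)
        assert ba.loa_high == pytest.approx(2.0 + 1.96)

    def test_translation_shifts_bias_only(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        ba = stats.bland_altman(x, y)
        ba_shift = stats.bland_altman(x + 5.0, y)
        assert ba_shift.bias == pytest.approx(ba.bias + 5.0)
        assert ba_shift.loa_high - ba_shift.loa_low == pytest.approx(
            ba.loa_high - ba.loa_low)

    def test_limits_symmetric_about_bias(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        ba = stats.bland_altman(x, y)
        assert ba.loa_high - ba.bias == pytest.approx(ba.bias - ba.loa_low)


class TestPairedTTest:
    def test_identical_degenerate_convention(self):
        t, p = stats.paired_ttest(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert (t, p) == (0.0, 1.0)

    def test_symmetric_diffs_give_zero_t(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        t, _ = stats.paired_ttest(x, np.zeros(4))
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = stats.paired_ttest(x, np.zeros(3))
        assert t == pytest.approx(2 / (1 / np.sqrt(3)))
        assert p == pytest.approx(2 * sps.t.sf(t, df=2), abs=1e-12)

    def test_against_scipy(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 25))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            t, p = stats.paired_ttest(x, y)
            ref = sps.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFolds:
    def _manifest(self, n_subjects, rng):
        rows = []
        for i in range(n_subjects):
            for v in range(int(rng.integers(1, 4))):
                rows.append({"subject_id": f"S{i:03d}", "visit": v, "level": "L23"})
        return pd.DataFrame(rows)

    def test_partition_contract(self, rng):
        m = self._manifest(10, rng)
        split = stats.make_folds(m, k=5, seed=1)
        sizes = [len(split.subjects_in_fold(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]
        assert set().union(*(split.subjects_in_fold(f) for f in range(5))) == set(
            m.subject_id.unique())

    def test_deterministic(self, rng):
        m = self._manifest(13, rng)
        a = stats.make_folds(m, k=5, seed=3)
        b = stats.make_folds(m, k=5, seed=3)
        assert a.assignment == b.assignment

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000), n=st.integers(5, 60))
    def test_subject_disjoint_property(self, seed, n):
        rng = np.random.default_rng(seed)
        m = self._manifest(n, rng)
        split = stats.make_folds(m, k=5, seed=seed)
        split.validate()
        seen = {}
        for f in range(5):
            for s in split.subjects_in_fold(f):
                assert s not in seen
                seen[s] = f
        assert len(seen) == n

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            stats.make_folds(self._manifest(3, rng), k=5, seed=0)


class TestCrossval:
    def test_aggregate_is_mean_of_fold_means(self, rng):
        rows = []
        for i in range(10):
            for v in range(2):
                rows.append({"subject_id": f"S{i:03d}", "visit": v, "level":
                             ("L23", "L45")[v % 2]})
        manifest = pd.DataFrame(rows)

        def train_fn(train_m, seed):
            return None

        def eval_fn(model, test_m):
            r = np.random.default_rng(len(test_m))
            out = test_m[["subject_id", "visit", "level"]].copy()
            out["dsc_sat"] = r.uniform(0.8, 1.0, len(test_m))
            out["dsc_vat"] = r.uniform(0.6, 1.0, len(test_m))
            return out

        report = stats.crossval(manifest, train_fn, eval_fn, k=5, seed=0)
        for cl in ("sat", "vat"):
            assert report.dsc_mean[cl] == pytest.approx(
                np.mean(report.per_fold_dsc[cl]), abs=1e-12)
        n_by_level = sum(v["n_images"] for v in report.per_level.values())
        assert n_by_level == len(report.per_image)


class TestAreaSummary:
    def _labelmap(self):
        outer = np.zeros((40, 40), bool)
        outer[5:35, 5:35] = True
        inner = np.zeros((40, 40), bool)
        inner[10:30, 10:30] = True
        labels = np.zeros((40, 40), np.int64)
        labels[6:8, 6:31] = 1  # SAT strip in the ring, 2x25 = 50 px
        labels[12:17, 12:22] = 2  # VAT block, 5x10 = 50 px
        return FourClassLabelMap(labels, RegionPair(outer, inner),
                                 pixel_spacing_mm=(1.1, 1.1))

    def test_unit_arithmetic(self):
        lm = self._labelmap()
        # 100 SAT pixels at 1.1 x 1.1 mm -> 1.21 cm^2
        out = stats.area_summary(lm)
        assert out["sat_pixels"] == 50
        assert out["sat_cm2"] == pytest.approx(50 * 1.21 / 100)

    def test_empty_vat_ratio_zero(self):
        lm = self._labelmap()
        lm.labels[lm.labels == 2] = 0
        out = stats.area_summary(lm)
        assert out["vat_over_inner"] == 0.0

    def test_ratios_spacing_invariant(self):
        lm = self._labelmap()
        a = stats.area_summary(lm, spacing_mm=(1.0, 1.0))
        b = stats.area_summary(lm, spacing_mm=(2.5, 2.5))
        for key in ("sat_over_outer", "vat_over_inner", "fat_over_outer"):
            assert a[key] == pytest.approx(b[key])

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            stats.area_summary(self._labelmap(), spacing_mm=(0.0, 1.0))


def test_agreement_plots_written(tmp_path, rng):
    n = 20
    per_image = pd.DataFrame({
        "dsc_sat": rng.uniform(0.8, 1.0, n),
        "sat_cm2_ref": rng.uniform(50, 150, n),
    })
    per_image["sat_cm2_pred"] = per_image["sat_cm2_ref"] + rng.normal(0, 3, n)
    report = stats.agreement_report(per_image)
    stats.plot_agreement(report, tmp_path)
    assert (tmp_path / "agreement_sat.png").exists()
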
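"""Overlap metrics, 95% Hausdorff distance, and nested-region construction."""

import warnings

import numpy as np
import pytest

from cagsnet.metrics import (
    REGIONS, average_reports, confusion_counts, evaluate_case, hausdorff95,
    overlap_metrics, region_masks, write_reports,
)


class TestRegionMasks:
    def test_all_background_gives_empty_masks(self):
        rm = region_masks(np.zeros((4, 4, 4), np.int16))
        assert not rm.wt.any() and not rm.tc.any() and not rm.et.any()

    def test_single_enhancing_voxel_is_in_all_regions(self):
        labels = np.zeros((3, 3, 3), np.int16)
        labels[1, 1, 1] = 4
        rm = region_masks(labels)
        assert rm.et[1, 1, 1] and rm.tc[1, 1, 1] and rm.wt[1, 1, 1]

    def test_set_arithmetic_of_counts(self, rng):
        labels = np.zeros(40, np.int16)
        labels[:5] = 1
        labels[5:12] = 2
        labels[12:15] = 4
        rm = region_masks(rng.permutation(labels).reshape(4, 10))
        assert rm.et.sum() == 3 and rm.tc.sum() == 8 and rm.wt.sum() == 15

    def test_nesting_holds_for_random_labels(self, rng):
        labels = rng.choice([0, 1, 2, 4], size=(6, 6, 6))
        rm = region_masks(labels)
        assert np.all(rm.et <= rm.tc) and np.all(rm.tc <= rm.wt)

    def test_unknown_labels_listed_in_error(self):
        labels = np.array([0, 3, 5])
        with pytest.raises(ValueError, match=r"\[3, 5\]"):
            region_masks(labels)


class TestConfusionAndOverlap:
    def test_exact_match_has_no_errors(self, rng):
        m = rng.random((4, 4)) < 0.5
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0 and c.tp == m.sum()

    def test_complement_has_no_agreement(self):
        m = np.array([[True, False], [False, True]])
        c = confusion_counts(~m, m)
        assert c.tp == 0 and c.tn == 0

    def test_two_by_two_enumeration(self):
        c = confusion_counts(np.array([1, 1, 0, 0], bool),
                             np.array([1, 0, 1, 0], bool))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        dsc, sens, ppv = overlap_metrics(c)
        assert dsc == pytest.approx(0.5)
        assert sens == pytest.approx(0.5) and ppv == pytest.approx(0.5)

    def test_direct_formula(self):
        from cagsnet.metrics import ConfusionCounts
        dsc, sens, ppv = overlap_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=0))
        assert dsc == pytest.approx(4 / 6)
        assert sens == pytest.approx(2 / 3) and ppv == pytest.approx(2 / 3)

    def test_degenerate_conventions(self):
        from cagsnet.metrics import ConfusionCounts
        assert overlap_metrics(ConfusionCounts(0, 0, 0, 8)) == (1.0, 1.0, 1.0)
        assert overlap_metrics(ConfusionCounts(0, 3, 2, 3)) == (0.0, 0.0, 0.0)

    def test_dsc_symmetry_and_sensitivity_ppv_duality(self, rng):
        a = rng.random((5, 5, 5)) < 0.4
        b = rng.random((5, 5, 5)) < 0.4
        dsc_ab, sens_ab, _ = overlap_metrics(confusion_counts(a, b))
        dsc_ba, _, ppv_ba = overlap_metrics(confusion_counts(b, a))
        assert dsc_ab == pytest.approx(dsc_ba)
        assert sens_ab == pytest.approx(ppv_ba)

    def test_dsc_is_harmonic_mean_of_sens_and_ppv(self, rng):
        a = rng.random((5, 5, 5)) < 0.5
        b = rng.random((5, 5, 5)) < 0.5
        dsc, sens, ppv = overlap_metrics(confusion_counts(a, b))
        assert dsc == pytest.approx(2 * sens * ppv / (sens + ppv))


def brute_force_hd(truth, pred, spacing, percentile):
    """All-pairs oracle over 6-connected boundary voxels."""
    def boundary(mask):
        pts = []
        for idx in np.argwhere(mask):
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    if (nb < 0).any() or (nb >= np.array(mask.shape)).any() \
                            or not mask[tuple(nb)]:
                        pts.append(idx)
                        break
                else:
                    continue
                break
        return np.array(pts, float)

    bt, bp = boundary(truth), boundary(pred)
    sp = np.asarray(spacing)
    dmat = np.linalg.norm((bt[:, None, :] - bp[None, :, :]) * sp, axis=-1)
    return max(np.percentile(dmat.min(axis=1), percentile),
               np.percentile(dmat.min(axis=0), percentile))


class TestHausdorff95:
    def test_identical_masks_give_zero(self, rng):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        assert hausdorff95(m, m) == 0.0

    def test_two_single_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert hausdorff95(a, b) == pytest.approx(3.0)

    def test_anisotropic_spacing_scales_distance(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[4, 4, 4] = True
        assert hausdorff95(a, b, spacing=(2.5, 1, 1)) == pytest.approx(5.0)

    def test_unit_translation_bounded_by_one(self):
        m = np.zeros((12, 12, 12), bool)
        m[3:9, 3:9, 3:9] = True
        shifted = np.roll(m, 1, axis=0)
        assert hausdorff95(m, shifted) <= 1.0 + 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle_on_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 9, 9)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        ca, cb = rng.integers(3, 6, 3), rng.integers(3, 6, 3)
        for m_, c in ((a, ca), (b, cb)):
            g = np.ogrid[:9, :9, :9]
            r = rng.uniform(1.5, 3.0)
            m_[:] = sum((gi - ci) ** 2 for gi, ci in zip(g, c)) <= r ** 2
        spacing = (1.0, 1.2, 0.8)
        got = hausdorff95(a, b, spacing=spacing)
        want = brute_force_hd(a, b, spacing, 95.0)
        assert got == pytest.approx(want, abs=1e-6)

    def test_percentile_100_upper_bounds_95(self, rng):
        a = rng.random((7, 7, 7)) < 0.3
        b = rng.random((7, 7, 7)) < 0.3
        if a.any() and b.any():
            assert hausdorff95(a, b, percentile=100.0) >= \
                hausdorff95(a, b, percentile=95.0)

    def test_empty_mask_conventions(self):
        empty = np.zeros((6, 6, 6), bool)
        full = ~empty.copy()
        full[:] = False
        full[3, 3, 3] = True
        assert hausdorff95(empty, empty) == 0.0
        with pytest.warns(UserWarning, match="empty"):
            sentinel = hausdorff95(full, empty)
        assert sentinel == pytest.approx(np.linalg.norm([6, 6, 6]))
        with pytest.warns(UserWarning):
            assert hausdorff95(full, empty, empty_sentinel=42.0) == 42.0


class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        labels = rng.choice([0, 1, 2, 4], size=(8, 8, 8),
                            p=[0.7, 0.1, 0.1, 0.1]).astype(np.int16)
        report = evaluate_case(labels, labels)
        assert set(report.scores) == set(REGIONS)
        for region in REGIONS:
            s = report.scores[region]
            assert set(s) == {"dsc", "sensitivity", "ppv", "hd95"}
            assert s["dsc"] == 1.0 and s["hd95"] == 0.0

    def test_planted_error_rate_reproduces_hand_dsc(self):
        truth = np.zeros((10, 10, 10), np.int16)
        truth[2:8, 2:8, 2:8] = 2          # 216 edema voxels
        pred = truth.copy()
        flat = np.argwhere(pred == 2)
        for idx in flat[:16]:             # remove 16 -> TP=200, FN=16, FP=0
            pred[tuple(idx)] = 0
        report = evaluate_case(pred, truth)
        assert report.scores["WT"]["dsc"] == pytest.approx(
            2 * 200 / (2 * 200 + 16 + 0))

    def test_report_io_roundtrip(self, tmp_path, rng):
        labels = rng.choice([0, 2, 4], size=(6, 6, 6)).astype(np.int16)
        reports = [evaluate_case(labels, labels, case_id="c0")]
        reports.append(average_reports(reports))
        write_reports(reports, csv_path=tmp_path / "m.csv",
                      json_path=tmp_path / "m.json")
        lines = (tmp_path / "m.csv").read_text().strip().splitlines()
        assert len(lines) == 1 + 2 * len(REGIONS)  # header + 2 reports x 3 regions
        assert (tmp_path / "m.json").exists()
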
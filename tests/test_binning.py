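"""Binning chain: mzML I/O, infusion window, bin maths, filters, transforms."""

import numpy as np
import pandas as pd
import pytest

from leafprint import (FeatureMatrix, Scan, ScanSet, StageError,
                       log2_transform, normalise_tic, occupancy_filter,
                       qc_rsd_filter, read_mzml, select_infusion_scans,
                       write_mzml)
from leafprint.binning import bin_scans


def make_matrix(values, stage="raw", sample_ids=None, modes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    cols = [f"n{100 + i}.00" for i in range(p)]
    data = pd.DataFrame(values, columns=cols,
                        index=sample_ids or [f"S{i}" for i in range(n)])
    info = pd.DataFrame({"mode": modes or ["negative"] * p,
                         "mz": [100.005 + i for i in range(p)]}, index=cols)
    return FeatureMatrix(data, info, stage=stage)


def make_samples(roles, groups=None):
    n = len(roles)
    return pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                         "role": roles,
                         "group": groups or ["A"] * n})


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

class TestMzml:
    def test_round_trip(self, tmp_path):
        scans = [Scan("positive", 0, [100.0, 200.0], [5.0, 7.0]),
                 Scan("negative", 0, [150.0], [3.0]),
                 Scan("positive", 1, [100.0], [4.0])]
        ss = ScanSet("demo", scans)
        write_mzml(ss, tmp_path / "demo.mzML")
        back = read_mzml(tmp_path / "demo.mzML")
        assert back.sample_id == "demo"
        assert len(back.scans) == 3
        key = lambda s: (s.index, s.mode)
        for a, b in zip(sorted(scans, key=key), sorted(back.scans, key=key)):
            assert a.mode == b.mode and a.index == b.index
            np.testing.assert_allclose(a.mz, b.mz)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "prof.mzML"
        write_mzml(ScanSet("prof", [Scan("positive", 0, [100.0], [1.0])]), path)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"')
        path.write_text(text)
        with pytest.raises(ValueError, match="centroid"):
            read_mzml(path)

    def test_missing_polarity_rejected(self, tmp_path):
        path = tmp_path / "nopol.mzML"
        write_mzml(ScanSet("nopol", [Scan("positive", 0, [100.0], [1.0])]), path)
        text = path.read_text().replace(
            '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>', "")
        path.write_text(text)
        with pytest.raises(ValueError, match="polarity"):
            read_mzml(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.mzML"
        write_mzml(ScanSet("empty", []), path)
        ss = read_mzml(path)
        assert ss.scans == []


# ---------------------------------------------------------------------------
# infusion window
# ---------------------------------------------------------------------------

class TestInfusionWindow:
    def test_triangular_profile(self):
        # TICs 1..5..1 over scans 1..9; threshold 0.5*5 keeps scans 3..7
        scans = [Scan("positive", i, [100.0], [float(min(i, 10 - i))])
                 for i in range(1, 10)]
        assert select_infusion_scans(ScanSet("s", scans), 0.5) == (3, 7)

    def test_single_scan(self):
        ss = ScanSet("s", [Scan("positive", 1, [100.0], [2.0])])
        assert select_infusion_scans(ss) == (1, 1)

    def test_flat_profile_keeps_all(self):
        scans = [Scan("negative", i, [100.0], [3.0]) for i in range(4)]
        assert select_infusion_scans(ScanSet("s", scans)) == (0, 3)

    def test_all_zero_tic_errors(self):
        scans = [Scan("positive", 0, [100.0], [0.0])]
        with pytest.raises(ValueError, match="zero TIC"):
            select_infusion_scans(ScanSet("s", scans))


# ---------------------------------------------------------------------------
# binning maths
# ---------------------------------------------------------------------------

class TestBinScans:
    def test_same_bin_aggregation(self):
        ss = ScanSet("s", [Scan("positive", 0, [100.004, 100.006], [10.0, 5.0])])
        fm = bin_scans(ss, bin_width=0.01)
        assert fm.bin_ids == ["p100.00"]
        assert fm.data.iloc[0, 0] == 15.0

    def test_half_open_boundary(self):
        ss = ScanSet("s", [Scan("positive", 0, [100.010], [1.0])])
        fm = bin_scans(ss, bin_width=0.01)
        assert fm.bin_ids == ["p100.01"]

    def test_mean_across_window_scans(self):
        scans = [Scan("negative", 0, [200.003], [10.0]),
                 Scan("negative", 1, [200.004], [20.0])]
        fm = bin_scans(ScanSet("s", scans), window=(0, 1), bin_width=0.01)
        assert fm.data.iloc[0, 0] == 15.0

    def test_out_of_range_excluded(self):
        scans = [Scan("positive", 0, [54.0, 100.0, 1250.0], [1.0, 2.0, 3.0])]
        fm = bin_scans(ScanSet("s", scans), mz_range=(55.0, 1200.0))
        assert fm.data.iloc[0].sum() == 2.0

    def test_accurate_mz_is_intensity_weighted(self):
        ss = ScanSet("s", [Scan("positive", 0, [100.002, 100.008], [1.0, 3.0])])
        fm = bin_scans(ss, bin_width=0.01)
        expected = (100.002 * 1 + 100.008 * 3) / 4
        assert abs(fm.bin_info["mz"].iloc[0] - expected) < 1e-12

    def test_conservation_within_scan(self):
        """Total binned intensity equals total in-range centroid intensity."""
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(60, 1100, 50))
        it = rng.uniform(0, 10, 50)
        fm = bin_scans(ScanSet("s", [Scan("negative", 0, mz, it)]))
        assert np.isclose(fm.data.iloc[0].sum(), it.sum())


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestOccupancyFilter:
    def test_best_class_rule(self):
        # bin0: 3/4 in A, 0/4 in B -> kept; bin1: 2/4 both -> dropped; bin2 all-zero
        vals = np.zeros((8, 3))
        vals[:3, 0] = 1.0
        vals[[0, 1, 4, 5], 1] = 1.0
        fm = make_matrix(vals)
        samples = make_samples(["sample"] * 8, ["A"] * 4 + ["B"] * 4)
        out = occupancy_filter(fm, samples, min_occupancy=2 / 3)
        assert out.bin_ids == [fm.bin_ids[0]]
        assert out.stage == "occupancy_filtered"

    def test_idempotent(self):
        vals = np.ones((4, 2))
        vals[2:, 1] = 0.0
        fm = make_matrix(vals)
        samples = make_samples(["sample"] * 4, ["A", "A", "B", "B"])
        once = occupancy_filter(fm, samples)
        twice = occupancy_filter(once, samples)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_empty_class_errors(self):
        fm = make_matrix(np.ones((2, 2)))
        samples = make_samples(["sample", "sample"], ["A", "A"])
        samples.loc[len(samples)] = {"sample_id": "ghost", "role": "sample",
                                     "group": "B"}
        with pytest.raises(ValueError, match="zero samples"):
            occupancy_filter(fm, samples)

    def test_row_permutation_invariant(self, rng):
        vals = rng.uniform(0, 1, (6, 5)) * (rng.random((6, 5)) > 0.4)
        fm = make_matrix(vals)
        samples = make_samples(["sample"] * 6, ["A"] * 3 + ["B"] * 3)
        out1 = occupancy_filter(fm, samples)
        perm = rng.permutation(6)
        fm2 = FeatureMatrix(fm.data.iloc[perm], fm.bin_info, "raw")
        out2 = occupancy_filter(fm2, samples)
        assert out1.bin_ids == out2.bin_ids


class TestQcRsdFilter:
    @pytest.mark.parametrize("qc_vals,kept", [
        ((10.0, 10.0, 10.0), True),    # RSD 0
        ((0.0, 0.0, 0.0), False),      # zero mean
        ((5.0, 10.0, 15.0), True),     # RSD exactly 0.5, inclusive threshold
        ((1.0, 10.0, 19.0), False),    # RSD 0.9
    ])
    def test_rsd_rule(self, qc_vals, kept):
        vals = np.vstack([np.full((2, 1), 3.0), np.array(qc_vals)[:, None]])
        fm = make_matrix(vals, stage="occupancy_filtered")
        samples = make_samples(["sample", "sample", "QC", "QC", "QC"])
        out = qc_rsd_filter(fm, samples, max_rsd=0.5)
        assert (len(out.bin_ids) == 1) == kept

    def test_too_few_qc_errors(self):
        fm = make_matrix(np.ones((3, 2)), stage="occupancy_filtered")
        samples = make_samples(["sample", "sample", "QC"])
        with pytest.raises(ValueError, match="2 QC"):
            qc_rsd_filter(fm, samples)

    def test_stage_enforced(self):
        fm = make_matrix(np.ones((3, 2)), stage="raw")
        samples = make_samples(["QC", "QC", "QC"])
        with pytest.raises(StageError):
            qc_rsd_filter(fm, samples)


class TestNormaliseLog2:
    def test_median_target_scaling(self):
        vals = np.array([[50.0, 50.0], [150.0, 150.0], [100.0, 100.0]])
        fm = make_matrix(vals, stage="qc_filtered")
        out = normalise_tic(fm)
        sums = out.data.sum(axis=1)
        assert np.allclose(sums, 200.0)
        assert out.stage == "normalised"
        # scale factors 2.0 and 2/3 for the 100- and 300-sum rows
        assert np.allclose(out.data.iloc[0], [100.0, 100.0])
        assert np.allclose(out.data.iloc[1], [100.0, 100.0])

    def test_single_sample_unchanged(self):
        fm = make_matrix([[2.0, 4.0]], stage="qc_filtered")
        out = normalise_tic(fm)
        np.testing.assert_allclose(out.data.to_numpy(), [[2.0, 4.0]])

    def test_zero_row_errors(self):
        fm = make_matrix(np.array([[1.0, 1.0], [0.0, 0.0]]), stage="qc_filtered")
        with pytest.raises(ValueError, match="S1"):
            normalise_tic(fm)

    def test_log2_values_and_imputation(self):
        fm = make_matrix([[8.0, 0.0, 2.0]], stage="normalised")
        out = log2_transform(fm)
        # zero imputed to half the smallest non-zero (1.0) -> log2 = 0
        np.testing.assert_allclose(out.data.to_numpy(), [[3.0, 0.0, 1.0]])
        assert out.stage == "log2"

    def test_log2_monotone(self, rng):
        vals = rng.uniform(0.5, 100, (1, 20))
        fm = make_matrix(vals, stage="normalised")
        out = log2_transform(fm).data.to_numpy()[0]
        assert np.all(np.argsort(out) == np.argsort(vals[0]))

    def test_stage_order_enforced(self):
        fm = make_matrix(np.ones((2, 2)), stage="raw")
        with pytest.raises(StageError):
            normalise_tic(fm)
        with pytest.raises(StageError):
            log2_transform(fm)


class TestFeatureMatrixIO:
    def test_write_read_round_trip(self, tmp_path, small_study):
        fm, _, _ = small_study
        fm.write(tmp_path / "m.csv")
        back = FeatureMatrix.read(tmp_path / "m.csv")
        assert back.stage == fm.stage
        pd.testing.assert_frame_equal(back.data, fm.data, check_exact=False,
                                      rtol=1e-9)
        pd.testing.assert_frame_equal(back.bin_info, fm.bin_info,
                                      check_exact=False, rtol=1e-9)
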
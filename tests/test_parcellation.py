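import numpy as np
import pandas as pd
import pytest

from stemcortex.exceptions import FormatError, ParameterError, ShapeError
from stemcortex.parcellation import (
    AnnotationTable,
    ParcellationScheme,
    TimeSeriesSet,
    compute_tsnr,
    extract_parcel_timeseries,
    read_annotation,
    read_matrix,
    read_parcellation,
    read_timeseries,
    write_annotation,
    write_matrix,
    write_parcellation,
    write_timeseries,
)


def _table(n_ctx=4, n_bs=2):
    rows = []
    for i in range(n_ctx):
        rows.append(dict(label=f"c{i}", structure="cortex",
                         hemisphere="L" if i % 2 else "R",
                         x=float(i), y=0.0, z=1.0,
                         sx=1.0, sy=0.0, sz=0.0))
    for i in range(n_bs):
        rows.append(dict(label=f"b{i}", structure="brainstem",
                         hemisphere="midline", x=0.0, y=0.0, z=-50.0 - i,
                         sx=np.nan, sy=np.nan, sz=np.nan))
    return pd.DataFrame(rows)


class TestParcellationScheme:
    def test_valid_table_roundtrips(self, tmp_path):
        scheme = ParcellationScheme(_table())
        assert len(scheme) == 6
        assert scheme.n_cortex == 4
        assert scheme.n_brainstem == 2
        p = tmp_path / "scheme.tsv"
        write_parcellation(scheme, p)
        back = read_parcellation(p)
        assert list(back.labels) == list(scheme.labels)
        np.testing.assert_allclose(back.centroids, scheme.centroids)

    def test_missing_column_raises(self):
        df = _table().drop(columns=["hemisphere"])
        with pytest.raises(FormatError, match="hemisphere"):
            ParcellationScheme(df)

    def test_duplicate_labels_raise(self):
        df = _table()
        df.loc[1, "label"] = "c0"
        with pytest.raises(FormatError, match="duplicate"):
            ParcellationScheme(df)

    def test_unknown_structure_raises(self):
        df = _table()
        df.loc[0, "structure"] = "cerebellum"
        with pytest.raises(FormatError, match="structure"):
            ParcellationScheme(df)

    def test_nonnumeric_coordinate_raises(self):
        df = _table()
        df["x"] = df["x"].astype(object)
        df.loc[0, "x"] = "wide"
        with pytest.raises(FormatError):
            ParcellationScheme(df)

    def test_masks_partition_regions(self):
        scheme = ParcellationScheme(_table())
        m_c, m_b = scheme.mask("cortex"), scheme.mask("brainstem")
        assert not (m_c & m_b).any()
        assert (m_c | m_b).all()
        with pytest.raises(ParameterError):
            scheme.mask("thalamus")


class TestTimeSeries:
    def test_shape_and_runs_validated(self):
        with pytest.raises(ShapeError):
            TimeSeriesSet("s", np.zeros(5), 2.5)
        with pytest.raises(ParameterError):
            TimeSeriesSet("s", np.zeros((3, 4)), 2.5, run_boundaries=[0, 3])
        with pytest.raises(FormatError):
            TimeSeriesSet("s", np.full((2, 5), np.nan), 2.5)
        with pytest.raises(ParameterError):
            TimeSeriesSet("s", np.zeros((2, 5)), -1.0)

    def test_roundtrip(self, tmp_path, rng):
        data = rng.standard_normal((3, 10))
        ts = TimeSeriesSet("sub-00", data, 2.5)
        p = tmp_path / "ts.tsv"
        write_timeseries(ts, ["a", "b", "c"], p)
        back = read_timeseries(p, subject_id="sub-00")
        np.testing.assert_allclose(back.data, data)
        assert back.subject_id == "sub-00"


class TestAnnotation:
    def test_zscore(self):
        t = AnnotationTable("m", [1.0, 2.0, 3.0])
        z = t.zscored()
        assert abs(z.values.mean()) < 1e-12
        assert abs(z.values.std() - 1.0) < 1e-12

    def test_constant_map_zscore_raises(self):
        with pytest.raises(ParameterError):
            AnnotationTable("m", [2.0, 2.0]).zscored()

    def test_roundtrip(self, tmp_path):
        t = AnnotationTable("m", [0.5, -1.5, 2.25])
        p = tmp_path / "m.tsv"
        write_annotation(t, ["a", "b", "c"], p)
        back = read_annotation(p, map_name="m")
        np.testing.assert_allclose(back.values, t.values)


class TestMatrixIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        M = rng.standard_normal((5, 5))
        p = tmp_path / "m.tsv"
        write_matrix(M, [f"r{i}" for i in range(5)], p)
        back, labels = read_matrix(p)
        np.testing.assert_allclose(back, M)  # %.17g is lossless for float64
        assert list(labels) == [f"r{i}" for i in range(5)]

    def test_npz_roundtrip_bit_exact(self, tmp_path, rng):
        M = rng.standard_normal((4, 4))
        p = tmp_path / "m.npz"
        write_matrix(M, list("abcd"), p)
        back, labels = read_matrix(p)
        assert np.array_equal(back, M)

    def test_nonsquare_raises(self, tmp_path):
        with pytest.raises(ShapeError):
            write_matrix(np.zeros((2, 3)), ["a", "b"], tmp_path / "m.tsv")


class TestExtraction:
    def _volume(self):
        # 2x1x1 grid, 4 timepoints; voxel 0 and voxel 1 carry distinct series
        img = np.zeros((2, 1, 1, 4))
        img[0, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        img[1, 0, 0] = [10.0, 20.0, 30.0, 40.0]
        return img

    def test_threshold_is_strict(self):
        img = self._volume()
        atlas = np.zeros((2, 1, 1, 2))
        atlas[0, 0, 0, 0] = 0.35   # exactly at threshold -> excluded
        atlas[1, 0, 0, 0] = 0.9
        atlas[:, 0, 0, 1] = 0.5    # both voxels
        ts, missing = extract_parcel_timeseries(img, atlas, threshold=0.35)
        np.testing.assert_allclose(ts.data[0], img[1, 0, 0])
        np.testing.assert_allclose(ts.data[1], img.mean(axis=(0, 1, 2)))
        assert not missing.any()

    def test_missing_region_masked_with_warning(self):
        img = self._volume()
        atlas = np.zeros((2, 1, 1, 2))
        atlas[:, 0, 0, 0] = 0.9
        # region 1 never exceeds the threshold
        with pytest.warns(UserWarning, match="empty after thresholding"):
            ts, missing = extract_parcel_timeseries(img, atlas, threshold=0.35)
        assert missing.tolist() == [False, True]
        assert np.isnan(ts.data[1]).all()
        assert np.isfinite(ts.data[0]).all()

    def test_grid_mismatch_raises(self):
        with pytest.raises(ShapeError, match="grid"):
            extract_parcel_timeseries(self._volume(), np.zeros((3, 1, 1, 2)))

    def test_bad_threshold_raises(self):
        with pytest.raises(ParameterError):
            extract_parcel_timeseries(self._volume(), np.zeros((2, 1, 1, 1)),
                                      threshold=1.5)


class TestTsnr:
    def test_known_value(self):
        data = np.array([[1.0, 2.0, 3.0]])
        ts = TimeSeriesSet("s", data, 1.0)
        t = compute_tsnr(ts)
        assert t.values[0] == pytest.approx(2.0 / 1.0)  # mean 2, sd (ddof=1) 1

    def test_zero_variance_is_nan_with_warning(self):
        ts = TimeSeriesSet("s", np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]), 1.0)
        with pytest.warns(UserWarning, match="constant"):
            t = compute_tsnr(ts)
        assert np.isnan(t.values[0])
        assert np.isfinite(t.values[1])
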
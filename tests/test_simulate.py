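import json

import numpy as np
import pytest

from stemcortex import connectome as conn
from stemcortex import simulate as sim
from stemcortex.exceptions import ParameterError


class TestDefaults:
    def test_default_sizes(self, default_model, default_scheme):
        assert len(default_scheme) == 458
        assert default_scheme.n_cortex == 400
        assert default_scheme.n_brainstem == 58
        hemis = default_scheme.table.loc[default_scheme.mask("brainstem"),
                                         "hemisphere"]
        assert (hemis == "midline").sum() == 8
        assert default_model.n_receptor_maps == 18
        assert default_model.n_term_maps == 123

    def test_bilateral_pairs_are_mirrored(self, default_model, default_scheme):
        bs = default_scheme.table[default_scheme.mask("brainstem")]
        lateral = bs[bs.hemisphere != "midline"]
        assert len(lateral) == 50
        xyz = lateral[["x", "y", "z"]].to_numpy()
        for i in range(0, len(xyz), 2):
            a, b = xyz[i], xyz[i + 1]
            assert a[0] == pytest.approx(-b[0])
            assert a[1] == b[1] and a[2] == b[2]

    def test_cortex_on_sphere(self, default_model, default_scheme):
        s = default_scheme.sphere_coords[default_scheme.mask("cortex")]
        np.testing.assert_allclose(np.linalg.norm(s, axis=1), 1.0, atol=1e-12)

    def test_projection_maps_nearly_orthogonal(self, default_model):
        _, _, proj, _ = sim.planted_structures(default_model)
        C = np.corrcoef(proj)
        off = C[~np.eye(len(C), dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_projection_maps_zscored(self, default_model):
        _, _, proj, _ = sim.planted_structures(default_model)
        np.testing.assert_allclose(proj.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(proj.std(axis=1), 1.0, atol=1e-10)

    def test_community_sizes_balanced(self, default_model, default_truth):
        sizes = np.bincount(default_truth.community_labels)
        assert len(sizes) == default_model.K
        assert sizes.max() - sizes.min() <= 1


class TestDeterminism:
    def test_same_seed_same_everything(self, small_model):
        a = sim.simulate_timeseries(small_model, sim.make_scheme(small_model),
                                    n_subjects=2)
        b = sim.simulate_timeseries(small_model, sim.make_scheme(small_model),
                                    n_subjects=2)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.data, tb.data)
        ma = sim.make_annotation_maps(small_model, "receptor")
        mb = sim.make_annotation_maps(small_model, "receptor")
        for x, y in zip(ma, mb):
            assert np.array_equal(x.values, y.values)

    def test_different_seeds_differ(self):
        m1 = sim.GenerativeModel(seed=1, n_cortex=30, n_brainstem=10,
                                 n_midline=2, K=3, n_timepoints=90)
        m2 = sim.GenerativeModel(seed=2, n_cortex=30, n_brainstem=10,
                                 n_midline=2, K=3, n_timepoints=90)
        s1, s2 = sim.make_scheme(m1), sim.make_scheme(m2)
        a = sim.simulate_timeseries(m1, s1, n_subjects=1)[0]
        b = sim.simulate_timeseries(m2, s2, n_subjects=1)[0]
        assert not np.array_equal(a.data, b.data)

    def test_kinds_use_independent_streams(self, small_model):
        rec = sim.make_annotation_maps(small_model, "receptor")
        term = sim.make_annotation_maps(small_model, "term")
        assert not np.array_equal(rec[0].values, term[0].values)


class TestClosedForm:
    def test_empirical_fc_converges_to_expected(self, small_model, small_scheme):
        expected = sim.expected_fc(small_model, small_scheme)
        ts = sim.simulate_timeseries(small_model, small_scheme, n_subjects=1,
                                     n_timepoints=20000)[0]
        fc = conn.build_fc(ts, small_scheme)
        err = np.abs(fc.matrix - expected)
        assert np.nanmax(err) < 0.05
        off = ~np.eye(len(small_scheme), dtype=bool)
        r = np.corrcoef(fc.matrix[off], expected[off])[0, 1]
        assert r > 0.99

    def test_expected_fc_is_valid_correlation(self, small_model, small_scheme):
        e = sim.expected_fc(small_model, small_scheme)
        np.testing.assert_allclose(np.diag(e), 1.0, atol=1e-12)
        np.testing.assert_allclose(e, e.T, atol=1e-12)
        assert np.abs(e).max() <= 1.0 + 1e-12
        evals = np.linalg.eigvalsh(e)
        assert evals.min() > -1e-10


class TestAnnotations:
    def test_counts(self, small_model):
        assert len(sim.make_annotation_maps(small_model, "receptor")) == 6
        assert len(sim.make_annotation_maps(small_model, "term")) == 15
        with pytest.raises(ParameterError):
            sim.make_annotation_maps(small_model, "sulcal")

    def test_mixing_recorded_in_truth(self, small_model):
        truth = sim.ground_truth(small_model)
        assert truth.receptor_mixing.shape == (small_model.K, 6)
        assert truth.term_mixing.shape == (small_model.K, 15)
        # each map has exactly one dominant community weight
        assert (truth.term_mixing.max(axis=0) >= 0.8).all()

    def test_zero_noise_maps_are_exact_mixtures(self):
        m = sim.GenerativeModel(seed=5, n_cortex=60, n_brainstem=12,
                                n_midline=2, K=3, annotation_noise_sd=0.0,
                                n_receptor_maps=4)
        truth = sim.ground_truth(m)
        maps = sim.make_annotation_maps(m, "receptor")
        for j, t in enumerate(maps):
            np.testing.assert_allclose(
                t.values, truth.receptor_mixing[:, j] @ truth.projection_maps,
                atol=1e-12)


class TestValidation:
    def test_bad_parameters_raise(self):
        with pytest.raises(ParameterError):
            sim.GenerativeModel(K=0)
        with pytest.raises(ParameterError):
            sim.GenerativeModel(n_brainstem=11, n_midline=2)  # odd lateral count
        with pytest.raises(ParameterError):
            sim.GenerativeModel(noise_sd=0.0)
        with pytest.raises(ParameterError):
            sim.GenerativeModel(n_brainstem=8, n_midline=0, K=5)
        with pytest.raises(ParameterError):
            sim.simulate_timeseries(sim.GenerativeModel(), None, n_timepoints=10)


class TestWriteDataset:
    def test_files_written(self, tmp_path):
        m = sim.GenerativeModel(seed=2, n_cortex=30, n_brainstem=10,
                                n_midline=2, K=3, n_subjects=2,
                                n_timepoints=90, n_receptor_maps=3,
                                n_term_maps=4, n_distance_factors=6)
        manifest = sim.write_dataset(m, tmp_path)
        assert (tmp_path / "parcellation.tsv").exists()
        assert len(list(tmp_path.glob("timeseries_*.tsv"))) == 2
        assert len(list((tmp_path / "receptor_maps").glob("*.tsv"))) == 3
        assert len(list((tmp_path / "term_maps").glob("*.tsv"))) == 4
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(truth["community_labels"]) == 10
        assert manifest["n_regions"] == 40
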
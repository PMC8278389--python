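"""Trajectory container, COLVAR/CSV parsing, and serialization round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import torsmap as tm
from torsmap.errors import (ColvarParseError, EmptyInputError, FormatError,
                            MissingColumnError)
from torsmap.io import (export_distance_matrix_text, read_cluster_result,
                        write_cluster_result, write_labels_csv)


def _write(tmp_path, text, name="traj.colvar"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestWrap:
    @given(st.floats(-50, 50))
    @settings(derandomize=True)
    def test_wrap_idempotent_and_in_range(self, x):
        w = tm.wrap_angles(x)
        assert -np.pi <= w < np.pi
        assert tm.wrap_angles(w) == w

    def test_wrap_known_value(self):
        # 3.5 rad leaves [-pi, pi) and comes back as 3.5 - 2*pi
        assert tm.wrap_angles(3.5) == pytest.approx(3.5 - 2 * np.pi)

    def test_pi_maps_to_minus_pi(self):
        assert tm.wrap_angles(np.pi) == pytest.approx(-np.pi)


class TestReadColvar:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA tauB\n"
                             "0.0 0.1 -0.2\n1.0 0.3 0.4\n2.0 -1.0 1.0\n")
        traj = tm.read_colvar(p)
        assert traj.n_frames == 3 and traj.n_cv == 2
        assert traj.angle_names == ["tauA", "tauB"]
        np.testing.assert_allclose(traj.time, [0.0, 1.0, 2.0])

    def test_angles_wrapped_on_read(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 3.5\n")
        traj = tm.read_colvar(p)
        assert traj.angles[0, 0] == pytest.approx(3.5 - 2 * np.pi)

    def test_degrees_flag(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 90.0\n")
        traj = tm.read_colvar(p, degrees=True)
        assert traj.angles[0, 0] == pytest.approx(np.pi / 2)

    def test_missing_column_is_named_error(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 0.1\n")
        with pytest.raises(MissingColumnError, match="tauQ"):
            tm.read_colvar(p, angle_columns=["tauQ"])

    def test_ragged_row_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 0.1\n1.0\n")
        with pytest.raises(ColvarParseError, match=":3"):
            tm.read_colvar(p)

    def test_non_numeric_row_rejected_not_skipped(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 abc\n")
        with pytest.raises(ColvarParseError, match="non-numeric"):
            tm.read_colvar(p)

    def test_empty_file_error(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n")
        with pytest.raises(EmptyInputError):
            tm.read_colvar(p)

    def test_changed_fields_header_midfile_is_error(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n0.0 0.1\n"
                             "#! FIELDS time tauB\n0.0 0.2\n")
        with pytest.raises(ColvarParseError, match="mid-file"):
            tm.read_colvar(p)

    def test_repeated_identical_header_and_set_lines_ignored(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA\n#! SET min_tauA -pi\n"
                             "0.0 0.1\n#! FIELDS time tauA\n1.0 0.2\n")
        assert tm.read_colvar(p).n_frames == 2

    def test_bias_and_energy_columns(self, tmp_path):
        p = _write(tmp_path, "#! FIELDS time tauA vbias es exs\n"
                             "0.0 0.1 2.5 -100.0 -50.0\n")
        traj = tm.read_colvar(p, angle_columns=["tauA"], bias_column="vbias",
                              energy_columns={"solute": "es",
                                              "solute_solvent": "exs"})
        assert traj.bias[0] == 2.5
        assert traj.energy_solute[0] == -100.0
        assert traj.energy_solute_solvent[0] == -50.0

    def test_colvar_round_trip(self, tmp_path, world):
        traj, lab = tm.sample_unbiased(world, 50, seed=7)
        traj = tm.attach_energies(traj, lab, world, seed=8)
        path = tmp_path / "rt.colvar"
        tm.write_colvar(traj, path)
        back = tm.read_colvar(path, angle_columns=world.angle_names,
                              energy_columns={"solute": "ene.solute",
                                              "solvent": "ene.solvent",
                                              "solute_solvent": "ene.xsolv"})
        np.testing.assert_array_equal(back.angles, traj.angles)
        np.testing.assert_array_equal(back.energy_solute, traj.energy_solute)

    def test_csv_reader_matches_colvar(self, tmp_path):
        (tmp_path / "t.csv").write_text("time,tauA,tauB\n0.0,0.1,-0.2\n"
                                        "1.0,3.5,0.4\n")
        traj = tm.read_csv_trajectory(tmp_path / "t.csv")
        assert traj.n_frames == 2 and traj.n_cv == 2
        assert traj.angles[1, 0] == pytest.approx(3.5 - 2 * np.pi)


class TestTrajectoryContainer:
    def test_optional_column_length_checked(self):
        with pytest.raises(ValueError, match="bias"):
            tm.DihedralTrajectory(np.zeros((3, 2)), ["a", "b"],
                                  bias=np.zeros(2))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            tm.DihedralTrajectory(np.zeros((2, 2)), ["a", "a"])

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            tm.DihedralTrajectory(np.zeros((0, 2)), ["a", "b"])


class TestFingerprintIO:
    @pytest.fixture
    def fingerprints(self, reference_run):
        traj, _, model = reference_run
        return tm.build_fingerprints(traj, model.labels_)

    def test_round_trip_bitwise(self, tmp_path, fingerprints):
        path = tmp_path / "fp.json"
        tm.write_fingerprints(fingerprints, path)
        back = tm.read_fingerprints(path)
        np.testing.assert_array_equal(back.probs, fingerprints.probs)
        np.testing.assert_array_equal(back.support, fingerprints.support)
        np.testing.assert_array_equal(back.bin_edges, fingerprints.bin_edges)
        assert back.angle_names == fingerprints.angle_names
        np.testing.assert_array_equal(back.cluster_ids,
                                      fingerprints.cluster_ids)

    def test_file_declares_12_records_of_6_distributions(self, tmp_path,
                                                         fingerprints):
        import json
        path = tmp_path / "fp.json"
        tm.write_fingerprints(fingerprints, path)
        payload = json.loads(path.read_text())
        assert len(payload["fingerprints"]) == 12
        assert all(len(rec["probs"]) == 6 for rec in payload["fingerprints"])

    def test_unnormalized_probabilities_rejected(self, tmp_path, fingerprints):
        import json
        path = tmp_path / "fp.json"
        tm.write_fingerprints(fingerprints, path)
        payload = json.loads(path.read_text())
        payload["fingerprints"][0]["probs"][0][0] += 0.01
        path.write_text(json.dumps(payload))
        with pytest.raises(FormatError, match="sum to 1"):
            tm.read_fingerprints(path)

    def test_wrong_version_rejected(self, tmp_path, fingerprints):
        import json
        path = tmp_path / "fp.json"
        tm.write_fingerprints(fingerprints, path)
        payload = json.loads(path.read_text())
        payload["version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(FormatError, match="version"):
            tm.read_fingerprints(path)


class TestDistanceMatrixIO:
    def test_round_trip_and_checksum(self, tmp_path, rng):
        angles = rng.uniform(-np.pi, np.pi, (20, 3))
        dm = tm.distance_matrix(angles)
        path = tmp_path / "d.npz"
        tm.save_distance_matrix(dm, path)
        back = tm.load_distance_matrix(path)
        np.testing.assert_array_equal(back.values, dm.values)
        assert back.form == dm.form

    def test_corruption_detected(self, tmp_path, rng):
        import json
        angles = rng.uniform(-np.pi, np.pi, (10, 2))
        dm = tm.distance_matrix(angles)
        path = tmp_path / "d.npz"
        tm.save_distance_matrix(dm, path)
        with np.load(path) as npz:
            values, meta = npz["values"].copy(), str(npz["meta"])
        values[0, 1] += 1.0
        np.savez(path, values=values, meta=np.array(meta))
        with pytest.raises(FormatError, match="checksum"):
            tm.load_distance_matrix(path)

    def test_text_export(self, tmp_path, rng):
        angles = rng.uniform(-np.pi, np.pi, (5, 2))
        dm = tm.distance_matrix(angles)
        export_distance_matrix_text(dm, tmp_path / "d.txt")
        np.testing.assert_allclose(np.loadtxt(tmp_path / "d.txt"), dm.values)


class TestClusterResultIO:
    def test_round_trip(self, tmp_path, reference_run):
        _, _, model = reference_run
        path = tmp_path / "clusters.json"
        write_cluster_result(model, path)
        back = read_cluster_result(path)
        np.testing.assert_array_equal(back["labels"], model.labels_)
        np.testing.assert_array_equal(back["centers"], model.centers_)
        np.testing.assert_array_equal(back["rho"], model.rho_)
        assert back["d_c"] == pytest.approx(model.d_c_)

    def test_labels_csv(self, tmp_path, reference_run):
        import pandas as pd
        traj, _, model = reference_run
        clf = tm.FingerprintClassifier().fit(traj, model.labels_)
        classified = clf.classify(traj)
        path = tmp_path / "labels.csv"
        write_labels_csv(classified, path, time=traj.time)
        df = pd.read_csv(path)
        assert list(df.columns) == ["frame", "time", "label", "score"]
        np.testing.assert_array_equal(df["label"].to_numpy(),
                                      classified.labels)
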
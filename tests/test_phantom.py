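"""Phantom generation: determinism, closed-form truth, recovery."""

import numpy as np
import pytest

import cardiomotion as cm
from cardiomotion.phantom import (
    load_spec,
    read_truth_summary,
    save_spec,
    _direction_coords,
)

from conftest import tiny_phantom_spec


class TestPrimitives:
    def test_primitive_validation(self):
        with pytest.raises(cm.PhantomError):
            cm.Ellipsoid((0, 0, 0), (1, -1, 1))
        with pytest.raises(cm.PhantomError):
            cm.EllipsoidShell((0, 0, 0), (5, 5, 5), 6.0)
        with pytest.raises(cm.PhantomError):
            cm.Tube((0, 0, 0), 2.0, 10.0, axis="XX")
        with pytest.raises(cm.PhantomError):
            cm.Tube((0, 0, 0), 2.0, 10.0, axis="CC", tilt_mm=(0, 0, 1))

    def test_closed_form_volumes(self):
        e = cm.Ellipsoid((0, 0, 0), (3, 4, 5))
        assert e.base_volume_mm3() == pytest.approx(4 / 3 * np.pi * 60)
        s = cm.EllipsoidShell((0, 0, 0), (5, 5, 5), 2.0)
        assert s.base_volume_mm3() == pytest.approx(4 / 3 * np.pi * (125 - 27))
        t = cm.Tube((0, 0, 0), 2.0, 10.0)
        assert t.base_volume_mm3() == pytest.approx(np.pi * 4 * 20 + 4 / 3 * np.pi * 8)


class TestGenerateSubject:
    def test_determinism(self):
        spec = tiny_phantom_spec(seed=3)
        s1, t1 = cm.generate_subject(spec, 2, "EIBH")
        s2, t2 = cm.generate_subject(spec, 2, "EIBH")
        for name in s1:
            for a, b in zip(s1[name].phases, s2[name].phases):
                assert np.array_equal(a.voxels, b.voxels)
            np.testing.assert_array_equal(
                t1.structures[name].volumes_ml, t2.structures[name].volumes_ml)

    def test_subject_jitter_is_state_independent(self):
        spec = tiny_phantom_spec(seed=3)
        _, te = cm.generate_subject(spec, 1, "EIBH")
        _, td = cm.generate_subject(spec, 1, "DIBH")
        for name in te.structures:
            np.testing.assert_allclose(te.structures[name].translation_amp_mm,
                                       td.structures[name].translation_amp_mm)
            assert te.structures[name].contraction == td.structures[name].contraction

    def test_zero_motion_phantom_is_static(self):
        spec = tiny_phantom_spec(
            structures=(cm.StructureSpec("heart",
                                         cm.Ellipsoid((28, 28, 35), (16, 14, 15))),),
            subject_sigma=0.0, size_sigma=0.0)
        series, truth = cm.generate_subject(spec, 0, "EIBH")
        s = cm.summarize_series(series["heart"])
        assert s.disp_lr_mm == s.disp_ap_mm == s.disp_cc_mm == 0.0
        assert s.dsc_min == 1.0 and s.hd_max_mm == 0.0
        assert truth.structures["heart"].volume_variation_pct == 0.0

    def test_pure_translation_recovers_amplitude(self):
        spec = tiny_phantom_spec(
            structures=(cm.StructureSpec(
                "heart", cm.Ellipsoid((24, 28, 35), (14, 13, 14)),
                translation_amp_mm=(6.0, 0.0, 0.0)),),
            subject_sigma=0.0, size_sigma=0.0, n_phases=8)
        series, truth = cm.generate_subject(spec, 0, "EIBH")
        traj = cm.compute_trajectory(series["heart"], with_pair_metrics=False)
        disp = traj.positions_mm.max(0) - traj.positions_mm.min(0)
        assert truth.structures["heart"].displacement_mm[0] == pytest.approx(6.0)
        assert disp[0] == pytest.approx(6.0, abs=2 * 2.0)  # 2 voxel lengths (LR)
        var = 100 * (traj.volumes_ml.max() - traj.volumes_ml.min()) / traj.volumes_ml.min()
        assert var < 5.0  # no programmed contraction, only voxelization jitter

    def test_contraction_recovers_volume_ratio(self):
        # a with (1-a)^-3 = 1.3  =>  a = 1 - 1.3**(-1/3)
        a = 1 - 1.3 ** (-1 / 3)
        spec = tiny_phantom_spec(
            structures=(cm.StructureSpec(
                "heart", cm.Ellipsoid((28, 28, 35), (16, 15, 16)),
                contraction=a),),
            subject_sigma=0.0, size_sigma=0.0, n_phases=8)
        series, truth = cm.generate_subject(spec, 0, "EIBH")
        assert truth.structures["heart"].volume_variation_pct == pytest.approx(30.0)
        traj = cm.compute_trajectory(series["heart"], with_pair_metrics=False)
        var = 100 * (traj.volumes_ml.max() - traj.volumes_ml.min()) / traj.volumes_ml.min()
        assert var == pytest.approx(30.0, abs=3.0)

    def test_structure_escaping_grid_is_named(self):
        spec = tiny_phantom_spec(
            structures=(cm.StructureSpec(
                "runaway", cm.Ellipsoid((28, 28, 35), (16, 14, 15)),
                translation_amp_mm=(40.0, 0.0, 0.0)),),
            subject_sigma=0.0)
        with pytest.raises(cm.PhantomError, match="runaway"):
            cm.generate_subject(spec, 0, "EIBH")

    def test_unknown_state_rejected(self):
        with pytest.raises(cm.PhantomError, match="state"):
            cm.generate_subject(tiny_phantom_spec(), 0, "XXBH")


class TestDefaultInventory:
    def test_voxelization_error_bound_on_base_geometry(self):
        """Voxelized volume within 5% of the analytic volume for every
        default structure at the default grid resolution."""
        spec = cm.default_phantom_spec()
        coords = _direction_coords(spec)
        for s in spec.structures:
            vox = int(s.primitive.inside(coords, 1.0, np.zeros(3)).sum())
            analytic = s.primitive.base_volume_mm3() / np.prod(spec.spacing_mm)
            assert abs(vox - analytic) / analytic < 0.05, s.name

    def test_truth_consistent_with_spec_at_reference_phase(self):
        spec = cm.default_phantom_spec(seed=11)
        _, truth = cm.generate_subject(spec, 0, "EIBH")
        for s in spec.structures:
            st = truth.structures[s.name]
            expected = s.primitive.base_volume_mm3() * st.size_factor**3 / 1000
            assert st.volumes_ml[0] == pytest.approx(expected)
            np.testing.assert_allclose(st.centroids_mm[0], s.primitive.center_mm)

    def test_dibh_volumes_lower_than_eibh_for_every_structure(self):
        """The deep-inspiration state compresses every structure — the
        qualitative direction of the breath-hold volume effect."""
        spec = tiny_phantom_spec(seed=9)
        vols = {"EIBH": [], "DIBH": []}
        for state in vols:
            for subj in range(3):
                series, _ = cm.generate_subject(spec, subj, state)
                vols[state].append(
                    {n: np.mean([cm.volume_ml(m) for m in ps.phases])
                     for n, ps in series.items()})
        for name in vols["EIBH"][0]:
            ei = np.mean([v[name] for v in vols["EIBH"]])
            di = np.mean([v[name] for v in vols["DIBH"]])
            assert di < ei, name


class TestCohortOnDisk:
    def test_cohort_determinism_and_roundtrip(self, tmp_path):
        spec = tiny_phantom_spec(seed=4, n_phases=4)
        d1 = cm.generate_cohort(spec, 2, ["EIBH"], tmp_path / "a")
        d2 = cm.generate_cohort(spec, 2, ["EIBH"], tmp_path / "b")
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
        # masks are loadable as series through the standard reader
        s = cm.load_series(d1 / "subject00", "heart", "EIBH", subject_id="subject00")
        assert s.n_phases == 4
        # truth file round-trips
        truth = read_truth_summary(d1)
        assert set(truth.structure) == {"heart", "LV"}
        assert len(truth) == 2 * 2  # subjects x structures

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = cm.default_phantom_spec(seed=7)
        save_spec(spec, tmp_path / "spec.yaml")
        back = load_spec(tmp_path / "spec.yaml")
        assert back == spec
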
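"""Phantom generator: determinism, label rules, modality gap, DVH consistency."""

import numpy as np
import pytest

from mrgart.dlir import mutual_information_hard
from mrgart.labeler import StrategyLabel, determine_strategy, evaluate_plan
from mrgart.synthetic import (
    PhantomSpec,
    generate_case,
    generate_cohort,
    generate_dvh_tables,
    read_cohort,
    recompute_label,
    split_by_patient,
    write_cohort,
)
from mrgart.volume import DisplacementField


SMALL = dict(grid_shape=(32, 32, 16), voxel_spacing=(4.0, 4.0, 6.0),
             deformation_smoothness=18.0, roi_margin_mm=16.0)


class TestGenerateCase:
    def test_zero_deformation(self):
        spec = PhantomSpec(deformation_amplitude=0.0, noise_sigma=0.0, **SMALL)
        case = generate_case(spec, "P0", 0)
        assert np.all(case.true_field.u == 0.0)
        assert case.label is StrategyLabel.ATP
        # fixed is the MR rendering of the *undeformed* anatomy
        from mrgart.synthetic import base_anatomy, mr_transfer

        np.testing.assert_allclose(case.fixed.data, mr_transfer(base_anatomy(spec)))

    def test_fixed_seed_determinism(self):
        spec = PhantomSpec(seed=5, **SMALL)
        a = generate_case(spec, "P1", 2)
        b = generate_case(spec, "P1", 2)
        assert np.array_equal(a.fixed.data, b.fixed.data)
        assert np.array_equal(a.moving.data, b.moving.data)
        assert np.array_equal(a.true_field.u, b.true_field.u)
        assert a.label == b.label

    def test_large_amplitude_labels_ats(self):
        spec = PhantomSpec(deformation_amplitude=8.0, label_threshold=2.0,
                           deformation_smoothness=15.0)
        case = generate_case(spec)
        mean_mm = case.true_field.mean_magnitude_mm(case.roi_mask.data > 0.5)
        assert mean_mm > 2.0
        assert case.label is StrategyLabel.ATS

    def test_degenerate_amplitude_rejected(self):
        spec = PhantomSpec(deformation_amplitude=200.0)
        with pytest.raises(ValueError, match="amplitude"):
            generate_case(spec, "P0", 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(4, 32, 32))
        with pytest.raises(ValueError):
            PhantomSpec(deformation_smoothness=0.5)
        with pytest.raises(ValueError):
            PhantomSpec(label_threshold=0.0)

    def test_structures_disjoint_and_nonempty(self):
        case = generate_case(PhantomSpec(**SMALL), "P0", 0)
        occupancy = sum(m.data for m in case.structures.values())
        assert occupancy.max() <= 1
        for m in case.structures.values():
            assert m.data.sum() > 0

    def test_label_consistency_invariant(self):
        spec = PhantomSpec(seed=9, deformation_amplitude=6.0)
        case = generate_case(spec, "P2", 1)
        assert recompute_label(case.true_field, case.roi_mask.data,
                               spec.label_threshold) == case.label

    def test_field_smoothness_bound(self):
        # max finite-difference gradient bounded by amplitude/correlation length
        spec = PhantomSpec(deformation_amplitude=8.0, deformation_smoothness=15.0)
        case = generate_case(spec, "P0", 0)
        sp = np.asarray(spec.voxel_spacing).reshape(3, 1, 1, 1)
        u_mm = case.true_field.u * sp
        max_grad = 0.0
        for ax in range(1, 4):
            d = np.abs(np.diff(u_mm, axis=ax)) / spec.voxel_spacing[ax - 1]
            max_grad = max(max_grad, float(d.max()))
        bound = 3.0 * spec.deformation_amplitude / spec.deformation_smoothness
        assert max_grad <= bound


class TestModalityGap:
    def test_intensity_mismatch_but_mi_persists(self):
        spec = PhantomSpec(deformation_amplitude=0.0, **SMALL)
        case = generate_case(spec, "P0", 0)
        f, m = case.fixed.data.ravel(), case.moving.data.ravel()
        corr = np.corrcoef(f, m)[0, 1]
        assert corr < 0.999  # the MR transfer + noise breaks intensity identity
        mi, _ = mutual_information_hard(f, m, bins=16)
        rng = np.random.default_rng(0)
        mi_perm, _ = mutual_information_hard(f, rng.permutation(m), bins=16)
        assert mi > 10 * mi_perm
        assert mi > 0.5


class TestGenerateCohort:
    def test_counts_and_patient_ids(self):
        cases = generate_cohort(PhantomSpec(**SMALL), 4, 5, ats_fraction_target=0.5)
        assert len(cases) == 20
        pids = {c.patient_id for c in cases}
        assert len(pids) == 4
        for pid in pids:
            assert sum(c.patient_id == pid for c in cases) == 5

    def test_all_ats_at_target_one(self):
        cases = generate_cohort(PhantomSpec(**SMALL), 2, 3, ats_fraction_target=1.0)
        assert all(c.label is StrategyLabel.ATS for c in cases)

    def test_clinical_cohort_size(self):
        # 36 patients x 5 fractions = 180; counting only, tiny grids
        # coarse 16^3 voxels but the standard 128 mm physical extent
        cases = generate_cohort(PhantomSpec(grid_shape=(16, 16, 16),
                                            voxel_spacing=(8.0, 8.0, 6.0),
                                            deformation_smoothness=20.0,
                                            roi_margin_mm=16.0),
                                36, 5, ats_fraction_target=0.77)
        assert len(cases) == 180
        n_ats = sum(int(c.label) for c in cases)
        assert n_ats == round(0.77 * 180)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(PhantomSpec(**SMALL), 2, 2, ats_fraction_target=1.5)

    def test_patient_level_split_is_leak_free(self):
        cases = generate_cohort(PhantomSpec(**SMALL), 6, 2, ats_fraction_target=0.5)
        train, test = split_by_patient(cases, 4)
        assert {c.patient_id for c in train}.isdisjoint({c.patient_id for c in test})
        assert len(train) == 8 and len(test) == 4


class TestDvhTables:
    def _case(self, target_mean):
        return generate_case(PhantomSpec(seed=3, **SMALL), "P0", 0,
                             _target_mean_mm=target_mean)

    def test_zero_deformation_atp_within_tolerance(self):
        spec = PhantomSpec(deformation_amplitude=0.0, **SMALL)
        case = generate_case(spec, "P0", 0)
        assert evaluate_plan(case.dvh_atp).acceptable

    def test_large_deformation_atp_violates(self):
        case = self._case(target_mean=4.0)  # 2x the label threshold
        ev = evaluate_plan(case.dvh_atp)
        assert not ev.acceptable
        assert len(ev.violations) >= 1

    @pytest.mark.parametrize("target_mean", [0.8, 1.6, 3.0, 4.0])
    def test_ats_table_always_acceptable(self, target_mean):
        case = self._case(target_mean)
        assert evaluate_plan(case.dvh_ats).acceptable

    @pytest.mark.parametrize("target_mean", [0.8, 1.6, 3.0, 4.0])
    def test_dosimetric_label_matches_geometric_label(self, target_mean):
        case = self._case(target_mean)
        decision = determine_strategy(case.dvh_atp, case.dvh_ats)
        assert decision.label == case.label

    def test_empty_structures_rejected(self):
        rng = np.random.default_rng(0)
        field = DisplacementField(np.zeros((3, 8, 8, 8)))
        with pytest.raises(ValueError):
            generate_dvh_tables(field, {}, rng)


def test_cohort_write_read_round_trip(tmp_path):
    cases = generate_cohort(PhantomSpec(seed=7, **SMALL), 2, 2, ats_fraction_target=0.5)
    manifest = write_cohort(cases, tmp_path / "cohort")
    back = read_cohort(manifest)
    assert len(back) == len(cases)
    for a, b in zip(cases, sorted(back, key=lambda c: (c.patient_id, c.fraction_index))):
        assert a.patient_id == b.patient_id and a.label == b.label
        np.testing.assert_allclose(a.fixed.data, b.fixed.data, atol=1e-6)
        np.testing.assert_allclose(a.true_field.u, b.true_field.u, atol=1e-6)
        np.testing.assert_array_equal(a.roi_mask.data, b.roi_mask.data)
        assert a.dvh_atp.values.keys() == b.dvh_atp.values.keys()
        b.validate()
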
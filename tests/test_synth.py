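"""Synthetic-data generator: determinism, anchors, recovery."""

import numpy as np
import pytest
from scipy.optimize import brentq

from thermacup.errors import ConfigurationError, InvalidArgumentError
from thermacup.metrics import POST_TIMEPOINTS, TIMEPOINTS
from thermacup.register import AffineTransform2D, EllipseSpec, estimate_affine
from thermacup.roi import REGION_NAMES, derive_concentric, rasterize_masks
from thermacup.synth import (
    CohortParams,
    ErythemaGroupParams,
    KineticsParams,
    RegionKinetics,
    SubjectRecord,
    generate_cohort,
    generate_erythema_series,
    generate_fiducials,
    generate_study,
    generate_thermal_series,
)

CENTER_ROI = EllipseSpec((160.0, 120.0), (80.0, 64.0), 0.3)


def any_subject(mst_level=7):
    return SubjectRecord("S001", "female", 28.0, 60.0, mst_level)


class TestGenerateCohort:
    def test_group_sizes_and_total(self):
        cohort = generate_cohort(30, 5, seed=1)
        assert len(cohort) == 35
        assert sum(r.mst_level >= 6 for r in cohort) == 30
        assert sum(r.mst_level <= 5 for r in cohort) == 5

    def test_minimal_cohort(self):
        (rec,) = generate_cohort(0, 1, seed=7)
        assert rec.mst_group == "lighter"

    def test_seed_determinism(self):
        assert generate_cohort(30, 5, seed=1) == generate_cohort(30, 5, seed=1)
        assert generate_cohort(30, 5, seed=1) != generate_cohort(30, 5, seed=2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_cohort(0, 0, seed=1)

    def test_derived_fields_consistent(self):
        for rec in generate_cohort(10, 3, seed=3):
            assert (rec.mst_group == "darker") == (rec.mst_level >= 6)

    def test_bmi_marginal_over_many_cohorts(self):
        """Empirical mean BMI within ±1 of the configured mean over 200 cohorts."""
        p = CohortParams()
        means = [
            np.mean([r.bmi for r in generate_cohort(30, 5, seed=s)]) for s in range(200)
        ]
        assert np.mean(means) == pytest.approx(p.bmi_mean, abs=1.0)


class TestGenerateThermalSeries:
    def test_noise_free_minute0_region_medians(self):
        frames, _ = generate_thermal_series(
            any_subject(), CENTER_ROI, KineticsParams().noise_free(), seed=1
        )
        masks = rasterize_masks(derive_concentric(CENTER_ROI), (240, 320))
        m0 = next(f for f in frames if f.timepoint == "m0")
        pre = next(f for f in frames if f.timepoint == "pre")
        expected = {"Peri-ROI": 0.37, "ROI Edge": -0.06, "ROI Center": -0.54}
        for name, mask in masks:
            delta = np.median(m0.temperatures[mask]) - np.median(pre.temperatures[mask])
            assert delta == pytest.approx(expected[name], abs=0.02), name

    def test_pre_frame_is_flat_baseline(self):
        params = KineticsParams().noise_free()
        frames, _ = generate_thermal_series(any_subject(), CENTER_ROI, params, seed=1)
        pre = next(f for f in frames if f.timepoint == "pre")
        assert np.all(pre.temperatures == params.baseline_temp)

    def test_null_perturbation_gives_uniform_frames(self):
        flat = RegionKinetics(0.0, 0.0, 1.0, 0.0)
        params = KineticsParams(peri=flat, edge=flat, center=flat, noise_sd=0.0)
        frames, _ = generate_thermal_series(any_subject(), CENTER_ROI, params, seed=1)
        for f in frames:
            assert np.all(f.temperatures == params.baseline_temp)

    def test_center_kinetics_cross_zero_between_minutes_3_and_4(self):
        """Root of the default ROI Center relaxation, by an independent root finder."""
        k = KineticsParams().center
        root = brentq(lambda t: float(k.delta(t)), 0.0, 7.0)
        assert 3.0 < root < 4.0

    def test_invalid_tau_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RegionKinetics(0.1, 0.0, 0.0)

    def test_roi_outside_frame_rejected(self):
        roi = EllipseSpec((30.0, 30.0), (80.0, 64.0))
        with pytest.raises(InvalidArgumentError):
            generate_thermal_series(any_subject(), roi, KineticsParams(), seed=1)

    def test_noise_free_regeneration_is_bitwise_identical(self):
        params = KineticsParams().noise_free()
        f1, _ = generate_thermal_series(any_subject(), CENTER_ROI, params, seed=9)
        f2, _ = generate_thermal_series(any_subject(), CENTER_ROI, params, seed=9)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.temperatures, b.temperatures)

    def test_ground_truth_matches_emitted_frames(self):
        frames, truth = generate_thermal_series(
            any_subject(), CENTER_ROI, KineticsParams().noise_free(), seed=1
        )
        masks = rasterize_masks(derive_concentric(CENTER_ROI), (240, 320))
        pre = next(f for f in frames if f.timepoint == "pre")
        for f in frames:
            if f.timepoint == "pre":
                continue
            for name, mask in masks:
                measured = np.median(f.temperatures[mask]) - np.median(pre.temperatures[mask])
                assert measured == pytest.approx(truth.true_region_deltas[name][f.timepoint], abs=0.02)


class TestGenerateErythemaSeries:
    def test_noise_free_group_deltas_match_configured_means(self):
        params = ErythemaGroupParams().noise_free()
        darker = generate_erythema_series(any_subject(7), params, seed=1)
        lighter = generate_erythema_series(any_subject(5), params, seed=1)
        assert darker["m0"] - darker["pre"] == pytest.approx(1.11, abs=1e-9)
        assert lighter["m0"] - lighter["pre"] == pytest.approx(3.80, abs=1e-9)
        deltas = [darker[tp] - darker["pre"] for tp in POST_TIMEPOINTS]
        assert deltas == pytest.approx(list(params.mean_delta["darker"]), abs=1e-9)

    def test_missing_group_parameters_rejected(self):
        params = ErythemaGroupParams(
            mean_delta={"darker": (0.0,) * 8}, sd_delta={"darker": (0.0,) * 8}
        )
        with pytest.raises(ConfigurationError):
            generate_erythema_series(any_subject(5), params, seed=1)


class TestGenerateFiducials:
    def test_identity_no_jitter_gives_equal_points(self):
        fid = generate_fiducials(AffineTransform2D.identity(), [[0, 0], [10, 0], [0, 10]], 0.0)
        assert np.array_equal(fid.optical_points, fid.thermal_points)

    def test_translation_offsets_thermal_points(self):
        t = AffineTransform2D(np.eye(2), [5.0, 3.0])
        fid = generate_fiducials(t, [[0, 0], [10, 0], [0, 10]], 0.0)
        assert np.allclose(fid.thermal_points - fid.optical_points, [5.0, 3.0])

    def test_jittered_fiducials_recover_transform_approximately(self, rng):
        truth = AffineTransform2D(np.array([[0.5, 0.05], [-0.04, 0.52]]), [20.0, 10.0])
        corners = rng.uniform(0, 400, (4, 2))
        fid = generate_fiducials(truth, corners, jitter_sd=0.5, seed=3)
        est, _ = estimate_affine(fid)
        assert np.abs(est.matrix - truth.matrix).max() < 0.05
        assert np.abs(est.offset - truth.offset).max() < 5.0

    def test_noise_free_fiducials_recover_transform_exactly(self):
        truth = AffineTransform2D(np.array([[0.5, 0.02], [0.01, 0.48]]), [12.0, -3.0])
        fid = generate_fiducials(truth, [[0, 0], [100, 0], [100, 80], [0, 80]], 0.0)
        est, rms = estimate_affine(fid)
        assert rms < 1e-9
        assert np.abs(est.matrix - truth.matrix).max() < 1e-9


class TestGenerateStudy:
    def test_noise_free_study_is_reproducible(self):
        kw = dict(
            n_darker=2, n_lighter=1, seed=5,
            kinetics=KineticsParams().noise_free(),
            erythema_params=ErythemaGroupParams().noise_free(),
            render_optical=False,
        )
        s1, s2 = generate_study(**kw), generate_study(**kw)
        assert s1.cohort == s2.cohort
        for a, b in zip(s1.subjects, s2.subjects):
            for fa, fb in zip(a.frames, b.frames):
                assert np.array_equal(fa.temperatures, fb.temperatures)
            assert a.erythema == b.erythema
            assert np.array_equal(a.fiducials.thermal_points, b.fiducials.thermal_points)

    def test_pipeline_recovers_ground_truth_on_noise_free_data(self, noise_free_study, noise_free_results):
        """Every temperature delta within 0.02 °C of truth; erythema deltas exact."""
        table = noise_free_results.cohort_table
        for subject in noise_free_study.subjects:
            truth = subject.ground_truth
            sid = subject.record.subject_id
            for region in REGION_NAMES:
                for tp in POST_TIMEPOINTS:
                    row = table[
                        (table["subject_id"] == sid)
                        & (table["modality"] == "temperature")
                        & (table["region"] == region)
                        & (table["timepoint"] == tp)
                    ]
                    assert abs(row["delta"].iloc[0] - truth.true_region_deltas[region][tp]) <= 0.02
            for tp in POST_TIMEPOINTS:
                row = table[
                    (table["subject_id"] == sid)
                    & (table["modality"] == "erythema")
                    & (table["timepoint"] == tp)
                ]
                assert row["delta"].iloc[0] == pytest.approx(truth.true_erythema_deltas[tp], abs=1e-12)
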
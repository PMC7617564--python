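"""Voxel fitting, masking, and region-aggregation tests.

Round-trip oracles: the synthetic generator produces noise-free series from
known parameters, and the fit must recover them.  The truncation regime is
checked by direct evaluation of the objective (flat in bolus duration beyond
the sampled range).
"""

import dataclasses

import numpy as np
import pytest

from conftest import clean_series
from vsasl.fitting import (
    FitResult,
    MaskSpec,
    VoxelSeries,
    aggregate_subjects,
    build_mask,
    fit_image,
    fit_voxel,
    objective,
    postprocess_fit,
    summarize_regions,
)
from vsasl.model import AcquisitionTiming, TissueParams, model_curve


class TestObjective:
    def test_zero_at_truth(self, gm_truth, exp1_timing, consts):
        series = clean_series(gm_truth, exp1_timing, consts)
        assert objective(gm_truth, series, exp1_timing, consts) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_positive_when_perturbed(self, gm_truth, exp1_timing, consts):
        series = clean_series(gm_truth, exp1_timing, consts)
        off = dataclasses.replace(gm_truth, f=gm_truth.f * 1.05)
        assert objective(off, series, exp1_timing, consts) > 0

    def test_hand_summed_three_point_toy(self, consts):
        # 3 observations, params chosen so the model is the macro term only
        timing = AcquisitionTiming((0.5, 1.0, 1.5), crusher_to_readout=0.0,
                                   slice_delay=0.0, n_slices=1)
        params = TissueParams(f=0.0, bolus_duration=0.0, macro_bv=0.001,
                              macro_bolus_duration=2.0, m0=1000.0)
        amp = 2 * 0.56 * 0.86 * 0.001 * 1000.0
        model = amp * np.exp(-np.array([0.5, 1.0, 1.5]) / 1.6)
        obs = np.array([1.0, 2.0, 3.0])
        series = VoxelSeries(obs, np.array([0.5, 1.0, 1.5]), 0, 1000.0)
        expected = float(np.sum((obs - model) ** 2))
        assert objective(params, series, timing, consts) == pytest.approx(expected)


class TestFitVoxel:
    def test_round_trip_experiment1(self, exp1_timing, consts):
        # macro bolus set on a sampled readout edge so it is point-identified
        truth = TissueParams(f=9.5e-3, bolus_duration=2.20, macro_bv=1e-3,
                             macro_bolus_duration=1.20, m0=1000.0)
        series = clean_series(truth, exp1_timing, consts)
        result = fit_voxel(series, exp1_timing, consts)
        p = result.params
        assert p.f == pytest.approx(truth.f, rel=0.01)
        assert p.bolus_duration == pytest.approx(2.20, rel=0.01)
        assert p.macro_bv == pytest.approx(1e-3, rel=0.01)
        assert p.macro_bolus_duration == pytest.approx(1.20, rel=0.01)
        assert result.converged
        assert not result.boundary_flag

    def test_macro_bolus_is_interval_censored(self, exp1_timing, consts):
        # readout samples at 1.20 and 1.44 s bracket the true edge (1.22 s):
        # every value in [1.20, 1.44) gives identical data, and the estimator
        # reports the smallest equal-sse value, i.e. the covered sample
        truth = TissueParams(f=9.5e-3, bolus_duration=2.20, macro_bv=1e-3,
                             macro_bolus_duration=1.22, m0=1000.0)
        series = clean_series(truth, exp1_timing, consts)
        result = fit_voxel(series, exp1_timing, consts)
        assert result.params.macro_bolus_duration == pytest.approx(1.20, abs=1e-9)
        assert result.sse == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_series(self, exp1_timing, consts):
        series = VoxelSeries(np.zeros(11), np.asarray(exp1_timing.lct_values),
                             0, 1000.0)
        result = fit_voxel(series, exp1_timing, consts)
        assert abs(result.params.f) < 1e-4
        assert abs(result.params.macro_bv) < 1e-4
        assert result.bolus_unidentifiable

    def test_truncated_range_hits_boundary(self, consts, exp2_timing):
        # true bolus outside the sampled range: any tau >= max LCT fits
        # identically, so the canonical estimate is the boundary itself
        truth = TissueParams(f=9.5e-3, bolus_duration=3.0, m0=1000.0)
        series = clean_series(truth, exp2_timing, consts)
        result = fit_voxel(series, exp2_timing, consts)
        assert result.params.bolus_duration == pytest.approx(2.0, rel=1e-3)
        assert result.boundary_flag
        assert result.sse == pytest.approx(0.0, abs=1e-6)

    def test_sse_flat_beyond_max_lct(self, consts, exp2_timing, gm_truth):
        truth = dataclasses.replace(gm_truth, bolus_duration=2.2)
        series = clean_series(truth, exp2_timing, consts)
        base = dataclasses.replace(truth, bolus_duration=2.0)
        values = {
            objective(dataclasses.replace(base, bolus_duration=tau), series,
                      exp2_timing, consts)
            for tau in (2.0, 2.2, 2.5, 3.0, 10.0)
        }
        assert max(values) - min(values) == pytest.approx(0.0, abs=1e-20)

    def test_multi_start_dominance(self, gm_truth, exp1_timing, consts):
        series = clean_series(gm_truth, exp1_timing, consts)
        result = fit_voxel(series, exp1_timing, consts)
        finite = [s for s in result.start_sse if np.isfinite(s)]
        norm_sse = result.sse / gm_truth.m0**2
        assert norm_sse <= min(finite) + 1e-12

    def test_determinism(self, gm_truth, exp1_timing, consts):
        series = clean_series(gm_truth, exp1_timing, consts)
        a = fit_voxel(series, exp1_timing, consts)
        b = fit_voxel(series, exp1_timing, consts)
        assert a.params == b.params
        assert a.sse == b.sse
        assert a.start_used == b.start_used

    def test_too_few_points(self, consts):
        timing = AcquisitionTiming((0.5, 1.0, 1.5, 2.0, 2.5))
        series = VoxelSeries(np.ones(5), np.array([0.5, 1.0, 1.5, 2.0, 2.5]),
                             0, 1.0)
        with pytest.raises(ValueError):
            fit_voxel(series, timing, consts)

    def test_noise_bias_shrinks_with_noise(self, exp1_timing, consts):
        # halving the noise SD must not increase the bolus-duration bias
        truth = TissueParams(f=9.5e-3, bolus_duration=2.2, macro_bv=1e-3,
                             macro_bolus_duration=1.20, m0=1000.0)
        clean = model_curve(truth, exp1_timing, 0, consts)
        lct = np.asarray(exp1_timing.lct_values)
        biases = []
        for sd in (2.0, 1.0):
            rng = np.random.default_rng(7)
            taus = []
            for _ in range(100):
                noisy = clean + rng.normal(0.0, sd, clean.size)
                r = fit_voxel(VoxelSeries(noisy, lct, 0, 1000.0),
                              exp1_timing, consts)
                taus.append(r.params.bolus_duration)
            biases.append(abs(np.mean(taus) - 2.2))
        assert biases[1] <= biases[0] + 0.02  # Monte-Carlo slack


class TestPostprocess:
    def _result(self, **params):
        defaults = dict(f=0.009, bolus_duration=2.0, macro_bv=1e-3,
                        macro_bolus_duration=1.2, m0=1000.0)
        defaults.update(params)
        return FitResult(params=TissueParams(**defaults), sse=0.0,
                         n_starts_converged=1, start_used=0, converged=True)

    def test_negative_f_zeroes_bolus(self):
        out = postprocess_fit(self._result(f=-0.001))
        assert out.params.bolus_duration == 0.0

    def test_nonpositive_macro_bv_zeroes_and_excludes(self):
        out = postprocess_fit(self._result(macro_bv=0.0))
        assert out.params.macro_bolus_duration == 0.0
        assert out.macro_excluded

    def test_all_positive_unchanged(self):
        res = self._result()
        out = postprocess_fit(res)
        assert out.params == res.params
        assert not out.macro_excluded


class TestBuildMask:
    def test_all_true(self):
        gm = np.ones((4, 4, 2))
        m0 = np.full((4, 4, 2), 100.0)
        assert build_mask(gm, m0).all()

    def test_gm_threshold_is_inclusive(self):
        gm = np.array([[[0.49, 0.50, 0.51]]])
        m0 = np.ones((1, 1, 3))
        assert build_mask(gm, m0).tolist() == [[[False, True, True]]]

    def test_m0_fraction_rule(self):
        gm = np.ones((1, 1, 3))
        m0 = np.array([[[1000.0, 501.0, 500.0]]])
        # strictly greater than 50 % of the maximum
        assert build_mask(gm, m0).tolist() == [[[True, True, False]]]

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            build_mask(np.ones((2, 2, 2)), np.ones((2, 2, 3)))

    def test_phantom_bookkeeping(self):
        from vsasl.synthetic import experiment1_preset, make_phantom

        spec, _ = experiment1_preset(grid=(16, 16, 4))
        phantom = make_phantom(spec)
        mask = build_mask(phantom.gm_pve, phantom.m0)
        expected = (phantom.gm_pve >= 0.5) & (
            phantom.m0 > 0.5 * phantom.m0.max()
        )
        assert (mask == expected).all()
        # the low-signal pocket must knock out some high-PVE voxels
        assert ((phantom.gm_pve >= 0.5) & ~mask).sum() > 0


@pytest.fixture(scope="module")
def small_study(consts):
    from vsasl.synthetic import experiment2_preset, simulate_cohort

    spec, timing = experiment2_preset(grid=(12, 12, 3), n_subjects=1,
                                      noise_sd=0.0)
    cohort = simulate_cohort(spec, timing, consts)
    return cohort.subjects[0].images["normocapnia"], timing


class TestFitImage:
    def test_round_trip_maps(self, small_study, consts):
        img, timing = small_study
        mask = build_mask(img.gm_pve, img.m0)
        maps = fit_image(img.dm, img.m0, mask, timing, consts)
        sel = mask
        assert np.nanmax(
            np.abs(maps["bolus_duration"][sel] - img.truth["bolus_duration"][sel])
        ) < 0.02
        rel = np.abs(maps["cbf"][sel] - img.truth["cbf"][sel]) / img.truth["cbf"][sel]
        assert np.nanmax(rel) < 0.01

    def test_nan_outside_mask(self, small_study, consts):
        img, timing = small_study
        mask = build_mask(img.gm_pve, img.m0)
        maps = fit_image(img.dm, img.m0, mask, timing, consts)
        assert np.isnan(maps["cbf"][~mask]).all()
        assert np.isfinite(maps["cbf"][mask]).all()

    def test_grid_mismatch(self, small_study, consts):
        img, timing = small_study
        with pytest.raises(ValueError):
            fit_image(img.dm, img.m0, np.ones((2, 2, 2), bool), timing, consts)


class TestRegions:
    def test_single_region_constant(self, consts):
        from vsasl.synthetic import (
            ParamDist,
            PhantomSpec,
            RegionSpec,
            simulate_cohort,
        )
        from vsasl.model import AcquisitionTiming

        region = RegionSpec(
            name="gm", label=1,
            f=ParamDist(57 / 6000),
            bolus_duration=ParamDist(1.4),
            macro_bv=ParamDist(1e-3),
            macro_bolus_duration=ParamDist(1.0),
        )
        spec = PhantomSpec(regions=(region,), grid=(8, 8, 3), noise_sd=0.0)
        timing = AcquisitionTiming((0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0),
                                   n_slices=3)
        cohort = simulate_cohort(spec, timing, consts)
        img = cohort.subjects[0].images["normocapnia"]
        mask = build_mask(img.gm_pve, img.m0)
        maps = fit_image(img.dm, img.m0, mask, timing, consts)
        stats = summarize_regions(maps, img.atlas, img.region_pve,
                                  img.region_names, mask)
        assert len(stats) == 1
        assert stats[0].n_voxels == int(
            (mask & (img.region_pve[1] >= 0.25)).sum()
        )
        assert stats[0].medians["bolus_duration"] == pytest.approx(1.4, rel=0.01)
        assert stats[0].medians["cbf"] == pytest.approx(57.0, rel=0.01)

    def test_nine_region_round_trip(self, consts):
        from vsasl.synthetic import experiment1_preset, simulate_cohort

        spec, timing = experiment1_preset(grid=(16, 16, 3), n_subjects=1,
                                          noise_sd=0.0)
        cohort = simulate_cohort(spec, timing, consts)
        img = cohort.subjects[0].images["normocapnia"]
        mask = build_mask(img.gm_pve, img.m0)
        maps = fit_image(img.dm, img.m0, mask, timing, consts)
        stats = summarize_regions(maps, img.atlas, img.region_pve,
                                  img.region_names, mask)
        draws = cohort.subjects[0]  # truth via the stored maps
        for s in stats:
            label = next(k for k, v in img.region_names.items() if v == s.region)
            sel = mask & (img.region_pve[label] >= 0.25)
            if not sel.any():
                continue
            true_tau = np.median(img.truth["bolus_duration"][sel])
            assert s.medians["bolus_duration"] == pytest.approx(true_tau, rel=0.01)

    def test_empty_region(self, consts):
        maps = {k: np.full((2, 2, 2), 1.0) for k in
                ("cbf", "bolus_duration", "macro_bv", "macro_bolus_duration",
                 "macro_excluded")}
        atlas = np.ones((2, 2, 2), dtype=int)
        pve = {1: np.full((2, 2, 2), 0.1)}  # below the 25 % threshold
        mask = np.ones((2, 2, 2), bool)
        stats = summarize_regions(maps, atlas, pve, {1: "r1"}, mask)
        assert stats[0].n_voxels == 0
        assert np.isnan(stats[0].medians["cbf"])

    def test_macro_exclusion_respected(self):
        maps = {k: np.full((1, 1, 4), 1.0) for k in
                ("cbf", "bolus_duration", "macro_bv", "macro_bolus_duration")}
        maps["macro_bolus_duration"] = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        maps["macro_excluded"] = np.array([[[1.0, 0.0, 0.0, 1.0]]])
        atlas = np.ones((1, 1, 4), dtype=int)
        pve = {1: np.ones((1, 1, 4))}
        stats = summarize_regions(maps, atlas, pve, {1: "r"},
                                  np.ones((1, 1, 4), bool))
        assert stats[0].medians["macro_bolus_duration"] == pytest.approx(2.5)

    def test_aggregate_subjects_mean_sd(self):
        from vsasl.fitting import RegionStats

        def subj(tau):
            return [RegionStats("r", 5, {"cbf": 50.0, "bolus_duration": tau,
                                         "macro_bv": 1e-3,
                                         "macro_bolus_duration": 1.2})]

        out = aggregate_subjects([subj(2.0), subj(2.2), subj(2.4)])
        assert out[0].group_mean["bolus_duration"] == pytest.approx(2.2)
        assert out[0].group_sd["bolus_duration"] == pytest.approx(0.2)
        assert out[0].n_subjects == 3
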
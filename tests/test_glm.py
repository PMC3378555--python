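"""Concatenated-segment GLM: extraction, design construction, recovery."""

import numpy as np
import pandas as pd
import pytest

from retinowm import glm, roi, synthetic
from retinowm.design import boxcar_on_grid, canonical_hrf
from retinowm.protocol import BoldSeries, EffectSpec, OPPOSITE_QUADRANT, TaskTiming
from tests.conftest import single_trial_table


@pytest.fixture(scope="module")
def quad_map(tiny_sheet):
    return roi.segment_map_from_truth(tiny_sheet, "quadrant")


@pytest.fixture(scope="module")
def ring_map(tiny_sheet):
    return roi.segment_map_from_truth(tiny_sheet, "ring")


class TestExtractSegmentTimecourses:
    def test_single_voxel_segments_pass_through(self, tiny_sheet, quad_map, trials_categorical):
        # restrict to V1: each (quadrant, ring) cell holds exactly one voxel,
        # so a quadrant segment averages 4 voxels; check a 1-voxel map instead
        v1 = tiny_sheet.table[tiny_sheet.table["area"] == "V1"]
        one_per_seg = v1.groupby("quadrant").head(1)
        segmap = roi.SegmentMap(
            mode="quadrant",
            table=pd.DataFrame(
                {"voxel_id": one_per_seg["voxel_id"], "area": "V1",
                 "segment": one_per_seg["quadrant"]}
            ),
        )
        rng = np.random.default_rng(0)
        data = rng.standard_normal((tiny_sheet.n_voxels, 50))
        ser = BoldSeries(data, 1500.0, voxel_ids=tiny_sheet.voxel_ids)
        tcs = glm.extract_segment_timecourses(ser, segmap, "V1")
        for seg in (1, 2, 3, 4):
            vid = int(segmap.table.loc[segmap.table["segment"] == seg, "voxel_id"].iloc[0])
            np.testing.assert_array_equal(tcs.series[seg], data[vid])

    def test_duplicate_voxels_leave_mean_unchanged(self, tiny_sheet, quad_map):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((tiny_sheet.n_voxels, 30))
        ser = BoldSeries(data, 1500.0, voxel_ids=tiny_sheet.voxel_ids)
        tcs = glm.extract_segment_timecourses(ser, quad_map, "V2")
        doubled = roi.SegmentMap(
            mode="quadrant", table=pd.concat([quad_map.table] * 2, ignore_index=True)
        )
        tcs2 = glm.extract_segment_timecourses(ser, doubled, "V2")
        for seg in (1, 2, 3, 4):
            np.testing.assert_allclose(tcs.series[seg], tcs2.series[seg])

    def test_concatenation_is_four_sessions_long(self, tiny_sheet, quad_map):
        ser = BoldSeries(
            np.zeros((tiny_sheet.n_voxels, 123)) + np.arange(123),
            1500.0, voxel_ids=tiny_sheet.voxel_ids,
        )
        tcs = glm.extract_segment_timecourses(ser, quad_map, "V1")
        assert len(tcs.concatenated) == 4 * 123

    def test_empty_segment_error_names_segment(self, tiny_sheet, quad_map):
        ser = BoldSeries(
            np.zeros((tiny_sheet.n_voxels, 10)), 1500.0, voxel_ids=tiny_sheet.voxel_ids
        )
        broken = roi.SegmentMap(
            mode="quadrant", table=quad_map.table[quad_map.table["segment"] != 3]
        )
        with pytest.raises(ValueError, match="segment 3"):
            glm.extract_segment_timecourses(ser, broken, "V1")


def bruteforce_design_columns(trials, T, mode, hrf, include_own_quadrant=False):
    """Independent per-trial placement loop used as the design oracle."""
    timing: TaskTiming = trials.attrs["timing"]
    vol = timing.volume_ms
    cols = {
        name: {s: np.zeros(T) for s in (1, 2, 3, 4)}
        for name in ("delay_match", "delay_mismatch", "s1", "s2", "ecc_mod")
    }
    eccs = list(trials["s1_radius_deg"]) + list(
        trials.loc[trials["trial_type"] != "catch", "s2_radius_deg"]
    )
    ecc_mean = np.mean(eccs)
    for _, t in trials.iterrows():
        catch = t["trial_type"] == "catch"
        if t["instruction"] == "categorical":
            match = OPPOSITE_QUADRANT[t["s1_quadrant"]]
            mism = [q for q in (1, 2, 3, 4)
                    if q != match and (include_own_quadrant or q != t["s1_quadrant"])]
        else:
            match = t["s1_ring"]
            mism = [r for r in (1, 2, 3, 4) if r != match]
        s1_seg = t["s1_quadrant"] if mode == "quadrant" else t["s1_ring"]
        d0 = t["s1_onset_ms"] + timing.stim_ms
        d1 = d0 + timing.median_jitter_ms if catch else t["s2_onset_ms"]
        a, b = int(np.floor(d0 / vol)), int(np.ceil(d1 / vol))
        cols["delay_match"][match][a:b] += 1.0
        for s in mism:
            cols["delay_mismatch"][s][a:b] += 1.0
        i1 = int(np.floor(t["s1_onset_ms"] / vol))
        cols["s1"][s1_seg][i1] += 1.0
        cols["ecc_mod"][s1_seg][i1] += t["s1_radius_deg"] - ecc_mean
        if not catch:
            s2_seg = t["s2_quadrant"] if mode == "quadrant" else t["s2_ring"]
            i2 = int(np.floor(t["s2_onset_ms"] / vol))
            cols["s2"][s2_seg][i2] += 1.0
            cols["ecc_mod"][s2_seg][i2] += t["s2_radius_deg"] - ecc_mean
    out = {}
    for name, blocks in cols.items():
        out[name] = np.concatenate(
            [np.convolve(blocks[s], hrf.samples)[:T] for s in (1, 2, 3, 4)]
        )
    return out


class TestBuildConcatenatedDesign:
    def test_single_trial_delay_support(self):
        trials = single_trial_table("categorical", s1_quadrant=3, s1_ring=2)
        timing = trials.attrs["timing"]
        T = int(np.ceil(trials.attrs["session_ms"] / timing.volume_ms))
        with pytest.warns(UserWarning, match="ecc_mod"):  # single trial centers to zero
            design = glm.build_concatenated_design(trials, T, mode="quadrant")
        col = design.matrix["delay_match"].to_numpy()
        # support entirely inside the block of quadrant 1 (the matching one)
        nz = np.nonzero(col)[0]
        assert len(nz) > 0 and (nz // T == 0).all()
        # support begins right after the S1-offset volume (HRF is 0 at t=0)
        start = int((trials["s1_onset_ms"][0] + timing.stim_ms) // timing.volume_ms)
        assert nz.min() == start + 1

    def test_zero_trials_reduces_to_baseline(self, trials_categorical):
        empty = trials_categorical.iloc[0:0].copy()
        empty.attrs = dict(trials_categorical.attrs)
        with pytest.warns(UserWarning, match="all-zero"):
            design = glm.build_concatenated_design(empty, 100, mode="quadrant")
        assert all(c.startswith(("const_", "dct_")) for c in design.matrix.columns)

    @pytest.mark.parametrize(
        "which,mode",
        [("categorical", "quadrant"), ("coordinate", "ring")],
    )
    def test_full_session_matches_bruteforce_oracle(
        self, which, mode, trials_categorical, trials_coordinate
    ):
        trials = trials_categorical if which == "categorical" else trials_coordinate
        timing = trials.attrs["timing"]
        T = int(np.ceil(trials.attrs["session_ms"] / timing.volume_ms))
        hrf = canonical_hrf(timing.volume_ms)
        design = glm.build_concatenated_design(trials, T, mode=mode, hrf=hrf)
        oracle = bruteforce_design_columns(trials, T, mode, hrf)
        for name, expect in oracle.items():
            np.testing.assert_allclose(
                design.matrix[name].to_numpy(), expect, atol=1e-10, err_msg=name
            )

    def test_mode_instruction_mismatch_rejected(self, trials_categorical):
        with pytest.raises(ValueError, match="mode"):
            glm.build_concatenated_design(trials_categorical, 100, mode="ring")

    def test_overlapping_trials_rejected(self, trials_categorical):
        shuffled = trials_categorical.iloc[::-1].reset_index(drop=True)
        shuffled.attrs = dict(trials_categorical.attrs)
        with pytest.raises(ValueError, match="overlap"):
            glm.build_concatenated_design(shuffled, 100, mode="quadrant")


class TestFitGlm:
    @pytest.mark.parametrize("instruction", ["categorical", "coordinate"])
    @pytest.mark.parametrize("area", ["V1", "V3"])
    def test_noiseless_exact_recovery_all_factors(
        self, tiny_sheet, quad_map, ring_map, positions, instruction, area
    ):
        """Injected amplitudes recovered to ≤1e-6 relative error without noise.

        With one voxel per (quadrant, ring) cell, a stimulus excites 1/4 of
        its segment's voxels, so stimulus betas recover amp/4 exactly while
        the delay betas recover their amplitudes directly.
        """
        trials = synthetic.generate_trial_sequence(instruction, positions, seed=3)
        eff = EffectSpec(amp_s1=0.8, amp_s2=1.2, delay_match_amp=0.5, delay_mismatch_amp=0.2)
        ser = synthetic.simulate_task_series(tiny_sheet, trials, eff, seed=0)
        segmap = quad_map if instruction == "categorical" else ring_map
        tcs = glm.extract_segment_timecourses(ser, segmap, area)
        design = glm.build_concatenated_design(trials, tcs.T, mode=segmap.mode)
        fit = glm.fit_glm(tcs, design)
        assert fit.betas["delay_match"] == pytest.approx(0.5, rel=1e-6)
        assert fit.betas["delay_mismatch"] == pytest.approx(0.2, rel=1e-6)
        assert fit.betas["s1"] == pytest.approx(0.8 / 4, rel=1e-6)
        assert fit.betas["s2"] == pytest.approx(1.2 / 4, rel=1e-6)
        assert abs(fit.betas["ecc_mod"]) < 1e-9

    def test_equal_amplitudes_give_null_difference_under_noise(
        self, protocol, positions, quad_map
    ):
        sheet = synthetic.generate_voxel_sheet(16, protocol, seed=3, noise_sd=1.0)
        trials = synthetic.generate_trial_sequence("categorical", positions, seed=5)
        eff = EffectSpec(delay_match_amp=0.4, delay_mismatch_amp=0.4)
        ser = synthetic.simulate_task_series(sheet, trials, eff, seed=11)
        db = glm.delay_betas(ser, quad_map, trials, "V2")
        diff = db.loc[0, "beta"] - db.loc[1, "beta"]
        se = np.hypot(db.loc[0, "se"], db.loc[1, "se"])
        assert abs(diff) < 3 * se

    def test_noisy_recovery_unbiased(self, protocol, positions, quad_map):
        """Monte-Carlo: delay-beta estimates unbiased (mean error < 5% of
        the injected amplitude) at the default noise level."""
        sheet = synthetic.generate_voxel_sheet(16, protocol, seed=3)
        trials = synthetic.generate_trial_sequence("categorical", positions, seed=5)
        eff = EffectSpec(delay_match_amp=0.5, delay_mismatch_amp=0.2)
        timing = trials.attrs["timing"]
        T = synthetic.session_volumes(trials)
        design = glm.build_concatenated_design(trials, T, mode="quadrant")
        est = []
        for rep in range(150):
            ser = synthetic.simulate_task_series(sheet, trials, eff, seed=1000 + rep)
            tcs = glm.extract_segment_timecourses(ser, quad_map, "V3")
            fit = glm.fit_glm(tcs, design)
            est.append((fit.betas["delay_match"], fit.betas["delay_mismatch"]))
        est = np.array(est)
        assert abs(est[:, 0].mean() - 0.5) < 0.05 * 0.5
        assert abs(est[:, 1].mean() - 0.2) < 0.05 * 0.5
        # noise in the betas scales with the injected noise level
        assert est[:, 0].std() > 0

    def test_rank_deficiency_reported(self, tiny_sheet, quad_map, trials_categorical):
        T = synthetic.session_volumes(trials_categorical)
        design = glm.build_concatenated_design(trials_categorical, T, mode="quadrant")
        design.matrix["dup"] = design.matrix["s1"]
        ser = BoldSeries(
            np.zeros((tiny_sheet.n_voxels, T)) + 1e-3 * np.arange(T),
            trials_categorical.attrs["timing"].volume_ms,
            voxel_ids=tiny_sheet.voxel_ids,
        )
        tcs = glm.extract_segment_timecourses(ser, quad_map, "V1")
        with pytest.raises(ValueError, match="dup"):
            glm.fit_glm(tcs, design)


class TestStimulusBetas:
    def test_all_match_session_drops_empty_column(self, tiny_sheet, quad_map, trials_categorical):
        only_match = trials_categorical[trials_categorical["trial_type"] == "match"].copy()
        only_match.attrs = dict(trials_categorical.attrs)
        ser = synthetic.simulate_task_series(tiny_sheet, only_match, EffectSpec(), seed=0)
        with pytest.warns(UserWarning, match="s2_mismatch"):
            out = glm.stimulus_betas(ser, quad_map, only_match, "V1")
        assert set(out["factor"]) == {"s1", "s2_match"}

    def test_equal_s2_amplitude_null_split(self, protocol, positions, quad_map):
        sheet = synthetic.generate_voxel_sheet(16, protocol, seed=3, noise_sd=1.0)
        trials = synthetic.generate_trial_sequence("categorical", positions, seed=9)
        ser = synthetic.simulate_task_series(sheet, trials, EffectSpec(amp_s2=1.0), seed=21)
        out = glm.stimulus_betas(ser, quad_map, trials, "V2").set_index("factor")
        diff = out.loc["s2_match", "beta"] - out.loc["s2_mismatch", "beta"]
        se = np.hypot(out.loc["s2_match", "se"], out.loc["s2_mismatch", "se"])
        assert abs(diff) < 3 * se

    def test_s2_beta_linear_in_amplitude(self, tiny_sheet, quad_map, trials_categorical):
        betas = []
        for amp in (0.5, 1.0):
            ser = synthetic.simulate_task_series(
                tiny_sheet, trials_categorical, EffectSpec(amp_s2=amp), seed=0
            )
            out = glm.stimulus_betas(ser, quad_map, trials_categorical, "V1").set_index("factor")
            betas.append(out.loc["s2_match", "beta"])
        assert betas[1] == pytest.approx(2 * betas[0], rel=1e-6)


class TestContrastActivation:
    def test_noiseless_contrast_equals_cell_fraction(self, tiny_sheet, quad_map, trials_categorical):
        """Response confined to the stimulus cell: contrast = amp × 1/4
        under the even one-voxel-per-cell tiling."""
        ser = synthetic.simulate_task_series(
            tiny_sheet, trials_categorical, EffectSpec(amp_s1=1.0, amp_s2=1.0), seed=0
        )
        c = glm.contrast_activation(ser, quad_map, trials_categorical, "V1")
        assert c == pytest.approx(0.25, rel=1e-6)

    def test_uniform_response_gives_zero_contrast(
        self, tiny_sheet, ring_map, trials_coordinate
    ):
        """A stimulus response shared by every voxel carries no spatial
        information, so present-minus-absent is zero."""
        ser = synthetic.simulate_task_series(
            tiny_sheet, trials_coordinate, EffectSpec(amp_s1=1.0, amp_s2=1.0), seed=0
        )
        ser.data[:] = ser.data.mean(axis=0)  # flatten spatially
        c = glm.contrast_activation(ser, ring_map, trials_coordinate, "V1")
        assert abs(c) < 1e-8
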
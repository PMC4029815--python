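"""Synthetic-subject generator: atlas, run signal model, learning loop."""

import numpy as np
import pytest

from affectloop import decoder as dec
from affectloop.design import Condition, label_volumes, make_default_design
from affectloop.preproc import VolumeStream
from affectloop.simulate import (
    AcquisitionGrid,
    ConfigError,
    SubjectState,
    BASELINE_SIGNAL,
    make_atlas,
    simulate_cohort,
    simulate_run,
    simulate_subject,
    update_state,
)
from affectloop.stats import Group


def _short_design(tr=2.0):
    """Two emotional pairs, shortened blocks: fast but structurally complete."""
    return make_default_design(
        Condition.TENDERNESS,
        n_emotional_pairs=2,
        emotional_volumes=10,
        neutral_volumes=6,
        tr_seconds=tr,
    )


class TestAtlas:
    def test_patterns_disjoint_and_inside_mask(self, small_atlas):
        t = small_atlas.tenderness_pattern > 0
        p = small_atlas.pride_pattern > 0
        assert not (t & p).any()
        assert np.all(small_atlas.feature_mask[t])
        assert np.all(small_atlas.feature_mask[p])

    def test_mask_strictly_between_patterns_and_grid(self, small_atlas):
        n_mask = small_atlas.feature_mask.sum()
        for pat in (small_atlas.tenderness_pattern, small_atlas.pride_pattern):
            assert (pat > 0).sum() < n_mask
        assert n_mask < small_atlas.grid.n_voxels

    def test_svc_roi_overlaps_tenderness_pattern(self, small_atlas):
        assert small_atlas.svc_roi.any()
        assert (small_atlas.svc_roi & (small_atlas.tenderness_pattern > 0)).any()

    def test_seed_determinism(self, small_grid):
        a = make_atlas(small_grid, seed=3)
        b = make_atlas(small_grid, seed=3)
        np.testing.assert_array_equal(a.tenderness_pattern, b.tenderness_pattern)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ConfigError):
            AcquisitionGrid(dims=(3, 24, 12))


class TestSimulateRun:
    def test_degenerate_run_is_baseline_plus_drift(self, small_atlas):
        design = _short_design()
        state = SubjectState(
            amp_tenderness=0.0, amp_pride=0.0, noise_sd=1e-12, drift_slope=0.5
        )
        series = simulate_run(state, small_atlas, design)
        t = np.arange(design.n_volumes)
        expected = BASELINE_SIGNAL + 0.5 * t
        got = series.data[:, 0, 0, 0]
        np.testing.assert_allclose(got, expected, atol=1e-6)
        # spatially constant at every time point
        assert np.allclose(series.data, got[:, None, None, None], atol=1e-6)

    def test_neutral_blocks_carry_no_condition_signal(self, small_atlas):
        design = _short_design()
        state = SubjectState(
            amp_tenderness=5.0, amp_pride=5.0, noise_sd=1e-12, drift_slope=0.0
        )
        series = simulate_run(state, small_atlas, design)
        # first neutral block precedes any emotional block: pure baseline
        pattern_voxel = tuple(np.argwhere(small_atlas.tenderness_pattern > 0)[0])
        first_block = series.data[(slice(0, 6),) + pattern_voxel]
        np.testing.assert_allclose(first_block, BASELINE_SIGNAL, atol=1e-6)

    def test_noise_free_run_decodes_perfectly(self, small_atlas):
        """End-to-end: decoder trained on a clean run classifies it 100%."""
        design = _short_design()
        labels = label_volumes(design)
        state = SubjectState(amp_tenderness=1.0, amp_pride=1.0, noise_sd=1e-9)
        series = simulate_run(state, small_atlas, design)
        stream = VolumeStream(labels, small_atlas.feature_mask, small_atlas.grid.voxel_size_mm)
        feats = [fv for t in range(design.n_volumes) if (fv := stream.push(series.data[t]))]
        d = dec.train_from_run(feats)
        assert all(d.classify(fv) is fv.condition for fv in feats)

    def test_lag_one_autocorrelation_matches_phi(self, small_atlas):
        design = make_default_design()  # long run for a stable estimate
        for phi in (0.0, 0.5):
            state = SubjectState(
                amp_tenderness=0.0, amp_pride=0.0, drift_slope=0.0,
                noise_sd=2.0, ar_coeff=phi, rng_seed=9,
            )
            series = simulate_run(state, small_atlas, design)
            x = series.data[:, :4, 0, 0] - BASELINE_SIGNAL
            r1 = np.mean([
                np.corrcoef(x[:-1, i], x[1:, i])[0, 1] for i in range(4)
            ])
            assert r1 == pytest.approx(phi, abs=0.12)

    def test_seed_determinism(self, small_atlas):
        design = _short_design()
        state = SubjectState(rng_seed=21)
        a = simulate_run(state, small_atlas, design)
        b = simulate_run(state, small_atlas, design)
        np.testing.assert_array_equal(a.data, b.data)

    def test_feedback_stream_length_validated(self, small_atlas):
        design = _short_design()
        with pytest.raises(ConfigError):
            simulate_run(SubjectState(), small_atlas, design, feedback_stream=[1, 2, 3])


class TestUpdateState:
    def test_zero_learning_rate_is_identity(self):
        s = SubjectState(learning_rate=0.0)
        assert update_state(s, 20.0, contingent=True) == s

    def test_non_contingent_never_updates(self):
        s = SubjectState(learning_rate=2.0, group=Group.CTR)
        assert update_state(s, 20.0, contingent=False) == s

    def test_plug_in_update_rule(self):
        s = SubjectState(amp_tenderness=1.0, learning_rate=0.5)
        out = update_state(s, 20.0, contingent=True)
        assert out.amp_tenderness == pytest.approx(1.5)

    def test_amplitude_floored_at_zero(self):
        s = SubjectState(amp_tenderness=0.1, learning_rate=5.0)
        out = update_state(s, 1.0, contingent=True)
        assert out.amp_tenderness == 0.0

    def test_level_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            update_state(SubjectState(), 25.0, contingent=True)


class TestClosedLoop:
    def test_feedback_logs_reproducible_from_seed(self, small_atlas):
        kwargs = dict(n_per_group=1, n_runs=2, seed=4, atlas=small_atlas)
        a = simulate_cohort(**kwargs)
        b = simulate_cohort(**kwargs)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            for sa, sb in zip(ra.sessions, rb.sessions):
                assert sa.frames.equals(sb.frames)

    def test_ctr_frames_non_contingent_and_state_frozen(self, small_atlas):
        records = simulate_cohort(n_per_group=1, n_runs=3, seed=8, atlas=small_atlas)
        ctr = next(r for r in records if r.group is Group.CTR)
        for sess in ctr.sessions:
            assert (sess.frames["contingent"] == 0).all()
        assert ctr.final_state.amp_tenderness == pytest.approx(
            SubjectState().amp_tenderness
        )

    def test_nfb_frames_contingent(self, small_atlas):
        records = simulate_cohort(n_per_group=1, n_runs=2, seed=8, atlas=small_atlas)
        nfb = next(r for r in records if r.group is Group.NFB)
        assert (nfb.sessions[0].frames["contingent"] == 1).all()

    def test_zero_learning_rate_groups_indistinguishable(self, small_atlas):
        """With eta = 0 in both groups, last-minus-first accuracy changes
        should not differ systematically between NFB and CTR."""
        from scipy import stats as sps

        nfb_deltas, ctr_deltas = [], []
        for seed in range(20):
            records = simulate_cohort(
                n_per_group=1, n_runs=3, seed=seed, atlas=small_atlas,
                nfb_learning_rate=0.0,
            )
            for r in records:
                delta = r.outcome.delta_last_first
                (nfb_deltas if r.group is Group.NFB else ctr_deltas).append(delta)
        t, _ = sps.ttest_ind(nfb_deltas, ctr_deltas)
        assert abs(t) < 2.5

    def test_learning_monotone_under_accurate_decoding(self, small_atlas):
        """A subject decoded well (low noise) with eta > 0 never loses
        tenderness amplitude across the closed loop."""
        state = SubjectState(noise_sd=2.0, learning_rate=1.0, rng_seed=13)
        rec = simulate_subject(state, small_atlas, n_runs=4)
        assert rec.final_state.amp_tenderness >= state.amp_tenderness

    def test_minimum_two_runs_required(self, small_atlas):
        with pytest.raises(ConfigError):
            simulate_cohort(n_per_group=1, n_runs=1, seed=0, atlas=small_atlas)
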
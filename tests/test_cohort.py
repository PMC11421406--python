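"""Synthetic cohort: design, listener draws, block simulation, missingness."""

import numpy as np
import pandas as pd
import pytest

from speechresp import (CohortConfig, MissingnessPlan, TIME_RESOLUTION_S,
                        build_design, calibrate_residual_sd, design_cells,
                        draw_listener, generate_latent_cells, inject_missingness,
                        presentation_level, simulate_alignment, simulate_block,
                        simulate_cohort)
from speechresp.cohort import (DEFAULT_MASKERS, FLUCTUATING, STATIONARY,
                               STUDY_MODELS, _psychometric_p)


class TestBuildDesign:
    def test_full_study_is_6075_trials(self):
        d = build_design(15, 12, DEFAULT_MASKERS, (0, 3, 6, 9, 12), 5, seed=1)
        assert len(d) == 6075
        assert d.groupby("listener_id")["block_id"].nunique().eq(45).all()

    def test_single_block(self):
        d = build_design(1, 0, {"OLnoise": 2}, (0,), 5, seed=1)
        assert len(d) == 5

    def test_cardinality_product(self):
        d = build_design(2, 2, {"OLnoise": 2, "ISTS": 1}, (0, 3, 6, 9, 12), 5, seed=7)
        assert len(d) == 4 * 2 * 5 * 5

    def test_group_and_type_coding(self):
        d = build_design(1, 1, DEFAULT_MASKERS, (0,), 5, seed=2)
        assert set(d["group"]) == {1, 2}
        assert set(d.loc[d["masker_id"] == "OLnoise", "masker_type"]) == {2}
        assert set(d.loc[d["masker_id"] == "ISTS", "masker_type"]) == {1}

    def test_sentences_come_from_the_matrix(self):
        from speechresp import DEFAULT_VOCABULARY
        d = build_design(1, 0, {"OLnoise": 2}, (0,), 5, seed=3)
        for s in d["sentence"]:
            words = s.split()
            assert len(words) == 5
            assert all(DEFAULT_VOCABULARY.slot_of(w) == i
                       for i, w in enumerate(words))

    def test_errors(self):
        with pytest.raises(ValueError):
            build_design(1, 0, {}, (0,), 5, seed=1)
        with pytest.raises(ValueError):
            build_design(0, 0, {"OLnoise": 2}, (0,), 5, seed=1)

    def test_deterministic_under_seed(self):
        a = build_design(2, 1, DEFAULT_MASKERS, (0, 3), 5, seed=9)
        b = build_design(2, 1, DEFAULT_MASKERS, (0, 3), 5, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestDrawListener:
    def test_stationary_srt_means_match_group_defaults(self):
        cfg = CohortConfig(between_listener_srt_sd=0.0, per_masker_srt_jitter_sd=0.0)
        nh = draw_listener("NH", seed=1, config=cfg)
        hi = draw_listener("HI", seed=2, config=cfg)
        assert nh.srt_per_masker["OLnoise"] == pytest.approx(-7.5)
        assert nh.srt_per_masker["IFnoise"] == pytest.approx(-8.5)
        assert hi.srt_per_masker["OLnoise"] == pytest.approx(-5.1)
        assert hi.srt_per_masker["IFnoise"] == pytest.approx(-5.5)

    def test_release_from_masking_for_every_listener(self):
        for seed in range(20):
            for group in ("NH", "HI"):
                lst = draw_listener(group, seed=seed)
                stat = [v for m, v in lst.srt_per_masker.items()
                        if DEFAULT_MASKERS[m] == STATIONARY]
                fluct = [v for m, v in lst.srt_per_masker.items()
                         if DEFAULT_MASKERS[m] == FLUCTUATING]
                assert min(stat) > max(fluct)

    def test_fluctuating_reduction_defaults(self):
        cfg = CohortConfig(between_listener_srt_sd=0.0, per_masker_srt_jitter_sd=0.0)
        nh = draw_listener("NH", seed=3, config=cfg)
        assert nh.srt_per_masker["ISTS"] == pytest.approx(-8.0 - 12.0)
        hi = draw_listener("HI", seed=3, config=cfg)
        assert hi.srt_per_masker["ISTS"] == pytest.approx(-5.3 - 6.0)

    def test_degenerate_draw_identical_listeners(self):
        cfg = CohortConfig(between_listener_srt_sd=0.0, per_masker_srt_jitter_sd=0.0)
        a = draw_listener("NH", seed=1, config=cfg)
        b = draw_listener("NH", seed=99, config=cfg)
        assert a.srt_per_masker == pytest.approx(b.srt_per_masker)

    def test_thresholds_ordered_and_slopes_steeper_for_stationary(self):
        lst = draw_listener("NH", seed=4)
        assert np.all(np.diff(lst.srle_thresholds) > 0)
        assert lst.slope_per_type[STATIONARY] > lst.slope_per_type[FLUCTUATING]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            draw_listener("XX", seed=1)


class TestPresentationLevel:
    @pytest.mark.parametrize("hl, expected", [(0, 65.0), (20, 75.0), (40, 80.0)])
    def test_values(self, hl, expected):
        assert presentation_level(hl) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            presentation_level(-5)


class TestSimulateBlock:
    def _trials(self, mtype, snr, group=1):
        return pd.DataFrame({"masker_type": [mtype] * 5, "snr_re_srt": [snr] * 5,
                             "group": [group] * 5})

    def test_half_correct_at_srt(self):
        """At SNR re SRT = 0 the expected word-correct proportion is 0.5."""
        lst = draw_listener("NH", seed=5)
        total, n = 0, 0
        for s in range(200):
            corr, *_ = simulate_block(lst, self._trials(STATIONARY, 0.0), "psychometric", s)
            total += sum(c.sum() for c in corr)
            n += 25
        assert total / n == pytest.approx(0.5, abs=0.03)

    def test_near_ceiling_at_plus_12(self):
        lst = draw_listener("NH", seed=5)
        total, n = 0, 0
        for s in range(50):
            corr, *_ = simulate_block(lst, self._trials(STATIONARY, 12.0), "psychometric", s)
            total += sum(c.sum() for c in corr)
            n += 25
        assert total / n > 0.99

    def test_psychometric_monotone_in_snr(self):
        p = [_psychometric_p(s, 0.15) for s in (-6, -3, 0, 3, 6, 9, 12)]
        assert np.all(np.diff(p) > 0)
        assert _psychometric_p(0.0, 0.15) == 0.5

    def test_latent_linear_noiseless_equals_predictor(self):
        cfg = CohortConfig(score_residual_sd=0.0, srle_residual_sd=0.0,
                           vrt_residual_sd=0.0, rsr_residual_sd=0.0,
                           vrt_pace_sd=0.0, rsr_pace_sd=0.0,
                           srle_threshold_shift_sd=0.0)
        lst = draw_listener("NH", seed=6, config=cfg)
        corr, srle, vrts, rsrs = simulate_block(
            lst, self._trials(STATIONARY, 3.0), "latent_linear", seed=0, config=cfg)
        # block score = 50 + 4*3 + 13*1 - 0 = 75% -> 18.75 of 25 words -> 19
        assert sum(c.sum() for c in corr) == round(0.75 * 25)
        assert len(set(np.round(vrts, 12))) == 1  # no residual: identical
        assert len(set(np.round(rsrs, 12))) == 1

    def test_unknown_mode_rejected(self):
        lst = draw_listener("NH", seed=7)
        with pytest.raises(ValueError):
            simulate_block(lst, self._trials(1, 0.0), "nope", seed=0)


class TestSimulateAlignment:
    def test_token_count_onset_and_span(self):
        ali = simulate_alignment("Peter sieht zwei alte Autos", 5, 0.45, 2.0,
                                 seed=1, sentence_end_s=2.0)
        assert ali.n_tokens == 5
        assert ali.first_onset_s == pytest.approx(2.45, abs=TIME_RESOLUTION_S)
        span = ali.last_end_s - ali.first_onset_s
        assert span == pytest.approx(2.5, abs=TIME_RESOLUTION_S)

    def test_all_times_on_the_30ms_grid(self):
        ali = simulate_alignment("Peter sieht zwei alte Autos", 4, 0.617, 2.3,
                                 seed=2, sentence_end_s=2.71)
        for _, onset, dur in ali.tokens:
            assert (onset / TIME_RESOLUTION_S) == pytest.approx(
                round(onset / TIME_RESOLUTION_S), abs=1e-6)
            assert (dur / TIME_RESOLUTION_S) == pytest.approx(
                round(dur / TIME_RESOLUTION_S), abs=1e-6)

    def test_no_response_trial(self):
        cfg = CohortConfig(substitution_rate=0.0)
        ali = simulate_alignment("Peter sieht zwei alte Autos", 0, 0.5, 2.0,
                                 seed=3, config=cfg, sentence_end_s=2.0)
        assert ali.n_tokens == 0

    def test_negative_vrt_starts_before_sentence_end(self):
        ali = simulate_alignment("Peter sieht zwei alte Autos", 5, -0.12, 2.0,
                                 seed=4, sentence_end_s=2.0)
        assert ali.first_onset_s < 2.0
        assert ali.first_onset_s == pytest.approx(1.88, abs=TIME_RESOLUTION_S)

    def test_nonpositive_rsr_rejected(self):
        with pytest.raises(ValueError):
            simulate_alignment("Peter sieht zwei alte Autos", 5, 0.5, 0.0,
                               seed=5, sentence_end_s=2.0)


class TestCohortAndMissingness:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_cohort(small_config, seed=42)
        b = simulate_cohort(small_config, seed=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.ratings, b.ratings)
        assert [x.tokens for x in a.alignments] == [x.tokens for x in b.alignments]

    def test_missingness_counts(self, small_cohort):
        plan = MissingnessPlan(1, 2, 3, 1)
        out = inject_missingness(small_cohort, plan, seed=0)
        assert (~out.trials["recorded"]).sum() == 1
        assert (~out.trials["complete"]).sum() == plan.total
        assert len(out.trials) - out.n_complete == 7

    def test_zero_plan_is_identity(self, small_cohort):
        out = inject_missingness(small_cohort, MissingnessPlan(0, 0, 0, 0), seed=0)
        assert out.n_complete == len(out.trials)

    def test_unrecorded_only_removes_asr_channel(self, small_cohort):
        out = inject_missingness(small_cohort, MissingnessPlan(1, 0, 0, 0), seed=3)
        key_cols = ["listener_id", "block_id", "sentence_index"]
        missing = out.trials.loc[~out.trials["recorded"], key_cols].iloc[0]
        key = (missing["listener_id"], int(missing["block_id"]),
               int(missing["sentence_index"]))
        ali = {a.trial_key: a for a in out.alignments}[key]
        assert ali.n_tokens == 0
        manual = out.manual_scores.set_index(key_cols)["n_correct"]
        assert not np.isnan(manual.loc[key])  # examiner score retained

    def test_plan_larger_than_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            inject_missingness(small_cohort, MissingnessPlan(300, 0, 0, 0), seed=0)


class TestLatentLinearCells:
    def test_design_cells_cardinality(self):
        cells = design_cells()
        assert len(cells) == 270
        assert cells["group"].value_counts().to_dict() == {1: 150, 2: 120}

    def test_calibration_matches_target_r2(self):
        """The calibrated residual SD reproduces the target R² (brute-force
        variance oracle: R² = Var(lp) / (Var(lp) + sigma²))."""
        m = STUDY_MODELS["a"]
        cells = design_cells()
        lp = m.intercept + sum(v * cells[k] for k, v in m.coefficients.items())
        sd = calibrate_residual_sd(lp, m.adj_r2)
        r2 = lp.var(ddof=0) / (lp.var(ddof=0) + sd ** 2)
        assert r2 == pytest.approx(m.adj_r2, abs=1e-12)

    def test_calibration_matches_printed_se(self):
        """The printed coefficient SEs follow from the calibrated noise:
        an independent consistency check of the generating conditions."""
        m = STUDY_MODELS["a"]
        cells = design_cells()
        lp = m.intercept + sum(v * cells[k] for k, v in m.coefficients.items())
        sd = calibrate_residual_sd(lp, m.adj_r2)
        se_snr = sd / np.sqrt(len(cells) * cells["snr_re_srt"].var(ddof=0))
        assert se_snr == pytest.approx(0.157, abs=0.01)

    def test_noiseless_cells_equal_predictor(self):
        m = STUDY_MODELS["b"]
        cells = generate_latent_cells("b", seed=0, residual_sd=0.0)
        lp = m.intercept + sum(v * cells[k] for k, v in m.coefficients.items())
        assert cells[m.response].to_numpy() == pytest.approx(lp.to_numpy())
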
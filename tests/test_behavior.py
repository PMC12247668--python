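import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvcseq import CohortSpec, generate_cellcounts, generate_cohort
from hvcseq import behavior as bh
from hvcseq.params import ParameterError
from hvcseq.synth import DEFAULT_CONTROL_RATIOS


def trial(**over):
    base = dict(
        bird_id="b0", motif_duration_ms=700.0, stim_onset_ms=150.0,
        truncated=True, truncation_latency_ms=66.55, category="motif_reset",
        restart_latency_ms=120.0, context="within_motif",
    )
    base.update(over)
    return base


class TestValidateTruncation:
    @pytest.mark.parametrize(
        "latency,expected",
        [(66.55, True), (300.0, True), (300.1, False)],
    )
    def test_stimulation_contingency_rule(self, latency, expected):
        assert bh.validate_truncation(trial(truncation_latency_ms=latency)) is expected

    def test_untruncated_trial_always_false(self):
        assert bh.validate_truncation(trial(truncated=False, truncation_latency_ms=10.0)) is False

    def test_missing_latency_is_schema_error(self):
        with pytest.raises(bh.SchemaError):
            bh.validate_truncation(trial(truncation_latency_ms=float("nan")))


class TestAdvancementBin:
    def test_quarter_of_motif(self):
        # 150 / (700 - 100) = 25%
        assert bh.advancement_bin(trial(), 150.0) == (20, 30)

    def test_zero_advancement(self):
        assert bh.advancement_bin(trial(), 0.0) == (0, 10)

    def test_full_span_closes_last_bin(self):
        assert bh.advancement_bin(trial(), 600.0) == (90, 100)

    def test_last_100ms_maps_to_negative_bins(self):
        b = bh.advancement_bin(trial(context="last_100ms"), 650.0)
        assert b in ((-20, -10), (-10, 0))

    def test_intro_event_by_distance_to_syllable_a(self):
        b = bh.advancement_bin(trial(context="intro_or_connector"), -80.0)
        assert b == (-20, -10)  # 80/600 = 13.3% before syllable A

    def test_intro_event_without_reference_excluded(self):
        assert bh.advancement_bin(trial(context="intro_or_connector"), float("nan")) is None

    def test_far_pre_motif_event_excluded(self):
        assert bh.advancement_bin(trial(context="intro_or_connector"), -300.0) is None

    def test_negative_time_without_context_rejected(self):
        with pytest.raises(bh.SchemaError):
            bh.advancement_bin(trial(), -5.0)

    def test_short_motif_rejected(self):
        with pytest.raises(ParameterError):
            bh.advancement_bin(trial(motif_duration_ms=90.0), 10.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        onset=st.floats(0.0, 699.9),
        motif=st.floats(200.0, 1200.0),
    )
    def test_every_in_motif_event_lands_in_exactly_one_bin(self, onset, motif):
        if onset >= motif:
            onset = motif * 0.5
        b = bh.advancement_bin(trial(motif_duration_ms=motif), onset)
        if b is None:
            # only possible when the event sits in the last 100 ms of a
            # short motif, where that span exceeds the -20% region
            assert onset > motif - 100.0
            assert (motif - onset) / (motif - 100.0) > 0.2
        else:
            lo, hi = b
            assert hi - lo == 10
            assert -20 <= lo < 100


class TestNormalizedReset:
    def test_half_with_two_motifs_per_bout(self):
        assert bh.normalized_reset_probability(0.5, 2.0) == 1.0

    def test_hand_computed_value(self):
        # 0.6916 / (1 - 1/3.2) = 0.6916 / 0.6875
        assert bh.normalized_reset_probability(0.6916, 3.2) == pytest.approx(
            0.6916 / 0.6875, rel=1e-12
        )

    def test_zero_numerator(self):
        assert bh.normalized_reset_probability(0.0, 5.0) == 0.0

    def test_large_M_limit_approaches_raw(self):
        assert bh.normalized_reset_probability(0.8, 1e9) == pytest.approx(0.8, rel=1e-8)

    def test_M_at_or_below_one_rejected(self):
        with pytest.raises(ParameterError):
            bh.normalized_reset_probability(0.5, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(raw=st.floats(0.01, 1.0), m1=st.floats(1.1, 10.0), m2=st.floats(1.1, 10.0))
    def test_monotone_in_M(self, raw, m1, m2):
        lo, hi = sorted((m1, m2))
        if hi - lo < 1e-9:
            return
        assert bh.normalized_reset_probability(raw, lo) > bh.normalized_reset_probability(raw, hi)


class TestResetRecovery:
    def test_recovers_generator_truth_within_binomial_ci(self):
        spec = CohortSpec(n_birds=1, trials_per_bird=500, p_truncation=1.0,
                         category_probs=(0.7, 0.1, 0.05, 0.1, 0.05), seed=3)
        trials, bouts, _ = generate_cohort(spec)
        per_bird, _ = bh.reset_probability_from_trials(trials, bouts)
        n = per_bird.n_truncations.iloc[0]
        half = 1.96 * math.sqrt(0.7 * 0.3 / n)
        assert abs(per_bird.raw.iloc[0] - 0.7) < half + 1e-9 or (
            per_bird.raw_wilson_low.iloc[0] <= 0.7 <= per_bird.raw_wilson_high.iloc[0]
        )

    def test_no_truncations_is_error(self):
        spec = CohortSpec(n_birds=1, trials_per_bird=20, p_truncation=0.0, seed=0)
        trials, bouts, _ = generate_cohort(spec)
        with pytest.raises(ValueError, match="no validated truncations"):
            bh.reset_probability_from_trials(trials, bouts)

    def test_category_fractions_sum_to_one(self):
        trials, _, _ = generate_cohort(CohortSpec(seed=5))
        frac = bh.category_fractions(trials)
        sums = frac[list(("motif_reset", "intro_notes_only", "call",
                          "pause_continuation", "none"))].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestLatencyCdf:
    def test_point_mass(self):
        cdf = bh.latency_cdf([50.0], bin_width=10.0)
        below = cdf[cdf.edge_ms < 50.0]
        assert (below.cum_prob == 0).all()
        assert cdf[cdf.edge_ms >= 50.0].cum_prob.iloc[0] == 1.0

    def test_uniform_quartile_steps(self):
        cdf = bh.latency_cdf([10.0, 20.0, 30.0, 40.0], bin_width=10.0)
        by_edge = dict(zip(cdf.edge_ms, cdf.cum_prob))
        assert by_edge[10.0] == 0.25
        assert by_edge[20.0] == 0.5
        assert by_edge[30.0] == 0.75
        assert by_edge[40.0] == 1.0

    def test_matches_naive_loop_ecdf(self, rng):
        lat = rng.exponential(scale=80.0, size=200)
        cdf = bh.latency_cdf(lat, bin_width=10.0)
        for edge, prob in zip(cdf.edge_ms, cdf.cum_prob):
            count = sum(1 for x in lat if x <= edge)  # naive loop oracle
            assert prob == count / len(lat)

    def test_reaches_one_and_monotone(self, rng):
        cdf = bh.latency_cdf(rng.lognormal(4, 0.5, 100))
        assert cdf.cum_prob.iloc[-1] == 1.0
        assert (np.diff(cdf.cum_prob) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh.latency_cdf([])

    def test_group_average_curve(self, rng):
        per_animal = {f"b{i}": rng.exponential(80.0, 50) for i in range(4)}
        g = bh.group_latency_cdf(per_animal)
        assert g.cum_prob_mean.iloc[-1] == pytest.approx(1.0)
        assert (g.cum_prob_sem.dropna() >= 0).all()


class TestBoutTermination:
    def test_all_false_is_zero(self):
        bouts = pd.DataFrame(dict(
            bird_id=["b"] * 10, motifs_in_bout=[2] * 10,
            stimulated_across_transition=[True] * 10, terminated_at_stim=[False] * 10,
        ))
        assert bh.bout_termination_probability(bouts, "stimulated") == 0.0

    def test_direct_fraction(self):
        flags = [True] * 10 + [False] * 40
        bouts = pd.DataFrame(dict(
            bird_id=["b"] * 50, motifs_in_bout=[2] * 50,
            stimulated_across_transition=[True] * 50, terminated_at_stim=flags,
        ))
        assert bh.bout_termination_probability(bouts, "stimulated") == 0.2

    def test_generator_truth_within_ci(self):
        spec = CohortSpec(n_birds=4, bouts_per_bird=50, p_bout_termination=0.3, seed=9)
        _, bouts, _ = generate_cohort(spec)
        est = bh.bout_termination_probability(bouts, "stimulated")
        n = int(bouts.stimulated_across_transition.sum())
        assert abs(est - 0.3) < 1.96 * math.sqrt(0.3 * 0.7 / n) + 1e-9

    def test_empty_condition_rejected(self):
        bouts = pd.DataFrame(dict(
            bird_id=["b"], motifs_in_bout=[1],
            stimulated_across_transition=[True], terminated_at_stim=[False],
        ))
        with pytest.raises(ValueError):
            bh.bout_termination_probability(bouts, "sham")


def counts_table(rows):
    return pd.DataFrame(rows, columns=["hemisphere_id", "nucleus", "cell_count"])


class TestLesionExtent:
    def test_intact_nucleus_reads_zero(self):
        ctrl = counts_table([("h0", "Uva", 100), ("h0", "mMAN", 146),
                             ("h1", "Uva", 200), ("h1", "mMAN", 292)])
        les = counts_table([("L0", "Uva", 100), ("L0", "mMAN", 146)])
        out = bh.lesion_extent(ctrl, les, "Uva", ["mMAN"])
        assert out.pct_lesion.iloc[0] == 0.0

    def test_complete_lesion_with_control_ratio(self):
        # control ratio mMAN/Uva = 1.46; lesioned Uva count 100 -> expected 146
        ctrl = counts_table([("h0", "Uva", 100), ("h0", "mMAN", 146)])
        les = counts_table([("L0", "Uva", 100), ("L0", "mMAN", 0)])
        out = bh.lesion_extent(ctrl, les, "Uva", ["mMAN"])
        assert out.expected.iloc[0] == pytest.approx(146.0)
        assert out.pct_lesion.iloc[0] == 100.0

    def test_exact_ratio_recovered_without_noise(self):
        # integer-consistent ratio 2.0, zero noise -> machine precision
        ctrl = generate_cellcounts({"mMAN": 2.0}, hemispheres=6, noise_cv=0.0, seed=4)
        piv = ctrl.pivot(index="hemisphere_id", columns="nucleus", values="cell_count")
        ratios = piv["mMAN"] / piv["Uva"]
        np.testing.assert_allclose(ratios, 2.0, rtol=0, atol=0)

    def test_overcount_clamped_to_zero(self):
        ctrl = counts_table([("h0", "Uva", 100), ("h0", "mMAN", 100)])
        les = counts_table([("L0", "Uva", 100), ("L0", "mMAN", 180)])
        out = bh.lesion_extent(ctrl, les, "Uva", ["mMAN"])
        assert out.pct_lesion.iloc[0] == 0.0

    def test_zero_reference_rejected(self):
        ctrl = counts_table([("h0", "Uva", 0), ("h0", "mMAN", 10)])
        les = counts_table([("L0", "Uva", 10), ("L0", "mMAN", 10)])
        with pytest.raises(ValueError):
            bh.lesion_extent(ctrl, les, "Uva", ["mMAN"])

    def test_missing_target_rejected(self):
        ctrl = counts_table([("h0", "Uva", 10)])
        les = counts_table([("L0", "Uva", 10), ("L0", "NIf", 5)])
        with pytest.raises(ValueError, match="NIf"):
            bh.lesion_extent(ctrl, les, "Uva", ["NIf"])

    def test_unlesioned_animal_reads_low(self):
        ctrl = generate_cellcounts(DEFAULT_CONTROL_RATIOS, hemispheres=12,
                                   noise_cv=0.3, seed=21)
        sham = generate_cellcounts(DEFAULT_CONTROL_RATIOS, hemispheres=12,
                                   noise_cv=0.3, seed=22)
        out = bh.lesion_extent(ctrl, sham, "Uva", list(DEFAULT_CONTROL_RATIOS))
        assert out.groupby("nucleus").pct_lesion.mean().max() < 15.0


class TestCsvSchemas:
    def test_trials_roundtrip(self, tmp_path):
        trials, bouts, _ = generate_cohort(CohortSpec(n_birds=2, trials_per_bird=10, seed=1))
        tp, bp = tmp_path / "t.csv", tmp_path / "b.csv"
        trials.to_csv(tp, index=False)
        bouts.to_csv(bp, index=False)
        t2, b2 = bh.read_trials(tp), bh.read_bouts(bp)
        assert len(t2) == len(trials) and len(b2) == len(bouts)
        np.testing.assert_allclose(t2.stim_onset_ms, trials.stim_onset_ms)

    def test_bad_header_reports_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("bird_id,wrong\nb0,1\n")
        with pytest.raises(bh.SchemaError, match="wrong"):
            bh.read_trials(path)

    def test_bad_value_reports_line_number(self, tmp_path):
        path = tmp_path / "cc.csv"
        path.write_text("hemisphere_id,nucleus,cell_count\nh0,Uva,12\nh1,Uva,oops\n")
        with pytest.raises(bh.SchemaError, match="line 3"):
            bh.read_cellcounts(path)

    def test_duplicate_cellcount_rows_rejected(self, tmp_path):
        path = tmp_path / "cc.csv"
        path.write_text("hemisphere_id,nucleus,cell_count\nh0,Uva,12\nh0,Uva,13\n")
        with pytest.raises(bh.SchemaError, match="duplicate"):
            bh.read_cellcounts(path)
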
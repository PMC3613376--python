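"""The three dyssynchrony measures, their axioms and their oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from strainsync import (
    Segment,
    dyssynchrony_report,
    max_ttp_delay,
    mean_vector_angle,
    scenario_preset,
    simulate_study,
    ttp_sd,
    vector_angle,
)
from strainsync.dyssynchrony import pairwise_mean_angle
from strainsync.errors import DataError, UsageError


def brute_force_mean_angle(vectors):
    """Independent double-loop oracle for the mean pairwise angle."""
    angles = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            a, b = np.asarray(vectors[i]), np.asarray(vectors[j])
            cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cos)))))
    return sum(angles) / len(angles)


nonzero_vectors = arrays(
    float,
    st.shared(st.integers(2, 12), key="dim"),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
).filter(lambda v: np.linalg.norm(v) > 1e-6)


class TestTTPMeasures:
    def test_max_delay_is_the_range(self):
        assert max_ttp_delay([40.0, 42.0, 44.0, 46.0, 48.0, 50.0]) == 10.0

    def test_synchronous_segments_give_zero(self):
        assert max_ttp_delay([30.0] * 6) == 0.0
        assert ttp_sd([30.0] * 6) == 0.0

    def test_sample_sd_hand_computed(self):
        # SD of [0,0,0,10,10,10] with n-1 denominator = sqrt(30) = 5.477
        assert ttp_sd([0.0, 0.0, 0.0, 10.0, 10.0, 10.0]) == pytest.approx(
            5.477, abs=1e-3
        )

    @given(st.lists(st.floats(0, 100), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_sd_never_exceeds_range(self, ttps):
        assert ttp_sd(ttps) <= max_ttp_delay(ttps) + 1e-9

    def test_wrong_count_rejected(self):
        with pytest.raises(UsageError):
            max_ttp_delay([1.0, 2.0])
        with pytest.raises(UsageError):
            ttp_sd(list(range(7)))


class TestVectorAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1.0, 0.0), (0.0, 1.0), 90.0),
            ((1.0, 2.0, 3.0), (-1.0, -2.0, -3.0), 180.0),
            ((1.0, 2.0), (2.0, 4.0), 0.0),
        ],
    )
    def test_reference_angles(self, a, b, expected):
        assert vector_angle(np.array(a), np.array(b)) == pytest.approx(
            expected, abs=1e-5
        )

    @given(a=nonzero_vectors)
    @settings(deadline=None)
    def test_identity_axiom(self, a):
        assert vector_angle(a, a) == pytest.approx(0.0, abs=1e-3)

    @given(a=nonzero_vectors, b=nonzero_vectors)
    @settings(deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        th = vector_angle(a, b)
        assert 0.0 <= th <= 180.0
        assert th == pytest.approx(vector_angle(b, a))

    @given(a=nonzero_vectors, b=nonzero_vectors, c=st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_positive_scale_invariance(self, a, b, c):
        assert vector_angle(a, c * b) == pytest.approx(vector_angle(a, b), abs=1e-4)

    def test_zero_norm_rejected(self):
        with pytest.raises(DataError):
            vector_angle(np.zeros(4), np.ones(4))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(UsageError):
            vector_angle(np.ones(3), np.ones(4))


class TestMeanVectorAngle:
    def test_three_vector_toy_case(self):
        vecs = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0])]
        res = pairwise_mean_angle(vecs)
        # pairwise angles 90, 45, 45 -> mean 60
        assert res.mean_angle_deg == pytest.approx(60.0, abs=1e-9)
        assert res.n_pairs == 3

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        vecs = [rng.normal(size=9) for _ in range(n)]
        res = pairwise_mean_angle(vecs)
        assert res.mean_angle_deg == pytest.approx(
            brute_force_mean_angle(vecs), abs=1e-9
        )
        assert res.n_pairs == n * (n - 1) // 2

    def test_identical_curves_give_zero(self):
        cfg = scenario_preset("sham", seed=0)
        cfg.noise_sd = 0.0
        cfg.phase_jitter_sd = 0.0
        cfg.amplitude_map = {s: 15.0 for s in cfg.amplitude_map}
        study = simulate_study(cfg)
        res = mean_vector_angle(study, "endo", study.cycles[0])
        assert res.mean_angle_deg == pytest.approx(0.0, abs=1e-4)
        assert res.n_vectors == 48 and res.n_pairs == 1128

    def test_amplitude_only_heterogeneity_gives_zero(self):
        # positive scalings of one waveform: angles are scale-invariant
        cfg = scenario_preset("sham", seed=0)
        cfg.noise_sd = 0.0
        cfg.phase_jitter_sd = 0.0
        study = simulate_study(cfg)  # apical > basal amplitudes, same phase
        res = mean_vector_angle(study, "endo", study.cycles[0])
        assert res.mean_angle_deg == pytest.approx(0.0, abs=1e-4)

    def test_48_vector_study_matches_oracle(self, sham_study, one_cycle):
        from strainsync.dyssynchrony import study_vectors

        vecs = [v.values for v in study_vectors(sham_study, "endo", one_cycle)]
        res = mean_vector_angle(sham_study, "endo", one_cycle)
        assert res.mean_angle_deg == pytest.approx(
            brute_force_mean_angle(vecs), abs=1e-9
        )


class TestReport:
    def test_synchronous_noiseless_study_is_all_zero(self):
        cfg = scenario_preset("sham", seed=0)
        cfg.noise_sd = 0.0
        cfg.phase_jitter_sd = 0.0
        study = simulate_study(cfg)
        res = dyssynchrony_report(study, "endo", study.cycles)
        assert res.max_ttp_delay_ms == 0.0
        assert res.ttp_sd_ms == pytest.approx(0.0, abs=1e-9)
        assert res.mean_vector_angle_deg == pytest.approx(0.0, abs=1e-4)

    def test_imposed_phase_range_recovered(self):
        cfg = scenario_preset("sham", seed=0)
        cfg.noise_sd = 0.0
        cfg.phase_jitter_sd = 0.0
        delta = 13.0  # ms, three frame intervals at 230 Hz
        cfg.segment_phase_offsets = {
            Segment.ANT_BASE: 0.0,
            Segment.POST_BASE: delta,
            Segment.ANT_MID: 0.0,
            Segment.POST_MID: delta,
            Segment.ANT_APEX: 0.0,
            Segment.POST_APEX: delta,
        }
        study = simulate_study(cfg)
        res = dyssynchrony_report(study, "endo", study.cycles)
        frame_ms = 1000.0 / cfg.frame_rate
        assert abs(res.max_ttp_delay_ms - delta) <= frame_ms

    def test_aac_larger_than_sham_across_seed_pairs(self):
        wins = 0
        n = 20
        for seed in range(n):
            sham = simulate_study(scenario_preset("sham", seed=seed))
            aac = simulate_study(scenario_preset("aac", seed=seed))
            a_sham = dyssynchrony_report(sham, "endo", sham.cycles)
            a_aac = dyssynchrony_report(aac, "endo", aac.cycles)
            wins += a_aac.mean_vector_angle_deg > a_sham.mean_vector_angle_deg
        assert wins >= 0.9 * n

    def test_empty_cycle_list_rejected(self, sham_study):
        with pytest.raises(UsageError):
            dyssynchrony_report(sham_study, "endo", [])
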
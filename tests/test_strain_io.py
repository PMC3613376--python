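"""I/O: the strainsync-v1 CSV dialect, type invariants and layer validation."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from strainsync import (
    CycleWindow,
    FrameGrid,
    Layer,
    PointTrace,
    Segment,
    StrainStudy,
    read_export,
    simulate_study,
    scenario_preset,
    validate_layer,
    write_export,
)
from strainsync.errors import FormatError, IntegrityError
from conftest import make_grid, make_study, uniform_study


class TestTypes:
    def test_frame_grid_rejects_non_increasing_times(self):
        with pytest.raises(IntegrityError):
            FrameGrid(frame_times=np.array([0.0, 2.0, 2.0]), frame_rate=500.0)

    def test_frame_grid_rejects_inconsistent_rate(self):
        # 10 ms spacing vs claimed 230 Hz (4.35 ms) is > 20% off nominal
        with pytest.raises(IntegrityError):
            FrameGrid(frame_times=np.arange(10) * 10.0, frame_rate=230.0)

    def test_point_trace_rejects_extreme_strain(self):
        with pytest.raises(IntegrityError):
            PointTrace(Segment.ANT_BASE, Layer.ENDO, 0, np.array([0.0, -120.0]))

    def test_point_trace_rejects_bad_point_index(self):
        with pytest.raises(IntegrityError):
            PointTrace(Segment.ANT_BASE, Layer.ENDO, 8, np.zeros(4))

    def test_study_rejects_duplicate_trace(self):
        grid = make_grid(8)
        tr = PointTrace(Segment.ANT_BASE, Layer.ENDO, 0, np.zeros(8))
        tr2 = PointTrace(Segment.ANT_BASE, Layer.ENDO, 0, np.ones(8) * -1)
        with pytest.raises(IntegrityError):
            StrainStudy(grid=grid, traces=[tr, tr2])

    def test_study_rejects_overlapping_cycles(self):
        with pytest.raises(IntegrityError):
            StrainStudy(
                grid=make_grid(24),
                traces=[PointTrace(Segment.ANT_BASE, Layer.ENDO, 0, np.zeros(24))],
                cycles=[CycleWindow(0, 10), CycleWindow(8, 20)],
            )

    def test_cycle_window_must_span_four_frames(self):
        with pytest.raises(IntegrityError):
            CycleWindow(0, 3)


class TestValidateLayer:
    def test_complete_layer_counts_48(self, sham_study):
        rep = validate_layer(sham_study, "endo")
        assert rep.n_present == 48 and rep.n_missing == 0 and rep.complete

    def test_missing_segment_reports_8(self):
        study = uniform_study()
        study = StrainStudy(
            grid=study.grid,
            traces=[t for t in study.traces if t.segment is not Segment.POST_MID],
        )
        rep = validate_layer(study, Layer.ENDO)
        assert rep.n_missing == 8
        assert all(seg is Segment.POST_MID for seg, _ in rep.missing)

    def test_empty_study_reports_48_missing(self):
        study = StrainStudy(
            grid=make_grid(8),
            traces=[PointTrace(Segment.ANT_BASE, Layer.EPI, 0, np.zeros(8))],
        )
        rep = validate_layer(study, Layer.ENDO)
        assert rep.n_missing == 48 and rep.n_present == 0

    def test_present_plus_missing_is_48(self, sham_study):
        for layer in Layer:
            rep = validate_layer(sham_study, layer)
            assert rep.n_present + rep.n_missing == 48


class TestRoundTrip:
    def test_two_layer_study_round_trips(self, tmp_path, sham_study):
        path = write_export(sham_study, tmp_path / "s.csv")
        back = read_export(path)
        assert len(back.traces) == 96
        assert len(back.layer_traces("endo")) == 48
        assert back.cycles == sham_study.cycles
        assert back.meta == sham_study.meta
        assert back.grid == sham_study.grid
        for a, b in zip(
            sham_study.sorted_layer_traces("endo"), back.sorted_layer_traces("endo")
        ):
            np.testing.assert_allclose(a.strain, b.strain, rtol=1e-6, atol=1e-6)
            np.testing.assert_allclose(a.position, b.position, rtol=1e-6, atol=1e-6)

    def test_positions_omitted_when_absent(self, tmp_path):
        study = uniform_study(n_frames=8)
        path = write_export(study, tmp_path / "nopos.csv")
        header = path.read_text().splitlines()[0]
        assert "pos_x_mm" not in header
        back = read_export(path)
        assert all(t.position is None for t in back.traces)

    def test_empty_study_refused(self, tmp_path):
        grid = make_grid(8)
        study = StrainStudy.__new__(StrainStudy)
        study.grid, study.traces, study.cycles, study.meta = grid, [], [], {}
        with pytest.raises(IntegrityError):
            write_export(study, tmp_path / "x.csv")

    @settings(max_examples=10, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 10_000), noise=st.floats(0.0, 3.0))
    def test_round_trip_random_studies(self, tmp_path, seed, noise):
        cfg = scenario_preset("aac", seed=seed)
        cfg.noise_sd = noise
        study = simulate_study(cfg)
        back = read_export(write_export(study, tmp_path / f"r{seed}.csv"))
        order = lambda s: sorted(s.traces, key=lambda t: (t.layer.value, t.segment.value, t.point_index))
        for a, b in zip(order(study), order(back)):
            assert a.key == b.key
            np.testing.assert_allclose(a.strain, b.strain, rtol=1e-6, atol=1e-6)


class TestReadErrors:
    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,time_ms,layer,segment,strain_pct\n")
        with pytest.raises(FormatError, match="point"):
            read_export(p)

    def test_unknown_segment_label_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = ["frame,time_ms,layer,segment,point,strain_pct"]
        rows += [f"{i},{i*4.3},endo,septal_base,0,-5" for i in range(4)]
        p.write_text("\n".join(rows))
        with pytest.raises(FormatError):
            read_export(p)

    def test_duplicate_point_rows_rejected(self, tmp_path, sham_study):
        path = write_export(sham_study, tmp_path / "dup.csv")
        lines = path.read_text().splitlines()
        # duplicate one full data row -> same (trace, frame) appears twice
        path.write_text("\n".join(lines + [lines[1]]))
        with pytest.raises(IntegrityError):
            read_export(path)

    def test_ragged_trace_rejected(self, tmp_path, sham_study):
        path = write_export(sham_study, tmp_path / "ragged.csv")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]))  # drop last frame of last trace
        with pytest.raises(IntegrityError):
            read_export(path)

    def test_frame_rate_inferred_without_sidecar(self, tmp_path, sham_study):
        path = write_export(sham_study, tmp_path / "s.csv", write_sidecar=False)
        back = read_export(path)
        assert back.grid.frame_rate == pytest.approx(230.0, rel=0.01)
        assert back.cycles == []
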
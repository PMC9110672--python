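"""FCS round-trips, the arcsinh transform and rectangular gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pribin import (
    ConfigError,
    EventTable,
    FcsFormatError,
    GateSpec,
    GateStep,
    StateError,
    TransformSpec,
    apply_gates,
    apply_transform,
    read_fcs,
    write_fcs,
)

inf = np.inf


def make_table(values, channels=None, markers=None, transformed=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    channels = channels or [f"ch{i}" for i in range(values.shape[1])]
    return EventTable(values=values, channels=channels,
                      markers=markers or {}, transformed=transformed)


class TestEventTable:
    def test_duplicate_marker_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            EventTable(np.zeros((1, 2)), ["a", "b"], markers={"a": "CD4", "b": "CD4"})

    def test_marker_lookup_resolves_one_column(self):
        t = make_table([[1.0, 2.0]], channels=["c1", "c2"], markers={"c1": "CD4"})
        assert t.get("CD4")[0] == 1.0
        assert t.get("c2")[0] == 2.0
        with pytest.raises(ConfigError, match="CD8"):
            t.get("CD8")


class TestFcsRoundtrip:
    @pytest.mark.parametrize("shape", [(10, 2), (1000, 12), (50_000, 41)])
    def test_write_read_recovers_values_at_float32(self, rng, shape, tmp_path):
        values = rng.normal(100, 40, size=shape)
        t = make_table(values)
        path = tmp_path / "t.fcs"
        write_fcs(t, path)
        back = read_fcs(path)
        assert back.n_events == shape[0]
        assert back.channels == t.channels
        np.testing.assert_array_equal(
            back.values, values.astype(np.float32).astype(float)
        )

    def test_marker_labels_with_spaces_preserved(self, tmp_path):
        t = make_table([[1.0, 2.0]], channels=["Yb176Di", "Gd155Di"],
                       markers={"Yb176Di": "Ki 67", "Gd155Di": "PD L1"})
        back = read_fcs(write_fcs(t, tmp_path / "m.fcs"))
        assert back.markers == t.markers

    def test_zero_event_file(self, tmp_path):
        t = make_table(np.empty((0, 3)))
        back = read_fcs(write_fcs(t, tmp_path / "empty.fcs"))
        assert back.n_events == 0
        assert back.channels == t.channels

    def test_double_roundtrip_is_byte_identical(self, rng, tmp_path):
        t = make_table(rng.normal(50, 10, size=(200, 4)))
        p1, p2 = tmp_path / "a.fcs", tmp_path / "b.fcs"
        write_fcs(read_fcs(write_fcs(t, p1)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_fcs(tmp_path / "nope.fcs")

    def test_truncated_data_segment_names_tot(self, rng, tmp_path):
        path = tmp_path / "t.fcs"
        write_fcs(make_table(rng.normal(size=(100, 3))), path)
        blob = path.read_bytes()
        path.write_bytes(blob[:-50])
        with pytest.raises(FcsFormatError, match=r"\$TOT"):
            read_fcs(path)

    def test_garbage_header_rejected(self, tmp_path):
        path = tmp_path / "bad.fcs"
        path.write_bytes(b"not an fcs file at all, just some text padding...........")
        with pytest.raises(FcsFormatError):
            read_fcs(path)


class TestTransform:
    def test_zero_maps_to_zero_any_cofactor(self):
        for cofactor in (0.1, 1.0, 5.0):
            t = apply_transform(make_table([[0.0]]), TransformSpec(cofactor=cofactor))
            assert t.values[0, 0] == 0.0

    def test_closed_form_value(self):
        t = apply_transform(make_table([[10.0]]), TransformSpec(cofactor=0.1))
        assert t.values[0, 0] == pytest.approx(np.arcsinh(1.0), abs=1e-12)
        assert t.values[0, 0] == pytest.approx(0.881374, abs=1e-6)

    def test_divide_convention(self):
        t = apply_transform(make_table([[10.0]]),
                            TransformSpec(cofactor=0.1, convention="divide"))
        assert t.values[0, 0] == pytest.approx(np.arcsinh(100.0), rel=1e-12)

    def test_inverse_recovers_input(self, rng):
        values = rng.uniform(0, 1000, size=(500, 2))
        spec = TransformSpec(cofactor=0.1)
        t = apply_transform(make_table(values), spec)
        np.testing.assert_allclose(spec.inverse(t.values), values, rtol=1e-6)

    def test_preserves_per_channel_ordering(self, rng):
        values = rng.normal(0, 100, size=(300, 1))
        t = apply_transform(make_table(values))
        assert (np.argsort(t.values[:, 0]) == np.argsort(values[:, 0])).all()

    def test_excluded_channels_untouched(self, rng):
        values = rng.uniform(1, 10, size=(50, 2))
        t = apply_transform(make_table(values, channels=["a", "b"]),
                            TransformSpec(channels=("a",)))
        np.testing.assert_array_equal(t.values[:, 1], values[:, 1])

    def test_double_transform_raises(self):
        t = apply_transform(make_table([[1.0]]))
        assert t.transformed
        with pytest.raises(StateError):
            apply_transform(t)

    def test_cofactor_must_be_positive(self):
        with pytest.raises(ConfigError):
            TransformSpec(cofactor=0.0)


class TestGates:
    def g(self, name, x_iv, y_iv, x="X", y="Y"):
        return GateStep(name, x, y, x_iv, y_iv)

    def test_full_range_gate_is_identity(self, small_table):
        out, report = apply_gates(
            small_table, GateSpec((self.g("all", (-inf, inf), (-inf, inf)),))
        )
        assert out.n_events == small_table.n_events
        assert report.loc[0, "fraction_kept"] == 1.0

    def test_constructed_events_inside_survive(self):
        xy = [(1.5, 2.0), (1.0, 0.0), (2.0, 5.0),   # inside x:[1,2], y>=0
              (0.5, 1.0), (2.5, 1.0), (1.5, -1.0),
              (3.0, 3.0), (-1.0, 0.0), (0.0, -2.0), (4.0, 4.0)]
        t = make_table(xy, channels=["X", "Y"], transformed=True)
        out, _ = apply_gates(t, GateSpec((self.g("box", (1.0, 2.0), (0.0, inf)),)))
        assert out.n_events == 3
        np.testing.assert_array_equal(out.values, np.asarray(xy[:3], dtype=float))

    def test_chain_matches_brute_force_membership(self, rng):
        t = make_table(rng.normal(1.5, 1.2, size=(5000, 4)),
                       channels=["X", "Y", "Z", "W"], transformed=True)
        steps = (
            self.g("s1", (0.0, 3.0), (-inf, 2.5)),
            self.g("s2", (-inf, 2.0), (0.5, inf), x="Z", y="W"),
            self.g("s3", (0.2, inf), (-inf, inf), x="Y", y="X"),
        )
        out, report = apply_gates(t, GateSpec(steps))
        keep = np.ones(t.n_events, dtype=bool)
        for i, row in enumerate(t.values):
            x, y, z, w = row
            keep[i] = (
                (0.0 <= x <= 3.0) and (y <= 2.5)
                and (z <= 2.0) and (w >= 0.5)
                and (y >= 0.2)
            )
        np.testing.assert_array_equal(out.values, t.values[keep])
        assert report["n_out"].iloc[-1] == keep.sum()

    def test_order_independent_and_idempotent(self, small_table):
        steps = [
            self.g("a", (0.0, 2.5), (-inf, inf)),
            self.g("b", (-inf, inf), (0.5, 3.0)),
            self.g("c", (-1.0, inf), (-inf, 2.8), x="Z", y="W"),
        ]
        fwd, _ = apply_gates(small_table, GateSpec(tuple(steps)))
        rev, _ = apply_gates(small_table, GateSpec(tuple(reversed(steps))))
        np.testing.assert_array_equal(fwd.values, rev.values)
        again, _ = apply_gates(fwd, GateSpec(tuple(steps)))
        np.testing.assert_array_equal(again.values, fwd.values)

    def test_unknown_marker_names_it(self, small_table):
        with pytest.raises(ConfigError, match="CD99"):
            apply_gates(
                small_table,
                GateSpec((self.g("bad", (-inf, inf), (-inf, inf), x="CD99"),)),
            )

    def test_empty_interval_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            GateStep("bad", "X", "Y", (2.0, 1.0), (-inf, inf))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=1, max_size=200))
def test_gating_returns_subset(values):
    t = make_table(np.column_stack([values, values]), channels=["X", "Y"],
                   transformed=True)
    out, _ = apply_gates(
        t, GateSpec((GateStep("g", "X", "Y", (-1.0, 1.0), (-inf, inf)),))
    )
    assert out.n_events <= t.n_events
    rows = {tuple(r) for r in t.values}
    assert all(tuple(r) in rows for r in out.values)


class TestGateConfig:
    def test_yaml_roundtrip(self, tmp_path):
        from pribin.fcs import load_gate_spec

        path = tmp_path / "gates.yaml"
        path.write_text(
            "steps:\n"
            "  - name: box\n"
            "    x_marker: X\n"
            "    y_marker: Y\n"
            "    x_interval: [1.0, 2.0]\n"
            "    y_interval: [0.0, null]\n"
            "  - name: open\n"
            "    x_marker: Z\n"
            "    y_marker: W\n"
        )
        spec = load_gate_spec(path)
        assert [s.name for s in spec.steps] == ["box", "open"]
        assert spec.steps[0].x_interval == (1.0, 2.0)
        assert spec.steps[0].y_interval == (0.0, inf)
        assert spec.steps[1].x_interval == (-inf, inf)

    def test_missing_key_reported(self, tmp_path):
        from pribin.fcs import load_gate_spec

        path = tmp_path / "bad.yaml"
        path.write_text("steps:\n  - name: s\n    x_marker: X\n")
        with pytest.raises(ConfigError, match="missing key"):
            load_gate_spec(path)

    def test_cd4_template_chain(self):
        from pribin.fcs import cd4_gate_template

        spec = cd4_gate_template({"cd4_low": 2.0})
        names = [s.name for s in spec.steps]
        assert names == ["live_singlets", "bead_exclusion", "leukocytes",
                         "t_cells", "cd4_helpers"]
        assert spec.steps[-1].x_interval[0] == 2.0
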
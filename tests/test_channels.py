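"""Channel containers, the on-disk CSV dialect, manifests and RunConfig."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import turtlehr as t
from turtlehr.exceptions import (
    ChannelFormatError,
    ChannelParseError,
    IncompleteDeploymentError,
    ValidationError,
)


class TestChannel:
    def test_header_echo(self, tmp_path):
        p = tmp_path / "ch.csv"
        p.write_text("# name: ecg\n# rate_hz: 250\n# units: mV\n# t0_s: 0\n0.1\n0.2\n0.1\n")
        ch = t.read_channel(p)
        assert ch.name == "ecg" and ch.rate == 250 and ch.units == "mV" and ch.t0 == 0
        assert np.array_equal(ch.values, [0.1, 0.2, 0.1])

    def test_sample_times(self):
        ch = t.Channel("x", [0.0, 1.0, 2.0], rate=2.0, t0=5.0)
        assert np.allclose(ch.times(), [5.0, 5.5, 6.0])
        assert ch.duration_s == 1.5

    @pytest.mark.parametrize("rate", [0, -1.0])
    def test_nonpositive_rate_rejected(self, tmp_path, rate):
        p = tmp_path / "ch.csv"
        p.write_text(f"# name: x\n# rate_hz: {rate}\n# units: mV\n# t0_s: 0\n0.1\n")
        with pytest.raises(ValidationError):
            t.read_channel(p)

    def test_parse_error_reports_line_number(self, tmp_path):
        p = tmp_path / "ch.csv"
        p.write_text("# name: x\n# rate_hz: 16\n# units: mV\n# t0_s: 0\n0.1\noops\n")
        with pytest.raises(ChannelParseError) as exc:
            t.read_channel(p)
        assert exc.value.line_number == 6

    @pytest.mark.parametrize(
        "header",
        [
            "# name: x\n# rate_hz: 16\n# units: mV\n",  # missing t0_s
            "# name: x\n# name: y\n# rate_hz: 16\n# units: mV\n# t0_s: 0\n",  # duplicate
        ],
    )
    def test_bad_header_rejected(self, tmp_path, header):
        p = tmp_path / "ch.csv"
        p.write_text(header + "0.1\n")
        with pytest.raises(ChannelFormatError):
            t.read_channel(p)

    def test_nan_sample_rejected(self, tmp_path):
        p = tmp_path / "ch.csv"
        p.write_text("# name: x\n# rate_hz: 16\n# units: mV\n# t0_s: 0\nnan\n")
        with pytest.raises((ValidationError, ChannelParseError)):
            t.read_channel(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        ch = t.Channel("accel_long", rng.normal(size=1000), rate=16.0, units="m s^-2")
        t.write_channel(ch, tmp_path / "a.csv")
        assert t.read_channel(tmp_path / "a.csv") == ch

    def test_empty_channel_round_trip(self, tmp_path):
        ch = t.Channel("ecg", [], rate=250.0, units="mV")
        t.write_channel(ch, tmp_path / "e.csv")
        back = t.read_channel(tmp_path / "e.csv")
        assert back.n == 0 and back == ch

    def test_overwrite_protection(self, tmp_path):
        ch = t.Channel("ecg", [0.1], rate=250.0, units="mV")
        t.write_channel(ch, tmp_path / "e.csv")
        with pytest.raises(FileExistsError):
            t.write_channel(ch, tmp_path / "e.csv")
        t.write_channel(ch, tmp_path / "e.csv", force=True)  # no error

    @given(
        values=st.lists(
            st.floats(allow_nan=False, allow_infinity=False, width=64),
            max_size=50,
        ),
        rate=st.floats(min_value=0.5, max_value=1000, allow_nan=False),
        t0=st.floats(min_value=0, max_value=1e4, allow_nan=False),
    )
    def test_round_trip_property(self, tmp_path, values, rate, t0):
        """Write->read is bit-for-bit identity for arbitrary finite channels."""
        ch = t.Channel("x", values, rate=rate, units="mV", t0=t0)
        path = tmp_path / "prop.csv"
        t.write_channel(ch, path, force=True)
        assert t.read_channel(path) == ch


class TestDeployment:
    def _write(self, tmp_path, channels, placement="C"):
        for name, ch in channels.items():
            t.write_channel(ch, tmp_path / f"{name}.csv", force=True)
        manifest = tmp_path / "manifest.yaml"
        chan_lines = "\n".join(f"  {n}: {n}.csv" for n in channels)
        manifest.write_text(
            f"turtle_id: G0001\nplacement: {placement}\nchannels:\n{chan_lines}\n"
        )
        return manifest

    def test_valid_manifest_loads(self, tmp_path):
        ecg = t.Channel("ecg", np.zeros(250), rate=250.0, units="mV")
        acc = t.Channel("accel_long", np.zeros(16), rate=16.0, units="m s^-2")
        manifest = self._write(tmp_path, {"ecg": ecg, "accel_long": acc})
        rec = t.load_deployment(manifest)
        assert rec.turtle_id == "G0001" and rec.placement == "C"
        assert rec.ecg == ecg and rec.accel == acc  # values never altered

    def test_missing_required_channel(self, tmp_path):
        ecg = t.Channel("ecg", np.zeros(250), rate=250.0, units="mV")
        manifest = self._write(tmp_path, {"ecg": ecg})
        with pytest.raises(IncompleteDeploymentError):
            t.load_deployment(manifest)

    def test_unknown_placement(self, tmp_path):
        ecg = t.Channel("ecg", np.zeros(250), rate=250.0, units="mV")
        acc = t.Channel("accel_long", np.zeros(16), rate=16.0, units="m s^-2")
        manifest = self._write(tmp_path, {"ecg": ecg, "accel_long": acc}, placement="D")
        with pytest.raises(ValidationError):
            t.load_deployment(manifest)

    def test_save_then_load_directory(self, tmp_path):
        rec, _ = t.generate_deployment(t.BehaviorModel(duration_min=2), seed=1)
        t.save_deployment(rec, tmp_path / "dep")
        back = t.load_deployment(tmp_path / "dep")
        assert back.channels.keys() == rec.channels.keys()
        for name in rec.channels:
            assert back.channels[name] == rec.channels[name]


class TestRunConfig:
    def test_defaults_match_protocol(self):
        cfg = t.RunConfig()
        assert cfg.behavior_threshold_ms2 == 0.5
        assert cfg.min_phase_minutes == 2
        assert cfg.handling_exclusion_h == 12.0
        assert cfg.quality_cuts == (0.30, 0.70)

    @pytest.mark.parametrize(
        "kw",
        [
            {"band_low_hz": 30, "band_high_hz": 5},
            {"quality_cuts": (0.7, 0.3)},
            {"quality_cuts": (0.0, 0.7)},
            {"refractory_s": 0},
            {"min_phase_minutes": 0},
            {"threshold_quantile": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            t.RunConfig(**kw)

    def test_band_checked_against_nyquist(self):
        cfg = t.RunConfig(band_high_hz=30)
        with pytest.raises(ValidationError):
            cfg.validate_against_rate(50.0)  # Nyquist 25 < 30
        cfg.validate_against_rate(250.0)

    def test_yaml_round_trip_and_partial_file(self, tmp_path):
        cfg = t.RunConfig(band_low_hz=4.0, min_phase_minutes=3)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert t.RunConfig.from_yaml(tmp_path / "cfg.yaml") == cfg
        (tmp_path / "partial.yaml").write_text("min_phase_minutes: 5\n")
        partial = t.RunConfig.from_yaml(tmp_path / "partial.yaml")
        assert partial.min_phase_minutes == 5
        assert partial.behavior_threshold_ms2 == 0.5  # defaults fill the rest

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("not_a_field: 1\n")
        with pytest.raises(ValidationError):
            t.RunConfig.from_yaml(tmp_path / "bad.yaml")
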
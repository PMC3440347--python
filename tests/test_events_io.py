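import struct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

import cytoquant as cq
from cytoquant.errors import FormatError, ValidationError


class TestEventTable:
    def test_three_row_identity(self, tmp_path):
        df = pd.DataFrame({"fsc": [1.0, 2.0, 3.0], "ssc": [4.0, 5.0, 6.0],
                           "fl1": [7.0, 8.0, 9.0], "fl2": [10.0, 11.0, 12.0]})
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        t = cq.read_event_table(p)
        assert len(t) == 3
        pd.testing.assert_frame_equal(t.data, df)

    def test_write_read_round_trip(self, event_table, tmp_path):
        p = cq.write_event_table(event_table, tmp_path / "e.csv")
        back = cq.read_event_table(p)
        for ch in ("fsc", "ssc", "fl1", "fl2"):
            np.testing.assert_allclose(back.channel(ch), event_table.channel(ch),
                                       rtol=1e-6)

    def test_ground_truth_columns_preserved(self, small_scenario, tmp_path):
        t = cq.generate_cell_events(small_scenario, labeled=True, seed=1)
        back = cq.read_event_table(cq.write_event_table(t, tmp_path / "g.csv"))
        assert back.has_ground_truth
        np.testing.assert_allclose(back.data["true_receptors"],
                                   t.data["true_receptors"], rtol=1e-6)
        assert (back.data["population_label"] == t.data["population_label"]).all()

    def test_empty_table_header_only(self, tmp_path):
        t = cq.EventTable(pd.DataFrame({c: [] for c in ("fsc", "ssc", "fl1", "fl2")}))
        p = cq.write_event_table(t, tmp_path / "empty.csv")
        assert p.read_text().strip() == "fsc,ssc,fl1,fl2"
        assert len(cq.read_event_table(p)) == 0

    def test_missing_channel_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"fsc": [1.0], "ssc": [1.0], "fl1": [1.0]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="fl2"):
            cq.read_event_table(p)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            cq.EventTable(pd.DataFrame({"fsc": [1.0], "ssc": [1.0],
                                        "fl1": [-1.0], "fl2": [1.0]}))

    @given(arrays(np.float64, st.integers(1, 40),
                  elements=st.floats(0, 1e6, allow_nan=False, width=32)))
    def test_round_trip_is_identity(self, tmp_path_factory, values):
        tmp = tmp_path_factory.mktemp("rt")
        df = pd.DataFrame({c: values for c in ("fsc", "ssc", "fl1", "fl2")})
        t = cq.EventTable(df)
        back = cq.read_event_table(cq.write_event_table(t, tmp / "h.csv"))
        np.testing.assert_allclose(back.channel("fl2"), values, rtol=1e-6, atol=1e-9)


class TestBeadLevelSet:
    def test_default_is_quantibrite(self):
        assert cq.BeadLevelSet().levels == (515.0, 5956.0, 26653.0, 69045.0)

    @pytest.mark.parametrize("levels", [(515,), (515, 515), (5956, 515), (0, 515)])
    def test_invalid_level_sets_rejected(self, levels):
        with pytest.raises(ValidationError):
            cq.BeadLevelSet(levels)


class TestConfig:
    def test_empty_config_gives_protocol_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("{}\n")
        cfg = cq.load_config(p)
        assert isinstance(cfg, cq.PipelineConfig)
        assert cfg.outlier_k == 3.0
        assert cfg.bin_width == 500.0
        assert cfg.alpha == 0.05
        assert cfg.bead_levels.levels == (515.0, 5956.0, 26653.0, 69045.0)

    def test_overridden_field_retained(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("outlier_k: 2.5\n")
        assert cq.load_config(p).outlier_k == 2.5

    def test_invalid_value_names_field(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("bin_width: -1\n")
        with pytest.raises(ValidationError, match="bin_width"):
            cq.load_config(p)

    def test_scenario_config_dispatch(self, tmp_path):
        p = tmp_path / "s.yaml"
        p.write_text("receptor_distribution: {median: 1500, cv: 0.8}\nn_cells: 100\n")
        cfg = cq.load_config(p)
        assert isinstance(cfg, cq.ScenarioConfig)
        assert cfg.receptor_distribution.median == 1500

    def test_pipeline_config_round_trip(self, tmp_path):
        cfg = cq.PipelineConfig(outlier_k=2.5, alpha=0.01)
        from cytoquant.events_io import dump_config

        back = cq.load_config(dump_config(cfg, tmp_path / "rt.yaml"))
        assert back == cfg


def _write_fcs(path, data, datatype="F"):
    """Write a tiny FCS 3.0 file (float32 or uint16 list mode)."""
    n_tot, n_par = data.shape
    names = ["FSC", "SSC", "FL1", "FL2"]
    if datatype == "F":
        body = data.astype("<f4").tobytes()
        bits = 32
    else:
        body = data.astype("<u2").tobytes()
        bits = 16
    kv = {"$PAR": n_par, "$TOT": n_tot, "$MODE": "L", "$DATATYPE": datatype,
          "$BYTEORD": "1,2,3,4"}
    for i, nm in enumerate(names, 1):
        kv[f"$P{i}N"] = nm
        kv[f"$P{i}B"] = bits
    text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
    text_start = 58
    text_bytes = text.encode()
    data_start = text_start + len(text_bytes)
    header = (b"FCS3.0    "
              + f"{text_start:8d}".encode() + f"{data_start - 1:8d}".encode()
              + f"{data_start:8d}".encode() + f"{data_start + len(body) - 1:8d}".encode()
              + f"{0:8d}".encode() + f"{0:8d}".encode())
    path.write_bytes(header + text_bytes + body)


class TestFcsAdapter:
    @pytest.mark.parametrize("datatype", ["F", "I"])
    def test_fcs_read_matches_written_events(self, tmp_path, datatype):
        rng = np.random.default_rng(3)
        data = rng.integers(1, 1000, size=(25, 4)).astype(float)
        p = tmp_path / "t.fcs"
        _write_fcs(p, data, datatype)
        t = cq.read_event_table(p, dialect="fcs")
        assert len(t) == 25
        np.testing.assert_allclose(t.data.to_numpy(), data, rtol=1e-6)

    def test_non_fcs_file_rejected(self, tmp_path):
        p = tmp_path / "x.fcs"
        p.write_bytes(b"not an fcs file" * 10)
        with pytest.raises(FormatError):
            cq.read_event_table(p, dialect="fcs")
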
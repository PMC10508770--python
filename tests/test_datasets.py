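"""Label standardization, filtering and CSV ingestion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinleak.datasets import (BioactivityRecord, BioactivityTable, SchemaError,
                              clip_percent_inhibition, filter_table, kd_to_pkd,
                              percent_inhibition_to_pic50,
                              pic50_to_percent_inhibition,
                              read_bioactivity_csv)


class TestClip:
    @pytest.mark.parametrize("p,expected", [(99, 98), (1, 2), (50, 50),
                                            (98, 98), (2, 2), (0, 2), (100, 98)])
    def test_clipping(self, p, expected):
        assert clip_percent_inhibition(p) == expected

    @pytest.mark.parametrize("p", [-1, 101, 150])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            clip_percent_inhibition(p)


class TestPercentInhibitionToPic50:
    # oracle: solve f = D/(D + IC50) for IC50 at D = 0.5 uM, then -log10 molar
    @pytest.mark.parametrize("p,expected", [
        (50, 6.30103),    # IC50 = 0.5 uM
        (99, 7.99123),    # clips to 98; IC50 = 0.0102041 uM
        (1, 4.61083),     # clips to 2;  IC50 = 24.5 uM
    ])
    def test_hill_slope_oracle_values(self, p, expected):
        assert percent_inhibition_to_pic50(p) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(derandomize=True, max_examples=60)
    def test_strictly_monotone_between_clip_bounds(self, p1, p2):
        v1 = percent_inhibition_to_pic50(p1)
        v2 = percent_inhibition_to_pic50(p2)
        c1, c2 = clip_percent_inhibition(p1), clip_percent_inhibition(p2)
        if c1 < c2:
            assert v1 < v2
        elif c1 == c2:
            assert v1 == v2

    @given(st.floats(0, 100))
    @settings(derandomize=True, max_examples=60)
    def test_roundtrip_recovers_clipped_percent(self, p):
        pic50 = percent_inhibition_to_pic50(p)
        assert pic50_to_percent_inhibition(pic50) == pytest.approx(
            clip_percent_inhibition(p), abs=1e-10)

    def test_literal_formula_is_antimonotone(self):
        # the discarded literal reading: stronger inhibition -> weaker potency
        lo = percent_inhibition_to_pic50(10, formula="literal")
        hi = percent_inhibition_to_pic50(90, formula="literal")
        assert hi < lo


class TestKdToPkd:
    @pytest.mark.parametrize("kd,expected", [(1e-9, 9.0), (1.0, 0.0), (1e-6, 6.0)])
    def test_values(self, kd, expected):
        assert kd_to_pkd(kd) == pytest.approx(expected)

    @pytest.mark.parametrize("kd", [0.0, -5e-9])
    def test_nonpositive_rejected(self, kd):
        with pytest.raises(ValueError):
            kd_to_pkd(kd)

    @given(st.floats(1e-12, 1e-3), st.floats(1e-12, 1e-3))
    @settings(derandomize=True, max_examples=60)
    def test_lower_kd_means_higher_pkd(self, a, b):
        if a < b:
            assert kd_to_pkd(a) > kd_to_pkd(b)


class TestRecordInvariants:
    def test_klifs_length_enforced(self):
        with pytest.raises(ValueError):
            BioactivityRecord("K", "A" * 84, "I", "CCO", 7.0)

    def test_smiles_length_enforced(self):
        with pytest.raises(ValueError):
            BioactivityRecord("K", "A" * 85, "I", "C" * 91, 7.0)

    def test_nonfinite_label_rejected(self):
        with pytest.raises(ValueError):
            BioactivityRecord("K", "A" * 85, "I", "CCO", float("nan"))


def _make_table(smiles_lengths=(10, 90, 91), klifs_len=85):
    rows = []
    for i, L in enumerate(smiles_lengths):
        rows.append({"kinase_id": "K0", "klifs_sequence": "A" * klifs_len,
                     "inhibitor_id": f"I{i}", "smiles": "C" * L,
                     "label": 6.0, "label_type": "pAct"})
    return BioactivityTable(pd.DataFrame(rows))


class TestFilterTable:
    def test_smiles_boundary_strict_inequality(self):
        out, log = filter_table(_make_table((10, 90, 91)))
        assert len(out) == 2            # 90-char kept, 91-char dropped
        assert log.dropped_long_smiles == 1

    def test_bad_klifs_dropped(self):
        t = _make_table((10,))
        t.df.loc[0, "klifs_sequence"] = "A" * 80
        out, log = filter_table(t)
        assert len(out) == 0 and log.dropped_bad_klifs == 1

    def test_empty_table(self):
        from kinleak.datasets import CANONICAL_COLUMNS
        t = BioactivityTable(pd.DataFrame(columns=CANONICAL_COLUMNS))
        out, log = filter_table(t)
        assert len(out) == 0 and log.total_dropped == 0

    def test_idempotent(self):
        out1, _ = filter_table(_make_table((10, 90, 91)))
        out2, log2 = filter_table(out1)
        assert log2.total_dropped == 0
        pd.testing.assert_frame_equal(out1.df, out2.df)


class TestReadBioactivityCsv:
    def _write(self, tmp_path, rows, columns):
        path = tmp_path / "data.csv"
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    def test_kd_nm_conversion(self, tmp_path):
        rows = [["K0", "A" * 85, f"I{i}", "C" * (i + 1), kd]
                for i, kd in enumerate([1, 10, 100])]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "label"])
        t = read_bioactivity_csv(path, {"label_unit": "Kd_nM"})
        assert list(t.df.label) == pytest.approx([9.0, 8.0, 7.0])
        assert set(t.df.label_type) == {"Kd"}

    def test_pact_passthrough(self, tmp_path):
        rows = [["K0", "A" * 85, f"I{i}", "CC", v] for i, v in enumerate([5.5, 7.25])]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "label"])
        t = read_bioactivity_csv(path)
        assert list(t.df.label) == [5.5, 7.25]

    def test_percent_activity_bridge(self, tmp_path):
        # percent activity 50 -> inhibition 50 -> pIC50 of the 0.5 uM dose
        rows = [["K0", "A" * 85, "I0", "CC", 50.0],
                ["K0", "A" * 85, "I1", "CCC", 20.0]]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "label"])
        t = read_bioactivity_csv(path, {"label_unit": "percent_activity"})
        assert t.df.label[0] == pytest.approx(6.30103, abs=1e-4)
        assert t.df.label[1] > t.df.label[0]  # less residual activity = more potent

    def test_missing_column_is_schema_error(self, tmp_path):
        rows = [["K0", "A" * 85, "I0", 7.0]]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "label"])
        with pytest.raises(SchemaError):
            read_bioactivity_csv(path)

    def test_nonpositive_kd_dropped(self, tmp_path):
        rows = [["K0", "A" * 85, "I0", "CC", -5.0],
                ["K0", "A" * 85, "I1", "CCC", 10.0]]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "label"])
        t = read_bioactivity_csv(path, {"label_unit": "Kd_nM"})
        assert len(t) == 1 and t.df.inhibitor_id[0] == "I1"

    def test_duplicates_rejected_then_aggregated(self, tmp_path):
        rows = [["K0", "A" * 85, "I0", "CC", 6.0],
                ["K0", "A" * 85, "I0", "CC", 8.0]]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "label"])
        with pytest.raises(SchemaError):
            read_bioactivity_csv(path)
        t = read_bioactivity_csv(path, duplicates="mean")
        assert len(t) == 1 and t.df.label[0] == pytest.approx(7.0)

    def test_shipped_adapter_configs_load_and_apply(self, tmp_path):
        from pathlib import Path
        from kinleak.datasets import load_schema_config
        cfg_dir = Path(__file__).resolve().parents[1] / "configs"
        for name in ("anastassiadis", "christmann_franck", "davis", "elkins"):
            cfg = load_schema_config(cfg_dir / f"{name}.yaml")
            assert "label_unit" in cfg
        davis = load_schema_config(cfg_dir / "davis.yaml")
        rows = [["K0", "A" * 85, "I0", "CC", 1.0]]
        path = self._write(tmp_path, rows, ["kinase_id", "klifs_sequence",
                                            "inhibitor_id", "smiles", "Kd_nM"])
        t = read_bioactivity_csv(path, davis)
        assert t.df.label[0] == pytest.approx(9.0)

    def test_column_mapping(self, tmp_path):
        rows = [["K0", "A" * 85, "I0", "CC", 7.5]]
        path = self._write(tmp_path, rows, ["kin", "pocket", "cpd", "smi", "val"])
        t = read_bioactivity_csv(path, {
            "columns": {"kinase_id": "kin", "klifs_sequence": "pocket",
                        "inhibitor_id": "cpd", "smiles": "smi", "label": "val"},
            "label_unit": "pAct"})
        assert t.df.label[0] == 7.5
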
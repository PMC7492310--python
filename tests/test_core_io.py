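"""Domain types, activity transforms and file round trips."""

import io
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qsarkit.core import (
    ActivitySeries,
    DescriptorTable,
    DomainError,
    LinearModel,
    LoadError,
    QSARDataset,
    ic50_uM_from_pic50,
    pic50_from_ic50_uM,
)
from qsarkit.io import (
    designed_compounds,
    load_activity,
    load_descriptor_table,
    load_model,
    reference_model,
    reference_y_randomization,
    save_descriptor_table,
    save_model,
)


class TestActivityTransforms:
    @pytest.mark.parametrize(
        "ic50_uM, pic50",
        [
            (4.87, 5.3124),  # most potent dataset compound
            (97.18, 4.0124),  # least potent dataset compound
            (1_000_000.0, 0.0),  # 1 M
        ],
    )
    def test_pic50_from_ic50(self, ic50_uM, pic50):
        assert pic50_from_ic50_uM(ic50_uM) == pytest.approx(pic50, abs=1e-4)

    @pytest.mark.parametrize(
        "pic50, ic50_uM",
        [(5.8668, 1.3589), (6.0, 1.0), (5.4049, 3.9365)],
    )
    def test_ic50_from_pic50(self, pic50, ic50_uM):
        assert ic50_uM_from_pic50(pic50) == pytest.approx(ic50_uM, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_nonpositive_ic50_rejected(self, bad):
        with pytest.raises(DomainError):
            pic50_from_ic50_uM(bad)

    def test_nonfinite_pic50_rejected(self):
        with pytest.raises(DomainError):
            ic50_uM_from_pic50(np.inf)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_round_trip_identity(self, ic50):
        back = ic50_uM_from_pic50(pic50_from_ic50_uM(ic50))
        assert back == pytest.approx(ic50, rel=1e-9)

    def test_strictly_decreasing(self):
        grid = np.logspace(-3, 6, 50)
        vals = pic50_from_ic50_uM(grid)
        assert np.all(np.diff(vals) < 0)

    def test_designed_compound_table_is_self_consistent(self):
        # every printed (pIC50, IC50) pair agrees with the transform to 0.001 uM
        table = designed_compounds()
        back = ic50_uM_from_pic50(table["pIC50"].to_numpy())
        assert np.all(np.abs(back - table["IC50_uM"].to_numpy()) <= 1e-3)


class TestDescriptorTable:
    def test_load_toy_csv(self):
        csv = "Name,d1,d2\nc1,1.0,2.0\nc2,3.0,4.0\nc3,5.0,6.0\n"
        table = load_descriptor_table(io.StringIO(csv))
        assert table.shape == (3, 2)
        assert table.descriptor_names == ["d1", "d2"]
        assert table.compound_ids == ["c1", "c2", "c3"]

    def test_save_load_round_trip(self, tmp_path):
        table = DescriptorTable.from_arrays(
            ["a", "b"], ["d1", "d2"], [[1.123456789012, 2.0], [3.0, 4.0]]
        )
        path = tmp_path / "t.csv"
        save_descriptor_table(table, path)
        again = load_descriptor_table(path)
        assert again.equals(table)

    def test_na_cell_rejected_with_location(self):
        csv = "Name,d1,d2\nc1,1.0,NA\nc2,3.0,4.0\n"
        with pytest.raises(LoadError, match="NA.*d2.*c1"):
            load_descriptor_table(io.StringIO(csv))

    def test_duplicate_ids_rejected(self):
        csv = "Name,d1\nc1,1.0\nc1,2.0\n"
        with pytest.raises(LoadError, match="duplicate"):
            load_descriptor_table(io.StringIO(csv))

    def test_duplicate_descriptor_rejected(self):
        with pytest.raises(LoadError, match="duplicate"):
            DescriptorTable(
                pd.DataFrame([[1.0, 2.0]], index=["c1"], columns=["d", "d"])
            )

    def test_select_preserves_requested_order(self):
        table = DescriptorTable.from_arrays(["a"], ["d1", "d2", "d3"], [[1, 2, 3]])
        assert table.select(["d3", "d1"]).descriptor_names == ["d3", "d1"]

    def test_unknown_column_named_in_error(self):
        table = DescriptorTable.from_arrays(["a"], ["d1"], [[1.0]])
        with pytest.raises(DomainError, match="nope"):
            table.select(["nope"])


class TestActivityIO:
    def test_ic50_column_converted(self):
        csv = "Name,IC50_uM\nc1,1.0\nc2,10.0\n"
        act = load_activity(io.StringIO(csv))
        assert act.values == pytest.approx([6.0, 5.0])

    def test_pic50_column_passthrough(self):
        csv = "Name,pIC50\nc1,5.5\n"
        assert load_activity(io.StringIO(csv)).values == pytest.approx([5.5])

    def test_unknown_header_rejected(self):
        with pytest.raises(LoadError):
            load_activity(io.StringIO("Name,activity\nc1,5.5\n"))


class TestLinearModelIO:
    def test_bundled_model_contents(self, eq2):
        assert eq2.n_descriptors == 5
        assert eq2.intercept == 6.319854761
        assert eq2.coefficient("ETA_dBetaP") == 12.790319005

    def test_save_load_bit_identical(self, tmp_path, eq2):
        path = tmp_path / "m.json"
        save_model(eq2, path)
        again = load_model(path)
        assert again.descriptor_names == eq2.descriptor_names
        assert again.coefficients == eq2.coefficients  # exact float equality
        assert again.intercept == eq2.intercept

    def test_missing_intercept_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"descriptors": ["a"], "coefficients": [1.0]}))
        with pytest.raises(LoadError, match="intercept"):
            load_model(path)

    def test_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps({"descriptors": ["a", "b"], "coefficients": [1.0], "intercept": 0})
        )
        with pytest.raises(LoadError, match="coefficient"):
            load_model(path)

    def test_predict_joins_by_name_not_position(self, eq2):
        rows = DescriptorTable.from_arrays(
            ["q"], ["L3i", "nS", "VR1_Dze", "GATS5s", "ETA_dBetaP"], [[0, 0, 0, 0, 0]]
        )
        assert eq2.predict(rows).values[0] == pytest.approx(6.319854761)

    def test_unit_descriptor_change_moves_prediction_by_coefficient(self, eq2):
        base = {n: 1.0 for n in eq2.descriptor_names}
        bumped = dict(base, nS=2.0)
        rows = DescriptorTable(pd.DataFrame([base, bumped], index=["r0", "r1"]))
        pred = eq2.predict(rows).values
        assert pred[1] - pred[0] == pytest.approx(-0.124851343)

    def test_missing_descriptor_named_in_error(self, eq2):
        rows = DescriptorTable.from_arrays(["q"], ["nS"], [[1.0]])
        with pytest.raises(DomainError, match="GATS5s"):
            eq2.predict(rows)


class TestQSARDataset:
    def test_join_is_order_insensitive(self):
        table = DescriptorTable.from_arrays(["a", "b"], ["d"], [[1.0], [2.0]])
        act = ActivitySeries.from_values(["b", "a"], [5.0, 4.0])
        ds = QSARDataset(table, act)
        assert ds.activity.compound_ids == ["a", "b"]
        assert ds.activity.values == pytest.approx([4.0, 5.0])

    def test_id_mismatch_rejected(self):
        table = DescriptorTable.from_arrays(["a"], ["d"], [[1.0]])
        act = ActivitySeries.from_values(["z"], [5.0])
        with pytest.raises(DomainError, match="mismatch"):
            QSARDataset(table, act)

    def test_membership_subsets(self):
        table = DescriptorTable.from_arrays(["a", "b", "c"], ["d"], [[1], [2], [3]])
        act = ActivitySeries.from_values(["a", "b", "c"], [4, 5, 6])
        ds = QSARDataset(table, act).with_membership(["a", "c"], ["b"])
        X_tr, y_tr = ds.train()
        assert X_tr.compound_ids == ["a", "c"]
        assert y_tr.values == pytest.approx([4, 6])


class TestBundledReferenceData:
    def test_y_randomization_reference_shape(self):
        frame = reference_y_randomization()
        assert list(frame.columns) == ["R", "R2", "Q2"]
        assert len(frame) == 11  # original + 10 scrambled refits
        assert frame.loc["original", "R2"] == pytest.approx(0.739706)

    def test_reference_model_metadata_names_descriptors(self):
        meta = reference_model().metadata
        assert set(meta["descriptors"]) == {"nS", "GATS5s", "VR1_Dze", "ETA_dBetaP", "L3i"}
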
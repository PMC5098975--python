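"""Loading, validation, transformation and index construction."""

import io

import numpy as np
import pandas as pd
import pytest

from riiv.data import (
    Dataset,
    TransformConfig,
    build_indices,
    inverse_transform_y,
    load_long_csv,
    prepare_latent,
    transform,
    PreparedData,
)
from riiv.errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateDataError,
)

HEADER = "individual_id,week,batch,mass,temperature,am_pm,activity\n"


def _csv(rows: str):
    return io.StringIO(HEADER + rows)


TOY = (
    "f1,1,0,0.31,25.9,0,12\n"
    "f1,2,0,0.31,26.1,1,30\n"
    "f2,1,1,0.42,26.0,0,7\n"
    "f2,2,1,0.42,25.8,1,0\n"
)


class TestLoadLongCsv:
    def test_round_trip_identity(self):
        ds = load_long_csv(_csv(TOY))
        assert len(ds) == 4
        assert ds.n_dropped == 0
        assert ds.levels["individual_id"] == ["f1", "f2"]
        assert list(ds.df["activity"]) == [12, 30, 7, 0]

    def test_missing_field_row_is_dropped_and_counted(self):
        rows = TOY.replace("f2,1,1,0.42,26.0,0,7", "f2,1,1,,26.0,0,7")
        ds = load_long_csv(_csv(rows))
        assert len(ds) == 3
        assert ds.n_dropped == 1

    def test_negative_activity_rejected(self):
        rows = TOY.replace("f2,1,1,0.42,26.0,0,7", "f2,1,1,0.42,26.0,0,-1")
        with pytest.raises(DataValidationError, match="negative activity"):
            load_long_csv(_csv(rows))

    def test_missing_column_is_configuration_error(self):
        bad = io.StringIO("id,week\nf1,1\n")
        with pytest.raises(ConfigurationError, match="individual_id"):
            load_long_csv(bad)

    def test_column_map_renames(self):
        raw = io.StringIO(
            "fish,wk,batch,mass,temperature,am_pm,activity\n"
            "f1,1,0,0.3,26,0,5\nf2,1,1,0.4,26,1,9\n"
        )
        ds = load_long_csv(raw, column_map={"individual_id": "fish",
                                            "week": "wk"})
        assert ds.levels["individual_id"] == ["f1", "f2"]

    def test_non_numeric_mass_names_row(self):
        rows = TOY.replace("f2,1,1,0.42,26.0,0,7", "f2,1,1,heavy,26.0,0,7")
        with pytest.raises(DataValidationError, match="mass"):
            load_long_csv(_csv(rows))


class TestTransform:
    def test_log_mode_hand_oracle(self):
        """Counts (10, 20, 40): equally log-spaced, so Z(log) = (-1, 0, 1)."""
        df = pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "week": [1, 2, 3],
                "batch": [0, 0, 1],
                "mass": [0.3, 0.35, 0.4],
                "temperature": [25.0, 26.0, 27.0],
                "am_pm": [0, 1, 0],
                "activity": [10, 20, 40],
            }
        )
        ds = Dataset(df=df)
        prep = transform(ds, TransformConfig(log_mode="log"))
        np.testing.assert_allclose(prep.y, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_response_is_standardized(self, small_sim):
        df, _ = small_sim
        ds = Dataset(df=df[list(df.columns[:7])])
        prep = transform(ds)
        assert abs(prep.y.mean()) < 1e-10
        assert abs(prep.y.std(ddof=1) - 1.0) < 1e-10
        for col in (1, 3):  # z-mass, z-temperature in the mean design
            assert abs(prep.x_mean[:, col].mean()) < 1e-10
            assert abs(prep.x_mean[:, col].std(ddof=1) - 1.0) < 1e-10

    def test_week_centred_on_second_week(self):
        ds = load_long_csv(_csv(
            "f1,1,0,0.3,26,0,5\nf1,2,0,0.31,26,1,6\n"
            "f2,3,1,0.4,25,0,7\nf2,2,1,0.41,25,1,8\n"
        ))
        prep = transform(ds)
        assert prep.transform_record["week_centre"] == 2
        np.testing.assert_allclose(
            sorted(set(prep.x_mean[:, 2])), [-1.0, 0.0, 1.0]
        )

    def test_zero_variance_column_is_degenerate(self):
        ds = load_long_csv(_csv(
            "f1,1,0,0.3,26,0,5\nf2,1,1,0.3,26,1,7\n"
        ))
        with pytest.raises(DegenerateDataError, match="mass"):
            transform(ds)

    def test_log_of_zero_count_instructs_log1p(self):
        ds = load_long_csv(_csv(TOY))  # contains a zero count
        with pytest.raises(DegenerateDataError, match="log1p"):
            transform(ds, TransformConfig(log_mode="log"))

    @pytest.mark.parametrize("log_mode", ["log1p", "log"])
    def test_round_trip_recovers_counts(self, log_mode):
        rows = TOY if log_mode == "log1p" else TOY.replace(
            "f2,2,1,0.42,25.8,1,0", "f2,2,1,0.42,25.8,1,3"
        )
        ds = load_long_csv(_csv(rows))
        prep = transform(ds, TransformConfig(log_mode=log_mode))
        back = inverse_transform_y(prep.y, prep.transform_record)
        np.testing.assert_allclose(
            back, ds.df["activity"].to_numpy(float), atol=1e-9
        )


class TestBuildIndices:
    def test_full_cross(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a"] * 3 + ["b"] * 3,
                "week": [1, 2, 3, 1, 2, 3],
            }
        )
        idx = build_indices(df)
        assert idx.n_id == 2
        assert idx.n_cell == 6

    def test_single_id_single_week(self):
        df = pd.DataFrame({"individual_id": ["a", "a"], "week": [1, 1]})
        idx = build_indices(df)
        assert idx.n_id == 1
        assert idx.n_cell == 1

    def test_study_scale_design_with_missing_bursts(self, small_sim):
        df, _ = small_sim
        idx = build_indices(df)
        assert idx.n_id == 12
        assert idx.n_cell <= 36
        # nesting: each cell maps to exactly one individual
        for k in range(idx.n_cell):
            owners = set(idx.j_index[idx.k_index == k])
            assert owners == {idx.cell_to_id[k]}

    def test_indices_dense_and_order_stable(self, small_sim):
        df, _ = small_sim
        a = build_indices(df)
        b = build_indices(df)
        np.testing.assert_array_equal(a.j_index, b.j_index)
        np.testing.assert_array_equal(a.k_index, b.k_index)
        assert set(a.j_index) == set(range(a.n_id))
        assert set(a.k_index) == set(range(a.n_cell))


def test_prepared_data_npz_round_trip(tmp_path, small_prepared):
    path = tmp_path / "prep.npz"
    small_prepared.to_npz(path)
    back = PreparedData.from_npz(path)
    np.testing.assert_array_equal(back.y, small_prepared.y)
    np.testing.assert_array_equal(back.x_mean, small_prepared.x_mean)
    np.testing.assert_array_equal(back.j_index, small_prepared.j_index)
    assert back.transform_record == small_prepared.transform_record


def test_prepare_latent_keeps_response_scale(small_sim):
    df, truth = small_sim
    prep = prepare_latent(df)
    np.testing.assert_array_equal(prep.y, df["y_latent"].to_numpy())
    assert abs(prep.x_mean[:, 1].mean()) < 1e-10  # mass still standardized
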
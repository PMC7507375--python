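import numpy as np
import pandas as pd
import pytest

from icefalcon import (
    TwinDataError,
    build_regression_table,
    drop_incomplete_pairs,
    preset_scenarios,
    read_twin_csv,
    simulate,
    standardize,
)
from icefalcon.dataset import TwinPairDataset

from conftest import make_dataset


class TestReadTwinCsv:
    def test_minimal_valid_file(self, tmp_path, two_pair_dataset):
        path = tmp_path / "twins.csv"
        two_pair_dataset.to_csv(path)
        ds = read_twin_csv(path, trait_names=("x", "y"))
        assert ds.n_pairs == 2
        assert ds.pair_counts() == {"MZ": 1, "DZ": 1}

    def test_zygosity_normalized_case_insensitively(self, tmp_path):
        path = tmp_path / "twins.csv"
        path.write_text(
            "pair_id,twin_index,zygosity,age,height,x,y\n"
            "p1,1,mz,50,160,1.0,2.0\np1,2,Mz,50,161,1.5,2.5\n"
        )
        ds = read_twin_csv(path, trait_names=("x", "y"))
        assert set(ds.data["zygosity"]) == {"MZ"}

    def test_unpaired_individual_names_pair_id(self, tmp_path):
        path = tmp_path / "twins.csv"
        path.write_text(
            "pair_id,twin_index,zygosity,age,height,x,y\n"
            "p1,1,MZ,50,160,1.0,2.0\np1,2,MZ,50,161,1.5,2.5\n"
            "lonely,1,DZ,44,170,0.0,0.0\n"
        )
        with pytest.raises(TwinDataError, match="lonely"):
            read_twin_csv(path, trait_names=("x", "y"))

    def test_unknown_zygosity_code_rejected(self, tmp_path):
        path = tmp_path / "twins.csv"
        path.write_text(
            "pair_id,twin_index,zygosity,age,height,x,y\n"
            "p1,1,XX,50,160,1.0,2.0\np1,2,XX,50,161,1.5,2.5\n"
        )
        with pytest.raises(TwinDataError, match="zygosity"):
            read_twin_csv(path, trait_names=("x", "y"))

    def test_schema_maps_foreign_column_names(self, tmp_path):
        path = tmp_path / "twins.csv"
        path.write_text(
            "FamID,Member,Zyg,age,height,LM\n"
            "f1,1,MZ,50,160,40.2\nf1,2,MZ,50,161,41.0\n"
        )
        ds = read_twin_csv(
            path,
            schema={"pair_id": "FamID", "twin_index": "Member",
                    "zygosity": "Zyg", "lean_mass": "LM"},
            trait_names=("lean_mass",),
        )
        assert ds.data.loc[0, "lean_mass"] == 40.2

    def test_simulated_data_round_trips(self, tmp_path, cohort_scenarios):
        ds = simulate(cohort_scenarios["mixed"], seed=5)
        path = tmp_path / "sim.csv"
        ds.to_csv(path)
        back = read_twin_csv(path, trait_names=ds.trait_names)
        for v in ds.variables:
            np.testing.assert_allclose(
                back.data[v], ds.data[v], rtol=0, atol=1e-12
            )


class TestValidation:
    def test_duplicate_twin_index_rejected(self):
        with pytest.raises(TwinDataError, match="duplicated"):
            make_dataset(
                [
                    ("p1", 1, "MZ", {"x": 1.0}),
                    ("p1", 1, "MZ", {"x": 2.0}),
                ]
            )

    def test_mixed_zygosity_within_pair_rejected(self):
        with pytest.raises(TwinDataError, match="inconsistent zygosity"):
            make_dataset(
                [
                    ("p1", 1, "MZ", {"x": 1.0}),
                    ("p1", 2, "DZ", {"x": 2.0}),
                ]
            )

    def test_non_finite_values_rejected(self):
        with pytest.raises(TwinDataError, match="non-finite"):
            make_dataset(
                [
                    ("p1", 1, "MZ", {"x": np.inf}),
                    ("p1", 2, "MZ", {"x": 2.0}),
                ]
            )


class TestDropIncompletePairs:
    def test_pair_with_missing_member_value_removed(self):
        ds = make_dataset(
            [
                ("p1", 1, "MZ", {"x": 1.0, "y": 1.0}),
                ("p1", 2, "MZ", {"x": np.nan, "y": 1.0}),
                ("p2", 1, "DZ", {"x": 0.0, "y": 2.0}),
                ("p2", 2, "DZ", {"x": 0.5, "y": 2.0}),
                ("p3", 1, "MZ", {"x": 0.1, "y": 0.0}),
                ("p3", 2, "MZ", {"x": 0.2, "y": 0.0}),
            ]
        )
        kept, removed = drop_incomplete_pairs(ds, ["x", "y"])
        assert kept.n_pairs == 2 and removed == 1

    def test_no_missingness_is_identity(self, two_pair_dataset):
        kept, removed = drop_incomplete_pairs(two_pair_dataset, ["x", "y"])
        assert removed == 0
        pd.testing.assert_frame_equal(kept.data, two_pair_dataset.data)

    def test_all_pairs_incomplete_raises(self):
        ds = make_dataset(
            [
                ("p1", 1, "MZ", {"x": np.nan}),
                ("p1", 2, "MZ", {"x": 1.0}),
            ]
        )
        with pytest.raises(TwinDataError, match="no complete pairs"):
            drop_incomplete_pairs(ds, ["x"])

    def test_random_blanking_matches_brute_force(self, cohort_scenarios, rng):
        ds = simulate(cohort_scenarios["null"], seed=17)
        df = ds.data.copy()
        hit = rng.choice(len(df), size=10, replace=False)
        df.loc[df.index[hit], "outcome"] = np.nan
        blanked = TwinPairDataset(df, ds.trait_names, ds.covariate_names)
        kept, removed = drop_incomplete_pairs(blanked, ["outcome"])
        affected = df.loc[df["outcome"].isna(), "pair_id"].nunique()
        assert removed == affected
        assert kept.n_pairs == ds.n_pairs - affected


class TestStandardize:
    def test_moments_after_transform(self):
        ds = make_dataset(
            [
                ("p1", 1, "MZ", {"x": 1.0}),
                ("p1", 2, "MZ", {"x": 2.0}),
                ("p2", 1, "DZ", {"x": 3.0}),
                ("p2", 2, "DZ", {"x": 2.0}),
            ]
        )
        out = standardize(ds, ["x"])
        vals = out.data["x"]
        assert abs(vals.mean()) < 1e-12
        assert abs(vals.std(ddof=1) - 1) < 1e-12
        mean, sd = out.standardization["x"]
        np.testing.assert_allclose([mean, sd], [2.0, np.sqrt(2 / 3)])

    def test_idempotent_on_z_scores(self, cohort_scenarios):
        ds = simulate(cohort_scenarios["null"], seed=3)
        once = standardize(ds, ["exposure"])
        twice = standardize(once, ["exposure"])
        np.testing.assert_allclose(
            twice.data["exposure"], once.data["exposure"], atol=1e-12
        )

    def test_pooled_moments_match_flat_recomputation(self, cohort_scenarios):
        ds = simulate(cohort_scenarios["confounding_weak"], seed=8)
        out = standardize(ds, ["outcome"])
        flat = ds.data["outcome"].to_numpy()
        mean, sd = out.standardization["outcome"]
        assert mean == pytest.approx(flat.mean(), abs=1e-12)
        assert sd == pytest.approx(flat.std(ddof=1), abs=1e-12)

    def test_zero_variance_names_variable(self):
        ds = make_dataset(
            [
                ("p1", 1, "MZ", {"x": 1.0}),
                ("p1", 2, "MZ", {"x": 1.0}),
            ]
        )
        with pytest.raises(TwinDataError, match="'x'"):
            standardize(ds, ["x"])


class TestBuildRegressionTable:
    def test_swap_symmetry_single_pair(self):
        ds = make_dataset(
            [
                ("p1", 1, "MZ", {"x": 3.0, "y": 1.0}),
                ("p1", 2, "MZ", {"x": 7.0, "y": 2.0}),
                ("p2", 1, "DZ", {"x": 0.0, "y": 0.0}),
                ("p2", 2, "DZ", {"x": 1.0, "y": 0.5}),
            ]
        )
        tab = build_regression_table(ds, "y", "x")
        rows = tab.data[tab.data["cluster_id"] == "p1"]
        assert sorted(zip(rows["x_self"], rows["x_cotwin"])) == [
            (3.0, 7.0),
            (7.0, 3.0),
        ]

    def test_two_rows_per_pair(self, cohort_scenarios):
        ds = simulate(cohort_scenarios["null"], seed=1)
        tab = build_regression_table(ds, "outcome", "exposure", ("age", "height"))
        assert len(tab.data) == 2 * ds.n_pairs

    def test_outcome_equals_exposure_rejected(self, two_pair_dataset):
        with pytest.raises(TwinDataError, match="must differ"):
            build_regression_table(two_pair_dataset, "x", "x")

    def test_matches_manual_stacked_assembly(self, cohort_scenarios):
        """Regressing y_self on x_cotwin equals the hand-stacked regression
        of twin 1's y on twin 2's x concatenated with the reverse."""
        ds = simulate(cohort_scenarios["confounding_strong"], seed=4)
        tab = build_regression_table(ds, "outcome", "exposure")
        wide = ds.data.sort_values(["pair_id", "twin_index"])
        x = wide["exposure"].to_numpy().reshape(-1, 2)
        y = wide["outcome"].to_numpy().reshape(-1, 2)
        manual_y = np.concatenate([y[:, 0], y[:, 1]])
        manual_x = np.concatenate([x[:, 1], x[:, 0]])
        b_manual = np.polyfit(manual_x, manual_y, 1)[0]
        d = tab.data
        b_table = np.polyfit(d["x_cotwin"], d["y_self"], 1)[0]
        assert b_table == pytest.approx(b_manual, abs=1e-12)

    def test_double_entry_invariant_under_twin_relabeling(self, cohort_scenarios):
        ds = simulate(cohort_scenarios["mixed"], seed=6)
        flipped = ds.data.copy()
        flipped["twin_index"] = 3 - flipped["twin_index"]
        ds2 = TwinPairDataset(flipped, ds.trait_names, ds.covariate_names)
        t1 = build_regression_table(ds, "outcome", "exposure")
        t2 = build_regression_table(ds2, "outcome", "exposure")
        key = ["cluster_id", "x_self"]
        a = t1.data.sort_values(key).reset_index(drop=True)
        b = t2.data.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_standardize_commutes_with_double_entry(self, cohort_scenarios):
        ds = simulate(cohort_scenarios["causal_weak"], seed=9)
        tab_then_std = build_regression_table(
            standardize(ds, ["exposure", "outcome"]), "outcome", "exposure"
        )
        tab_raw = build_regression_table(ds, "outcome", "exposure")
        mean, sd = (
            ds.data["exposure"].mean(),
            ds.data["exposure"].std(ddof=1),
        )
        np.testing.assert_allclose(
            tab_then_std.data["x_cotwin"],
            (tab_raw.data["x_cotwin"] - mean) / sd,
            atol=1e-12,
        )
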
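import numpy as np
import pandas as pd
import pytest

from phquant import io as pio
from phquant.calibrate import fit_calibration
from phquant.experiment import (
    cells_to_pH,
    compare_groups,
    one_way_dunnett,
    summarize_conditions,
)
from phquant.quantify import measurements_frame, quantify_field
from phquant.simulate import SimConfig, Treatment, generate_experiment
from phquant.weakacid import BUILTIN_SPECIES, PartitionQuery, intracellular_total

BUTYRATE = BUILTIN_SPECIES["butyrate"]


def _ph_table(ph_by_condition, manifest_rows, n=15, sd=0.0, seed=0):
    """Hand-built per-cell pH table + matching manifest."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, ph in ph_by_condition.items():
        for i in range(n):
            rows.append(
                {
                    "field_id": f"{cond}_f000",
                    "cell_id": i + 1,
                    "ratio": 1.0,
                    "pH": ph + (rng.normal(0, sd) if sd else 0.0),
                    "extrapolated": False,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    return pd.DataFrame(rows), manifest


def _manifest_row(cond, pH_E, treatment="control", species="", conc=0.0):
    return {
        "field_id": f"{cond}_f000",
        "condition": cond,
        "treatment": treatment,
        "species": species,
        "conc_E_mM": conc,
        "pH_E": pH_E,
        "true_pH_I": np.nan,
        "path_ex405": "",
        "path_ex488": "",
        "path_labels": "",
    }


class TestCellsToPH:
    def test_round_trip_through_fitted_curve(self, fitted_curve):
        df = pd.DataFrame(
            {
                "field_id": ["f0"] * 3,
                "cell_id": [1, 2, 3],
                "ratio": fitted_curve.predict(np.array([6.5, 7.0, 7.5])),
                "qc_pass": [True, True, False],
            }
        )
        out = cells_to_pH(df, fitted_curve)
        assert len(out) == 2  # QC-failed cell dropped upstream
        assert out["pH"].tolist() == pytest.approx([6.5, 7.0], abs=1e-9)
        assert not out["extrapolated"].any()

    def test_missing_curve_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            cells_to_pH(pd.DataFrame({"ratio": [1.0], "qc_pass": [True]}), None)


class TestSummarizeConditions:
    def test_no_gradient_identity(self):
        ph, manifest = _ph_table(
            {"but7.2": 7.2},
            [_manifest_row("but7.2", 7.2, "butyrate", "butyrate", 10.0)],
        )
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_conc_I_mM"] == pytest.approx(10.0, abs=1e-9)
        assert row["sem_pH_I"] == pytest.approx(0.0, abs=1e-12)
        assert row["n_cells"] == 15

    def test_mild_gradient_concentration(self):
        ph, manifest = _ph_table(
            {"but6.5": 7.2},
            [_manifest_row("but6.5", 6.5, "butyrate", "butyrate", 10.0)],
        )
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        assert out["mean_conc_I_mM"].iloc[0] == pytest.approx(49.3, rel=2e-3)

    def test_consistency_with_direct_weakacid_call(self):
        ph, manifest = _ph_table(
            {"but6.0": 7.1},
            [_manifest_row("but6.0", 6.0, "butyrate", "butyrate", 10.0)],
            sd=0.1,
            seed=3,
        )
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        direct = np.mean(
            [
                intracellular_total(
                    PartitionQuery(BUTYRATE, pH_E=6.0, pH_I=p, conc_E=10.0)
                ).conc_I
                for p in ph["pH"]
            ]
        )
        assert out["mean_conc_I_mM"].iloc[0] == direct

    def test_mean_ph_mode_below_per_cell(self):
        """Jensen's inequality: the partition model is convex in pH_I."""
        ph, manifest = _ph_table(
            {"but6.0": 7.1},
            [_manifest_row("but6.0", 6.0, "butyrate", "butyrate", 10.0)],
            sd=0.15,
            seed=5,
        )
        per_cell = summarize_conditions(ph, manifest, species=BUTYRATE, mode="per_cell")
        mean_ph = summarize_conditions(ph, manifest, species=BUTYRATE, mode="mean_ph")
        assert mean_ph["mean_conc_I_mM"].iloc[0] < per_cell["mean_conc_I_mM"].iloc[0]

    def test_untreated_condition_has_no_concentration(self):
        ph, manifest = _ph_table({"ctrl7.0": 7.2}, [_manifest_row("ctrl7.0", 7.0)])
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        assert np.isnan(out["mean_conc_I_mM"].iloc[0])

    def test_extrapolated_cells_excluded_from_concentration(self):
        ph, manifest = _ph_table(
            {"but6.5": 7.2},
            [_manifest_row("but6.5", 6.5, "butyrate", "butyrate", 10.0)],
        )
        ph.loc[ph.index[:5], "extrapolated"] = True
        ph.loc[ph.index[:5], "pH"] = 8.0  # clamped values must not leak into conc
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        assert out["mean_conc_I_mM"].iloc[0] == pytest.approx(49.3, rel=2e-3)
        assert out["extrapolated_fraction"].iloc[0] == pytest.approx(5 / 15)

    def test_canonical_ordering_and_missing_metadata(self):
        ph, manifest = _ph_table(
            {"b": 7.0, "a": 7.1},
            [
                _manifest_row("b", 7.0, "butyrate", "butyrate", 10.0),
                _manifest_row("a", 6.5),
            ],
        )
        out = summarize_conditions(ph, manifest, species=BUTYRATE)
        assert out["pH_E"].tolist() == [6.5, 7.0]
        bad_manifest = manifest.drop(columns=["pH_E"]).assign(pH_E=[np.nan, 6.5])
        with pytest.raises(ValueError, match="pH_E"):
            summarize_conditions(ph, bad_manifest, species=BUTYRATE)


class TestCompareGroups:
    def _two_by_two(self, delta, n=15, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for pH_E in (6.5, 7.0):
            for treatment, shift in (("control", 0.0), ("butyrate", -delta)):
                for _ in range(n):
                    rows.append(
                        {"pH_E": pH_E, "treatment": treatment, "pH": 7.2 + shift + rng.normal(0, sd)}
                    )
        return pd.DataFrame(rows)

    def test_bonferroni_dominance(self):
        res = compare_groups(self._two_by_two(0.1, seed=1))
        assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-15).all()
        assert (res.contrasts["p_adj"] <= 1.0).all()
        assert res.n_contrasts == 2

    def test_strong_effect_detected(self):
        res = compare_groups(self._two_by_two(0.3, seed=2))
        assert res.contrasts["significant"].all()
        assert res.anova.loc["C(treatment)", "PR(>F)"] < 1e-6

    def test_null_not_rejected_on_average(self):
        """Type-I error of the per-level contrast stays near nominal under the null."""
        rejections = 0
        for seed in range(200):
            res = compare_groups(self._two_by_two(0.0, seed=seed))
            rejections += int((res.contrasts["p_raw"] < 0.05).iloc[0])
        assert 0.01 <= rejections / 200 <= 0.10

    def test_single_group_degenerate(self):
        df = pd.DataFrame({"pH_E": [7.0] * 4, "treatment": ["a"] * 4, "pH": [7.0, 7.1, 7.2, 7.3]})
        df2 = pd.concat([df, df.assign(treatment="a")])  # group vs itself: no contrast pairs
        res = compare_groups(pd.concat([df, df]))
        assert res.n_contrasts == 0

    def test_underpowered_cell_skipped_with_warning(self):
        df = self._two_by_two(0.2, n=15, seed=3)
        df = df[~((df["pH_E"] == 6.5) & (df["treatment"] == "butyrate"))]
        solo = pd.DataFrame({"pH_E": [6.5], "treatment": ["butyrate"], "pH": [6.9]})
        with pytest.warns(UserWarning, match="skipped"):
            res = compare_groups(pd.concat([df, solo], ignore_index=True))
        assert res.n_contrasts == 1

    def test_end_to_end_ordering(self, tmp_path, sensor):
        """Butyrate arms with lower true cytosolic pH come out lower after the full chain."""
        treatments = []
        for pH_E in (5.5, 6.5):
            treatments.append(Treatment(f"ctrl_{pH_E}", pH_E=pH_E, true_pH_I=7.2))
            treatments.append(
                Treatment(f"but_{pH_E}", pH_E=pH_E, true_pH_I=6.9, species="butyrate", conc_E_mM=10.0)
            )
        config = SimConfig(seed=23, treatments=tuple(treatments))
        from phquant.simulate import SensorModel, generate_experiment

        manifest, _ = generate_experiment(config, sensor, tmp_path / "exp")
        ms = []
        for _, row in manifest.iterrows():
            ms.extend(quantify_field(pio.load_field(row, root=tmp_path / "exp")))
        df = measurements_frame(ms)

        # calibration from an independently rendered buffer series, same seed family
        from phquant.simulate import generate_calibration_series

        cal_manifest, _ = generate_calibration_series(SimConfig(seed=24), sensor, tmp_path / "cal")
        cal_ms = []
        for _, row in cal_manifest.iterrows():
            cal_ms.extend(quantify_field(pio.load_field(row, root=tmp_path / "cal")))
        cal_df = measurements_frame(cal_ms).merge(
            cal_manifest[["field_id", "pH_E"]], on="field_id"
        )
        curve = fit_calibration(cal_df)

        ph = cells_to_pH(df, curve)
        summary = summarize_conditions(ph, manifest, species=BUTYRATE)
        for pH_E in (5.5, 6.5):
            sub = summary[summary["pH_E"] == pH_E].set_index("treatment")
            assert sub.loc["butyrate", "mean_pH_I"] < sub.loc["control", "mean_pH_I"]


class TestOneWayDunnett:
    def test_against_control(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "group": ["ctrl"] * 20 + ["lo"] * 20 + ["hi"] * 20,
                "y": np.concatenate(
                    [rng.normal(0, 1, 20), rng.normal(0.1, 1, 20), rng.normal(2.0, 1, 20)]
                ),
            }
        )
        out = one_way_dunnett(df, "y", "group", control="ctrl")
        assert set(out["group"]) == {"lo", "hi"}
        by = out.set_index("group")
        assert by.loc["hi", "p_adj"] < 0.001
        assert by.loc["lo", "p_adj"] > 0.1

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"group": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="control"):
            one_way_dunnett(df, "y", "group", control="zzz")
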
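"""End-to-end treatment analysis: ratios -> pH -> statistics -> SCFA load.

Converts per-cell 405/488 ratios from treatment conditions into pH via a
fitted calibration, summarizes each (buffer pH x treatment) condition
(mean +/- SEM over cells), tests the two factors with a fixed-effects ANOVA
plus Bonferroni-adjusted pairwise treatment contrasts within each buffer pH,
and applies the equilibrium weak-acid partition model to estimate the
intracellular SCFA concentration per condition.

Cells whose inversion was clamped (ratio outside the calibrated range) stay
in pH summaries, flagged, but are excluded from concentration estimates:
the partition model is exponential in pH, so clamped values would bias the
concentration far more than the pH mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from phquant.calibrate import RatiometricCalibration
from phquant.weakacid import PartitionQuery, WeakAcidSpecies, intracellular_total

__all__ = [
    "cells_to_pH",
    "summarize_conditions",
    "compare_groups",
    "one_way_dunnett",
    "ComparisonResult",
]


def cells_to_pH(
    measurements: pd.DataFrame,
    curve: RatiometricCalibration,
) -> pd.DataFrame:
    """Per-cell pH table from QC-passed measurements and a fitted calibration.

    Returns the input rows (QC-passed only) with ``pH`` and ``extrapolated``
    columns appended; deterministic.
    """
    if curve is None:
        raise ValueError("a fitted calibration curve is required")
    df = measurements[measurements["qc_pass"]].copy() if "qc_pass" in measurements.columns else measurements.copy()
    pH, flag = curve.inverse_predict(df["ratio"].to_numpy())
    df["pH"] = pH
    df["extrapolated"] = flag
    return df.reset_index(drop=True)


def _condition_conc(
    ph_values: np.ndarray,
    extrapolated: np.ndarray,
    species: WeakAcidSpecies,
    pH_E: float,
    conc_E: float,
    mode: str,
) -> float:
    usable = ph_values[~extrapolated]
    if usable.size == 0:
        return float("nan")
    if mode == "per_cell":
        concs = [
            intracellular_total(
                PartitionQuery(species=species, pH_E=pH_E, pH_I=float(p), conc_E=conc_E)
            ).conc_I
            for p in usable
        ]
        return float(np.mean(concs))
    if mode == "mean_ph":
        q = PartitionQuery(species=species, pH_E=pH_E, pH_I=float(usable.mean()), conc_E=conc_E)
        return float(intracellular_total(q).conc_I)
    raise ValueError(f"unknown mode {mode!r}; use 'per_cell' or 'mean_ph'")


def summarize_conditions(
    ph_table: pd.DataFrame,
    manifest: pd.DataFrame,
    species: Optional[WeakAcidSpecies] = None,
    mode: str = "per_cell",
) -> pd.DataFrame:
    """Per-condition pH summary and equilibrium intracellular SCFA estimate.

    ``ph_table`` must carry per-cell ``pH`` and ``extrapolated`` (from
    :func:`cells_to_pH`) plus ``field_id``; condition metadata (buffer pH,
    treatment, dose) is joined in from the manifest.  For conditions dosed
    with a weak acid (conc_E > 0), the intracellular concentration is the
    partition model applied per cell and averaged (``mode='per_cell'``,
    default) or applied once to the condition mean pH (``mode='mean_ph'``).
    """
    meta_cols = ["field_id", "condition", "treatment", "species", "conc_E_mM", "pH_E"]
    meta = manifest[meta_cols].copy()
    meta["field_id"] = meta["field_id"].astype(str)
    df = ph_table.copy()
    df["field_id"] = df["field_id"].astype(str)
    df = df.merge(meta, on="field_id", how="left", suffixes=("", "_manifest"))
    if df["pH_E"].isna().any():
        bad = sorted(df.loc[df["pH_E"].isna(), "field_id"].unique())
        raise ValueError(f"fields missing pH_E metadata in manifest: {bad}")

    rows = []
    for (cond, pH_E, treatment), grp in df.groupby(
        ["condition", "pH_E", "treatment"], dropna=False, sort=False
    ):
        ph = grp["pH"].to_numpy(dtype=float)
        extr = grp["extrapolated"].to_numpy(dtype=bool)
        conc_E = float(grp["conc_E_mM"].iloc[0]) if "conc_E_mM" in grp else 0.0
        sp = species
        if sp is None and isinstance(grp["species"].iloc[0], str) and grp["species"].iloc[0]:
            from phquant.weakacid import BUILTIN_SPECIES

            sp = BUILTIN_SPECIES.get(grp["species"].iloc[0])
        mean_conc = (
            _condition_conc(ph, extr, sp, float(pH_E), conc_E, mode)
            if (conc_E > 0 and sp is not None)
            else float("nan")
        )
        rows.append(
            {
                "condition": cond,
                "pH_E": float(pH_E),
                "treatment": treatment,
                "species": sp.name if (sp is not None and conc_E > 0) else "",
                "conc_E_mM": conc_E,
                "n_cells": int(len(grp)),
                "mean_pH_I": float(ph.mean()),
                "sem_pH_I": float(st.sem(ph)) if len(ph) >= 2 else float("nan"),
                "mean_conc_I_mM": mean_conc,
                "extrapolated_fraction": float(extr.mean()),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["pH_E", "treatment"], kind="mergesort").reset_index(drop=True)


@dataclass
class ComparisonResult:
    """Two-factor ANOVA table plus Bonferroni-adjusted pairwise contrasts."""

    anova: pd.DataFrame
    contrasts: pd.DataFrame  # pH_E, group1, group2, t, df, p_raw, p_adj
    n_contrasts: int


def compare_groups(ph_table: pd.DataFrame, alpha: float = 0.05) -> ComparisonResult:
    """Two-way fixed-effects ANOVA of per-cell pH on buffer pH x treatment.

    Type-II sums of squares (order-invariant for unbalanced designs); the
    pairwise treatment contrasts within each buffer-pH level use pooled-
    variance two-sample t tests, with the family-wise error controlled by
    multiplying each raw significance level by the number of contrasts
    (Bonferroni, capped at 1).  Design cells with fewer than 2 observations
    are skipped with a warning.
    """
    df = ph_table.copy()
    for col in ("pH_E", "treatment", "pH"):
        if col not in df.columns:
            raise ValueError(f"ph_table lacks required column {col!r}")
    factors = [c for c in ("pH_E", "treatment") if df[c].nunique() >= 2]
    if factors:
        terms = " * ".join(f"C({c})" for c in factors)
        model = smf.ols(f"pH ~ {terms}", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:  # degenerate design: a single group has nothing to test
        anova = pd.DataFrame(columns=["sum_sq", "df", "F", "PR(>F)"])

    records = []
    for pH_E, grp in df.groupby("pH_E", sort=True):
        treatments = sorted(grp["treatment"].unique())
        for t1, t2 in combinations(treatments, 2):
            x = grp.loc[grp["treatment"] == t1, "pH"].to_numpy()
            y = grp.loc[grp["treatment"] == t2, "pH"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                warnings.warn(
                    f"contrast {t1} vs {t2} at pH_E={pH_E} skipped: "
                    "fewer than 2 observations in a group",
                    stacklevel=2,
                )
                continue
            t_stat, p_raw = st.ttest_ind(x, y, equal_var=True)
            records.append(
                {
                    "pH_E": float(pH_E),
                    "group1": t1,
                    "group2": t2,
                    "mean1": float(x.mean()),
                    "mean2": float(y.mean()),
                    "t": float(t_stat),
                    "df": int(len(x) + len(y) - 2),
                    "p_raw": float(p_raw),
                }
            )
    contrasts = pd.DataFrame(
        records, columns=["pH_E", "group1", "group2", "mean1", "mean2", "t", "df", "p_raw"]
    )
    m = len(contrasts)
    contrasts["p_adj"] = np.minimum(contrasts["p_raw"] * max(m, 1), 1.0)
    contrasts["significant"] = contrasts["p_adj"] < alpha
    return ComparisonResult(anova=anova, contrasts=contrasts, n_contrasts=m)


def one_way_dunnett(
    values: pd.DataFrame,
    value_col: str,
    group_col: str,
    control: str,
) -> pd.DataFrame:
    """One-way ANOVA with Dunnett's many-to-one comparisons against a control.

    Generic utility for externally measured tables (e.g. plate-reader
    readouts); returns one row per non-control group with the Dunnett-
    adjusted p-value, plus the overall ANOVA F and p attached to every row.
    """
    groups = {g: grp[value_col].to_numpy(dtype=float) for g, grp in values.groupby(group_col)}
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    others = [g for g in sorted(groups) if g != control]
    if not others:
        raise ValueError("need at least one non-control group")
    F, p_overall = st.f_oneway(*[groups[g] for g in sorted(groups)])
    res = st.dunnett(*[groups[g] for g in others], control=groups[control])
    return pd.DataFrame(
        {
            "group": others,
            "control": control,
            "mean_diff": [groups[g].mean() - groups[control].mean() for g in others],
            "statistic": res.statistic,
            "p_adj": res.pvalue,
            "anova_F": F,
            "anova_p": p_overall,
        }
    )
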
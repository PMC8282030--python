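"""Ingestion of the deposited peak-level workbook and the reproduce run.

The original study deposited its peak-level records as an XLSX workbook
whose sheets are, by position: metadata, the filtered experiment data, the
ellipse-versus-nothing control, and the unfiltered experiment data.
Columns are matched by name heuristics with an explicit mapping override.
``reproduce`` refits both mixed models on such a workbook and prints a
side-by-side table against the estimates printed in the original report.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inference import baseline_check, fit_preference, fit_speed_vs_angle, posthoc

#: Estimates printed in the original report, used only for the side-by-side
#: comparison table of the reproduce run.
REFERENCE_RESULTS = {
    "angle_chisq": 3330.8,
    "during_contrasts": {
        "silhouette_vs_ellipse": -23.73,
        "scrambled_vs_random": -15.1,
        "bio_vs_random": -13.37,
        "bio_vs_scrambled": -1.04,
    },
    "between_contrasts": {
        "bio_vs_random": 0.52,
        "bio_vs_scrambled": 1.68,
        "scrambled_vs_random": 2.46,
        "silhouette_vs_ellipse": 3.4,
    },
    "baseline_during": 107.0,
    "baseline_between": -24.5,
    "n_trials": 188,
}

SHEET_POSITIONS = {"experiment": 1, "control": 2, "unfiltered": 3}

#: Canonical column -> lowercase substrings tried during autodetection.
COLUMN_HINTS = {
    "subject_id": ("subject", "spider", "animal", "id"),
    "trial_id": ("trial",),
    "condition": ("condition", "pair"),
    "period": ("period", "presence", "visible", "section"),
    "height_deg_s": ("height", "peak", "speed", "rotation"),
    "stimulus_angle_deg": ("angle", "position", "degree"),
    "time_s": ("time",),
}

_CONDITION_KEYWORDS = {
    "bio_vs_random": (("bio",), ("random",)),
    "scrambled_vs_random": (("scram",), ("random",)),
    "bio_vs_scrambled": (("bio",), ("scram",)),
    "silhouette_vs_ellipse": (("silhouette",), ("ellipse",)),
    "ellipse_vs_nothing": (("ellipse",), ("nothing", "none", "control")),
}


class WorkbookError(ValueError):
    """The workbook cannot be mapped onto the expected peak table."""


def _autodetect_columns(df: pd.DataFrame, overrides: dict | None) -> dict[str, str]:
    mapping: dict[str, str] = dict(overrides or {})
    lower = {c: str(c).lower() for c in df.columns}
    for canon, hints in COLUMN_HINTS.items():
        if canon in mapping:
            continue
        if canon in df.columns:
            mapping[canon] = canon
            continue
        for col, name in lower.items():
            if col in mapping.values():
                continue
            if any(h in name for h in hints):
                mapping[canon] = col
                break
    required = {"subject_id", "height_deg_s"}
    missing = required - set(mapping)
    if missing:
        raise WorkbookError(
            f"could not locate columns for {sorted(missing)}; "
            f"available: {list(df.columns)}; pass an explicit column mapping"
        )
    return mapping


def _normalize_condition(value) -> str:
    s = str(value).lower()
    for canon, (kw_a, kw_b) in _CONDITION_KEYWORDS.items():
        if any(k in s for k in kw_a) and any(k in s for k in kw_b):
            return canon
    return str(value)


def _normalize_period(value) -> str:
    s = str(value).strip().lower()
    if s in ("during", "between"):
        return s
    if s in ("true", "1", "visible", "yes", "on", "present"):
        return "during"
    if s in ("false", "0", "not visible", "no", "off", "absent", "invisible"):
        return "between"
    return s


def read_workbook(
    path: str | Path,
    sheet: str = "experiment",
    column_map: dict | None = None,
    sheet_index: int | None = None,
) -> pd.DataFrame:
    """Load one sheet of a deposited-style workbook as a coded peak table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"workbook not found at {path}. Download the study's deposited "
            "peak-level data ('S1 Data', XLSX) and pass its path."
        )
    if sheet_index is None:
        if sheet not in SHEET_POSITIONS:
            raise WorkbookError(f"sheet must be one of {sorted(SHEET_POSITIONS)}")
        sheet_index = SHEET_POSITIONS[sheet]
    raw = pd.read_excel(path, sheet_name=sheet_index, engine="openpyxl")
    mapping = _autodetect_columns(raw, column_map)
    df = pd.DataFrame({canon: raw[col] for canon, col in mapping.items()})
    if "condition" in df.columns:
        df["condition"] = df["condition"].map(_normalize_condition)
    elif sheet == "control":
        df["condition"] = "ellipse_vs_nothing"
    if "period" in df.columns:
        df["period"] = df["period"].map(_normalize_period)
    df["height_deg_s"] = pd.to_numeric(df["height_deg_s"], errors="coerce")
    df = df.dropna(subset=["height_deg_s"])
    df["abs_height_deg_s"] = df["height_deg_s"].abs()
    if "trial_id" not in df.columns:
        df["trial_id"] = df["subject_id"].astype(str) + "_" + df.get("condition", "t").astype(str)
    if "stimulus_angle_deg" in df.columns:
        df["stimulus_angle_deg"] = pd.to_numeric(df["stimulus_angle_deg"], errors="coerce").abs()
    else:
        df["stimulus_angle_deg"] = np.nan
    if "period" not in df.columns:
        df["period"] = "during"
    return df


def write_workbook(
    experiment: pd.DataFrame,
    control: pd.DataFrame,
    path: str | Path,
    unfiltered: pd.DataFrame | None = None,
    metadata: str = "synthetic peak-level workbook (generated)",
) -> Path:
    """Write a deposited-layout workbook (metadata, experiment, control, unfiltered).

    Used to exercise the reproduce path on synthetic data; the metadata
    sheet labels the file as generated.
    """
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        pd.DataFrame({"metadata": [metadata]}).to_excel(xl, sheet_name="metadata", index=False)
        experiment.to_excel(xl, sheet_name="experiment", index=False)
        control.to_excel(xl, sheet_name="control", index=False)
        (unfiltered if unfiltered is not None else experiment).to_excel(
            xl, sheet_name="unfiltered", index=False
        )
    return path


def reproduce(path: str | Path, column_map: dict | None = None) -> dict:
    """Refit both models on a deposited-style workbook.

    Returns the two fits, the post hoc tables, the control baseline and a
    side-by-side comparison frame against the originally printed estimates.
    """
    experiment = read_workbook(path, "experiment", column_map)
    control = read_workbook(path, "control", column_map)

    out: dict = {"n_trials": int(experiment["trial_id"].nunique())}
    if experiment["stimulus_angle_deg"].notna().any():
        speed_fit = fit_speed_vs_angle(experiment)
        out["speed_fit"] = speed_fit
        angle_rows = speed_fit.anova.loc[
            speed_fit.anova["term"].str.contains("angle") & ~speed_fit.anova["term"].str.contains(":")
        ]
        out["angle_chisq"] = float(angle_rows["chisq"].iloc[0]) if len(angle_rows) else float("nan")
    else:
        out["angle_chisq"] = float("nan")

    pref_fit = fit_preference(experiment)
    contrasts = posthoc(pref_fit, experiment)
    out["preference_fit"] = pref_fit
    out["contrasts"] = contrasts
    out["baseline"] = baseline_check(control)

    rows = [
        {
            "quantity": "angle chi-square",
            "reproduced": out["angle_chisq"],
            "printed": REFERENCE_RESULTS["angle_chisq"],
        },
        {
            "quantity": "trials analyzed",
            "reproduced": out["n_trials"],
            "printed": REFERENCE_RESULTS["n_trials"],
        },
    ]
    for period, ref_key in (("during", "during_contrasts"), ("between", "between_contrasts")):
        for cond, printed in REFERENCE_RESULTS[ref_key].items():
            sub = contrasts.loc[
                (contrasts["condition"] == cond) & (contrasts["period"] == period), "estimate"
            ]
            rows.append(
                {
                    "quantity": f"{cond} ({period})",
                    "reproduced": float(sub.iloc[0]) if len(sub) else float("nan"),
                    "printed": printed,
                }
            )
    for period, key in (("during", "baseline_during"), ("between", "baseline_between")):
        sub = out["baseline"].loc[out["baseline"]["period"] == period, "estimate"]
        rows.append(
            {
                "quantity": f"ellipse baseline ({period})",
                "reproduced": float(sub.iloc[0]) if len(sub) else float("nan"),
                "printed": REFERENCE_RESULTS[key],
            }
        )
    comparison = pd.DataFrame(rows)
    comparison["difference"] = comparison["reproduced"] - comparison["printed"]
    out["comparison"] = comparison
    return out
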
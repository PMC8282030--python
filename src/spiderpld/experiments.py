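"""End-to-end synthetic studies: simulate, extract, code, fit, recover.

These runners wire the virtual spider to the extraction and inference
chain and are what the parameter-recovery validation uses: inject a known
preference, run the whole pipeline, and check that the fitted
during-stimulus contrast recovers it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AgentParams, MAIN_CONDITIONS, ScheduleParams, StudyConfig, TimelineSpec
from .inference import fit_preference, posthoc
from .kinematics import code_peaks, extract_saccades
from .synthetic import make_dataset, simulate_spider


def run_study(
    n_subjects: int,
    preference: float,
    seed: int,
    conditions: tuple[str, ...] = MAIN_CONDITIONS,
    config: StudyConfig | None = None,
    schedule_params: ScheduleParams | None = None,
    subject_pref_sd: float = 0.08,
) -> pd.DataFrame:
    """Simulate a full study and return the pooled coded peak table.

    Individual spiders differ: each subject's preference is drawn around
    the population value with s.d. ``subject_pref_sd`` (clipped to [0, 1]),
    which is what the model's subject random intercept absorbs.
    """
    config = config or StudyConfig()
    spec = config.timeline
    sp = schedule_params or config.schedule
    rng = np.random.default_rng(seed + 500_000_001)
    base = {f: getattr(config.agent, f) for f in config.agent.__dataclass_fields__}
    design = make_dataset(
        n_subjects, conditions=conditions, seed=seed, spec=spec, schedule_params=sp
    )
    subject_pref = {
        s: float(np.clip(preference + rng.normal(0.0, subject_pref_sd), 0.0, 1.0))
        for s in design["subject_id"].unique()
    }
    frames = []
    for _, row in design.iterrows():
        agent = AgentParams(**{**base, "preference": subject_pref[row["subject_id"]]})
        trace, _ = simulate_spider(row["schedule"], spec, agent, seed=row["sim_seed"])
        peaks = extract_saccades(trace, config.analysis)
        frames.append(
            code_peaks(
                peaks,
                row["schedule"],
                spec,
                config.analysis,
                subject_id=row["subject_id"],
                trial_id=row["trial_id"],
            )
        )
    return pd.concat(frames, ignore_index=True)


def during_contrast_summary(peaks: pd.DataFrame) -> dict:
    """Marginal during-stimulus preference estimate averaged over conditions.

    The average of the during-period cell means is a single linear
    combination of the fixed effects, so its standard error comes from the
    full fixed-effect covariance.
    """
    import patsy

    fit = fit_preference(peaks)
    table = posthoc(fit, peaks, adjust="none")
    during = table.loc[table["period"] == "during"]
    conditions = sorted(peaks["condition"].unique())
    design_info = fit.result.model.data.design_info
    grid = pd.DataFrame(
        {
            "condition": conditions,
            "period": "during",
            "height_deg_s": 0.0,
            "abs_height_deg_s": 0.0,
            "stimulus_angle_deg": 0.0,
        }
    )
    (X,) = patsy.build_design_matrices([design_info], grid)
    L = np.asarray(X).mean(axis=0)
    beta = fit.result.fe_params.to_numpy()
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    est = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - 1.96 * se,
        "ci_high": est + 1.96 * se,
        "per_condition": during.set_index("condition")["estimate"].to_dict(),
    }


def recovery_curve(
    pi_values: tuple[float, ...] = (0.3, 0.5, 0.7),
    n_subjects: int = 20,
    seed: int = 0,
    config: StudyConfig | None = None,
    schedule_params: ScheduleParams | None = None,
) -> pd.DataFrame:
    """Fitted during-stimulus contrast at each injected preference level."""
    rows = []
    for i, pi in enumerate(pi_values):
        peaks = run_study(
            n_subjects,
            pi,
            seed=seed * 1009 + i,
            config=config,
            schedule_params=schedule_params,
        )
        s = during_contrast_summary(peaks)
        rows.append(
            {
                "preference": pi,
                "estimate": s["estimate"],
                "se": s["se"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "n_peaks": len(peaks),
            }
        )
    return pd.DataFrame(rows)


def sign_recovery_rate(
    pi: float,
    n_replicates: int = 100,
    n_subjects: int = 20,
    seed: int = 0,
    config: StudyConfig | None = None,
    schedule_params: ScheduleParams | None = None,
) -> float:
    """Fraction of replicates whose fitted contrast recovers sign(pi - 0.5)."""
    if pi == 0.5:
        raise ValueError("sign recovery is undefined at preference 0.5")
    expected = np.sign(pi - 0.5)
    hits = 0
    for r in range(n_replicates):
        peaks = run_study(
            n_subjects,
            pi,
            seed=seed * 7919 + 13 * r + 1,
            config=config,
            schedule_params=schedule_params,
        )
        s = during_contrast_summary(peaks)
        hits += int(np.sign(s["estimate"]) == expected)
    return hits / n_replicates
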
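"""Trial validity, observer exclusion, condition grouping and proportions.

The analysis chain mirrors the study's quantification steps:

1. drop trials with a fixation deviation of more than 2 deg (strictly
   greater; exactly 2 deg is valid);
2. exclude observers with too few valid trials in any grouped condition
   (fewer than 12 in experiments 1-2; fewer than 6 in any ungrouped
   experiment-3 condition) or with chance-like accuracy (<= 75% correct) in
   conditions where the answer is objectively defined -- excepting the
   foveal scotopic conditions, where low accuracy is the phenomenon itself;
3. merge screen sides and reversed temporal sequences into grouped
   conditions (lower eccentricity first), recoding discontinuity-instructed
   responses to "which interval appeared continuous";
4. compute, per grouped condition, the across-observer mean of per-observer
   proportions (correct / less-eccentric-reported-continuous /
   less-eccentric-selected / selected-reported-continuous) with BCa
   bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import BootstrapConfig, bca_ci

logger = logging.getLogger(__name__)

FIXATION_LIMIT_DEG = 2.0
MIN_VALID_TRIALS = {1: 12, 2: 12, 3: 6}
ACCURACY_FLOOR = 0.75
MIN_APPEARANCE_TRIALS = 14


@dataclass(frozen=True)
class ProportionEstimate:
    """Across-observer mean proportion for one grouped condition."""

    group: str
    metric: str
    point: float
    ci_low: float
    ci_high: float
    n_observers: int
    n_trials: int
    per_observer: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "metric": self.metric,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_observers": self.n_observers,
            "n_trials": self.n_trials,
        }


# ---------------------------------------------------------------------------
# grouping and recoding


def add_grouping(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach grouped-condition labels and recoded outcome columns.

    Adds retinal eccentricities, the lower-first grouped condition label,
    and per-trial outcome flags: ``correct`` (unambiguous conditions),
    ``chose_less_ecc`` (comparison task, different eccentricities),
    ``selected_less_ecc`` and ``appearance_correct`` (selection/appearance
    task).  Discontinuity-instructed comparison responses are recoded to
    "which interval appeared continuous" before any grouping.
    """
    df = trials.copy()
    df["retinal_first"] = (df["ecc_first"] - df["fixation_pos"]).abs()
    df["retinal_second"] = (df["ecc_second"] - df["fixation_pos"]).abs()
    df["ecc_low"] = df[["retinal_first", "retinal_second"]].min(axis=1)
    df["ecc_high"] = df[["retinal_first", "retinal_second"]].max(axis=1)
    df["same_ecc"] = df["retinal_first"] == df["retinal_second"]
    first_is_low = df["retinal_first"] <= df["retinal_second"]
    df["type_low"] = np.where(first_is_low, df["type_first"], df["type_second"])
    df["type_high"] = np.where(first_is_low, df["type_second"], df["type_first"])

    pair = (
        df["ecc_low"].map("{:g}".format) + "|" + df["ecc_high"].map("{:g}".format)
    )
    types = np.where(
        df["same_ecc"], "pooled", df["type_low"] + "|" + df["type_high"]
    )
    df["group"] = df["lighting"] + " " + pair + " " + types

    # comparison task: position reported as continuous
    has_comparison = df["response_comparison"].isin(["first", "second"])
    other = df["response_comparison"].map({"first": "second", "second": "first"})
    df["reported_continuous"] = np.where(
        df["instruction"] == "continuity", df["response_comparison"], other
    )
    df.loc[~has_comparison, "reported_continuous"] = ""

    rep_type = np.where(
        df["reported_continuous"] == "first", df["type_first"], df["type_second"]
    )
    rep_ecc = np.where(
        df["reported_continuous"] == "first",
        df["retinal_first"],
        df["retinal_second"],
    )
    df["correct"] = np.where(has_comparison, rep_type == "C", False)
    df["chose_less_ecc"] = np.where(
        has_comparison & ~df["same_ecc"], rep_ecc == df["ecc_low"], False
    )

    # selection/appearance task
    has_selection = df["response_selection"].isin(["first", "second"])
    sel_ecc = np.where(
        df["response_selection"] == "first",
        df["retinal_first"],
        df["retinal_second"],
    )
    sel_type = np.where(
        df["response_selection"] == "first", df["type_first"], df["type_second"]
    )
    df["selected_ecc"] = np.where(has_selection, sel_ecc, np.nan)
    df["selected_type"] = np.where(has_selection, sel_type, "")
    df["selected_less_ecc"] = np.where(
        has_selection & ~df["same_ecc"], sel_ecc == df["ecc_low"], False
    )
    df["reported_continuous_flag"] = df["response_appearance"] == "continuous"
    df["appearance_correct"] = np.where(
        has_selection,
        (df["response_appearance"] == "continuous") == (sel_type == "C"),
        False,
    )
    return df


def ungrouped_label(df: pd.DataFrame) -> pd.Series:
    """Design-cell label before side/sequence merging (experiment 3 rule)."""
    off1 = df["ecc_first"] - df["fixation_pos"]
    off2 = df["ecc_second"] - df["fixation_pos"]
    return (
        "fix"
        + df["fixation_pos"].map("{:+g}".format)
        + " "
        + off1.map("{:+g}".format)
        + "|"
        + off2.map("{:+g}".format)
        + " "
        + df["type_first"]
        + df["type_second"]
    )


# ---------------------------------------------------------------------------
# validity and exclusions


def filter_valid(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trials into fixation-valid and rejected sets.

    A trial is invalid when the maximal fixation deviation exceeds 2 deg
    strictly; exactly 2 deg is valid.  If no deviation column is present, a
    precomputed boolean ``valid`` flag is used instead.
    """
    if "max_fixation_deviation" in trials and trials["max_fixation_deviation"].notna().all():
        valid_mask = trials["max_fixation_deviation"] <= FIXATION_LIMIT_DEG
    elif "valid" in trials:
        valid_mask = trials["valid"].astype(bool)
    else:
        raise ValueError(
            "trials carry neither a max_fixation_deviation column nor a "
            "valid flag"
        )
    valid = trials[valid_mask].copy()
    rejected = trials[~valid_mask].copy()
    logger.info(
        "fixation filter: %d valid, %d rejected of %d trials",
        len(valid),
        len(rejected),
        len(trials),
    )
    return valid, rejected


def apply_exclusions(
    trials: pd.DataFrame, experiment: int
) -> tuple[pd.DataFrame, dict]:
    """Drop observers with too few valid trials or chance-like accuracy.

    ``trials`` must already be validity-filtered.  Returns the retained
    trials plus a report of who was excluded and why.  The accuracy floor
    (<= 75%) never applies to the foveal scotopic conditions: failing to
    discriminate inside the scotopic foveal scotoma is the expected result,
    not evidence of a careless observer.
    """
    if experiment not in (1, 2, 3):
        raise ValueError(f"unknown experiment {experiment!r}")
    df = add_grouping(trials)
    reasons: dict[str, list[str]] = {}

    def flag(obs: str, why: str) -> None:
        reasons.setdefault(str(obs), []).append(why)

    min_trials = MIN_VALID_TRIALS[experiment]
    cond_col = ungrouped_label(df) if experiment == 3 else df["group"]
    counts = df.groupby([df["observer_id"], cond_col]).size()
    # every observer must reach the floor in every condition they were
    # scheduled for; conditions entirely missing for an observer count as 0
    all_conds = cond_col.unique()
    for obs, sub in counts.groupby(level=0):
        have = sub.droplevel(0)
        have = have.reindex(all_conds, fill_value=0)
        if (have < min_trials).any():
            worst = have.idxmin()
            flag(obs, f"fewer than {min_trials} valid trials in {worst!r}")

    if experiment == 1:
        same = df[df["same_ecc"]]
        acc = same.groupby(["observer_id", "lighting", "ecc_low"])["correct"].mean()
        for (obs, lighting, ecc), value in acc.items():
            if lighting == "scotopic" and ecc == 0.0:
                continue  # scotoma condition: chance accuracy expected
            if value <= ACCURACY_FLOOR:
                flag(obs, f"accuracy {value:.2f} <= 0.75 in {lighting} {ecc:g} deg")
    elif experiment == 2:
        acc = df.groupby(
            ["observer_id", "lighting", "selected_ecc", "selected_type"]
        )["appearance_correct"].mean()
        for (obs, lighting, ecc, stype), value in acc.items():
            if lighting == "scotopic" and ecc == 0.0 and stype == "D":
                continue  # filled-in foveal scotoma: misreports expected
            if value <= ACCURACY_FLOOR:
                flag(
                    obs,
                    f"appearance accuracy {value:.2f} <= 0.75 for "
                    f"{stype} at {lighting} {ecc:g} deg",
                )
    else:
        unambiguous = df[df["type_first"] != df["type_second"]]
        acc = unambiguous.groupby("observer_id")["correct"].mean()
        for obs, value in acc.items():
            if value <= ACCURACY_FLOOR:
                flag(obs, f"accuracy {value:.2f} <= 0.75")

    excluded = set(reasons)
    retained = trials[~trials["observer_id"].astype(str).isin(excluded)].copy()
    if retained["observer_id"].nunique() == 0:
        logger.warning("exclusions removed every observer")
    report = {
        "experiment": experiment,
        "n_input_observers": int(trials["observer_id"].nunique()),
        "excluded": {k: v for k, v in sorted(reasons.items())},
        "retained": sorted(map(str, retained["observer_id"].unique())),
    }
    return retained, report


# ---------------------------------------------------------------------------
# proportion metrics


def _estimate(
    per_observer: pd.Series,
    group: str,
    metric: str,
    n_trials: int,
    config: BootstrapConfig,
) -> ProportionEstimate:
    values = per_observer.to_numpy(dtype=float)
    if values.size >= 2:
        lo, hi = bca_ci(values, config)
    else:
        lo = hi = float(values.mean())
    return ProportionEstimate(
        group=group,
        metric=metric,
        point=float(values.mean()),
        ci_low=lo,
        ci_high=hi,
        n_observers=int(values.size),
        n_trials=int(n_trials),
        per_observer=values,
    )


def per_observer_proportions(
    trials: pd.DataFrame, outcome: str, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Observer x grouped-condition matrix of per-observer proportions."""
    df = add_grouping(trials) if "group" not in trials else trials
    key = df["group"] if groups is None else groups
    return df.groupby([df["observer_id"], key])[outcome].mean().unstack()


def proportion_correct(
    trials: pd.DataFrame, config: BootstrapConfig | None = None
) -> list[ProportionEstimate]:
    """Proportion correct in same-eccentricity (objective) conditions.

    CD and DC sequences are pooled per eccentricity; each observer
    contributes one proportion and the group statistic is their mean.
    """
    config = config or BootstrapConfig()
    df = add_grouping(trials)
    df = df[df["same_ecc"] & df["reported_continuous"].isin(["first", "second"])]
    out = []
    for group, sub in sorted(df.groupby("group"), key=lambda kv: kv[0]):
        per_obs = sub.groupby("observer_id")["correct"].mean()
        out.append(_estimate(per_obs, group, "correct", len(sub), config))
    return out


def proportion_less_ecc(
    trials: pd.DataFrame,
    metric: str = "continuous",
    sequence_averaged: bool = False,
    config: BootstrapConfig | None = None,
) -> list[ProportionEstimate]:
    """Less-eccentric-stimulus proportions in different-eccentricity groups.

    ``metric="continuous"``: proportion of trials in which the
    less-eccentric interval was reported continuous (comparison task).
    ``metric="selected"``: proportion of trials in which the less-eccentric
    interval was selected for judgment (selection task).  With
    ``sequence_averaged=True`` the two mixed-type assignments (C at the
    lower vs. the higher eccentricity) are averaged per observer, which
    cancels idiosyncratic stimulus-type preferences.
    """
    if metric not in ("continuous", "selected"):
        raise ValueError(f"unknown metric {metric!r}")
    config = config or BootstrapConfig()
    outcome = "chose_less_ecc" if metric == "continuous" else "selected_less_ecc"
    response_col = (
        "reported_continuous" if metric == "continuous" else "response_selection"
    )
    df = add_grouping(trials)
    df = df[~df["same_ecc"] & df[response_col].isin(["first", "second"])]
    label_metric = "less_ecc_" + metric
    out = []
    if not sequence_averaged:
        for group, sub in sorted(df.groupby("group"), key=lambda kv: kv[0]):
            per_obs = sub.groupby("observer_id")[outcome].mean()
            out.append(_estimate(per_obs, group, label_metric, len(sub), config))
        return out
    mixed = df[df["type_low"] != df["type_high"]]
    for (lighting, lo, hi), sub in sorted(
        mixed.groupby(["lighting", "ecc_low", "ecc_high"]), key=lambda kv: kv[0]
    ):
        # average the two type-assignment conditions within observer
        per_cond = sub.groupby(["observer_id", "type_low"])[outcome].mean()
        per_obs = per_cond.groupby(level=0).mean()
        group = f"{lighting} {lo:g}|{hi:g} CD-averaged"
        out.append(
            _estimate(per_obs, group, label_metric + "_seqavg", len(sub), config)
        )
    return out


def proportion_reported_continuous(
    trials: pd.DataFrame,
    config: BootstrapConfig | None = None,
    min_trials: int = MIN_APPEARANCE_TRIALS,
) -> list[ProportionEstimate]:
    """Appearance task: proportion of selected stimuli reported continuous.

    Grouped by lighting, eccentricity and true type of the *selected*
    stimulus.  Because observers' selection biases determine how often each
    cell is visited, observer-cells with fewer than ``min_trials`` trials
    are dropped from the appearance analysis.
    """
    config = config or BootstrapConfig()
    df = add_grouping(trials)
    df = df[df["response_appearance"].isin(["continuous", "discontinuous"])]
    out = []
    keys = ["lighting", "selected_ecc", "selected_type"]
    for (lighting, ecc, stype), sub in sorted(
        df.groupby(keys), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        cell = sub.groupby("observer_id")["reported_continuous_flag"].agg(
            ["mean", "size"]
        )
        cell = cell[cell["size"] >= min_trials]
        if cell.empty:
            continue
        group = f"{lighting} {ecc:g} {stype} selected"
        out.append(
            _estimate(
                cell["mean"], group, "reported_continuous", int(cell["size"].sum()),
                config,
            )
        )
    return out


# ---------------------------------------------------------------------------
# trial-order trend series


def trend_series(
    trials: pd.DataFrame, outcome: str = "chose_less_ecc"
) -> pd.Series:
    """Across-observer mean outcome per within-condition trial number.

    Trials are ranked by presentation order within each observer x grouped
    condition, then the outcome is averaged over observers and conditions
    at each rank.  Feed the result to :func:`fovealbias.stats.trend_regression`.
    """
    df = add_grouping(trials)
    if outcome in ("chose_less_ecc", "selected_less_ecc"):
        df = df[~df["same_ecc"]]
    df = df.sort_values("trial_index")
    df["within_cond_number"] = df.groupby(["observer_id", "group"]).cumcount() + 1
    return df.groupby("within_cond_number")[outcome].mean()
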
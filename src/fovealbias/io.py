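"""Readers, writers, the foreign-schema adapter, and the pipeline runner.

The canonical on-disk format is a tidy UTF-8 comma-separated table with one
row per trial (columns in :data:`fovealbias.observer.TRIAL_COLUMNS`):
degrees as signed floats (negative = left of screen center), responses as
``first``/``second``, appearance reports as ``continuous``/``discontinuous``.
Deposited raw data with a different schema is consumed through a
:class:`ColumnMap`, which renames columns and recodes values (for example
interval responses coded 1/2).

:func:`run_pipeline` ties the whole chain together: simulate or load
trials, filter fixation validity, apply observer exclusions, compute the
proportion metrics with bootstrap CIs, the prediction table, the additivity
comparison and the trial-order trend, and write everything (plus a manifest
of seeds and counts) to an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import analysis, stats
from .design import build_sessions
from .observer import TRIAL_COLUMNS, default_cohort, simulate_experiment
from .predictions import prediction_table

logger = logging.getLogger(__name__)

_REQUIRED = [
    "observer_id",
    "experiment",
    "lighting",
    "trial_index",
    "ecc_first",
    "ecc_second",
    "fixation_pos",
    "type_first",
    "type_second",
]
_ALLOWED = {
    "lighting": {"scotopic", "photopic"},
    "type_first": {"C", "D"},
    "type_second": {"C", "D"},
    "instruction": {"continuity", "discontinuity", ""},
    "response_comparison": {"first", "second", ""},
    "response_selection": {"first", "second", ""},
    "response_appearance": {"continuous", "discontinuous", ""},
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical trial fields to a foreign file's schema.

    ``columns`` maps canonical names to source column names; ``values``
    maps canonical names to ``{source value: canonical value}`` recodings
    (applied after renaming; unlisted values pass through).
    """

    columns: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(columns=raw.get("columns", {}), values=raw.get("values", {}))

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [src for src in self.columns.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped source columns not found: {missing}")
        out = df.rename(columns={v: k for k, v in self.columns.items()}).copy()
        for canonical, mapping in self.values.items():
            if canonical in out.columns:
                out[canonical] = out[canonical].map(
                    lambda v, m=mapping: m.get(v, v)
                )
        return out


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in _ALLOWED:
        if col not in df.columns:
            df[col] = ""
    df = df.fillna({c: "" for c in _ALLOWED})
    errors = []
    for col, allowed in _ALLOWED.items():
        bad = ~df[col].astype(str).isin(allowed)
        for idx in df.index[bad]:
            # +2: header line plus 1-based indexing of the source file
            errors.append(
                f"line {idx + 2}: {col}={df.at[idx, col]!r} not in {sorted(allowed)}"
            )
    if errors:
        head = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise ValueError(f"invalid trial rows:\n  {head}{more}")
    ordered = [c for c in TRIAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def read_trials(path, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read and validate a trial table, via a column map if given."""
    df = pd.read_csv(path, sep=None, engine="python", keep_default_na=True)
    if column_map is not None:
        df = column_map.apply(df)
    df = df.reset_index(drop=True)
    for col in ("response_comparison", "response_selection", "response_appearance",
                "instruction", "side", "orientation"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
        else:
            df[col] = ""
    if "valid" not in df.columns:
        df["valid"] = True
    if "max_fixation_deviation" not in df.columns:
        df["max_fixation_deviation"] = float("nan")
    return _validate(df)


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# end-to-end pipeline

DEFAULT_CONFIG = {
    "experiment": 1,
    "source": "simulate",  # or a path to a canonical/foreign trial CSV
    "column_map": None,
    "n_observers": 22,
    "master_seed": 0,
    "observer_overrides": {},
    "bootstrap": {"n_samples": 20_000, "seed": 0, "unit": "observer"},
    "out_dir": "results",
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = dict(DEFAULT_CONFIG)
    merged.update(config or {})
    merged["bootstrap"] = {**DEFAULT_CONFIG["bootstrap"], **(merged.get("bootstrap") or {})}
    return merged


def run_pipeline(config) -> dict:
    """Run the full analysis chain from a config dict or YAML path.

    Returns a results bundle and writes CSV/JSON artifacts plus a manifest
    to ``out_dir``.  With ``source: simulate`` the run is fully
    self-contained and byte-reproducible from ``master_seed``.
    """
    cfg = _load_config(config)
    experiment = int(cfg["experiment"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in cfg.items() if k != "column_map"},
                      "stages": {}}
    boot = stats.BootstrapConfig(
        n_samples=int(cfg["bootstrap"]["n_samples"]),
        seed=int(cfg["bootstrap"]["seed"]),
        unit=cfg["bootstrap"]["unit"],
    )
    try:
        if cfg["source"] == "simulate":
            schedules = build_sessions(experiment, int(cfg["master_seed"]))
            cohort = default_cohort(
                experiment,
                int(cfg["n_observers"]),
                int(cfg["master_seed"]),
                **(cfg.get("observer_overrides") or {}),
            )
            trials = simulate_experiment(schedules, cohort)
            write_trials(trials, out_dir / "trials.csv")
        else:
            cmap = cfg.get("column_map")
            if isinstance(cmap, (str, Path)):
                cmap = ColumnMap.from_yaml(cmap)
            elif isinstance(cmap, dict):
                cmap = ColumnMap(**cmap)
            trials = read_trials(cfg["source"], cmap)
        manifest["stages"]["input_trials"] = len(trials)
        manifest["stages"]["input_observers"] = int(trials["observer_id"].nunique())

        valid, rejected = analysis.filter_valid(trials)
        manifest["stages"]["valid_trials"] = len(valid)
        manifest["stages"]["rejected_trials"] = len(rejected)

        retained, exclusion_report = analysis.apply_exclusions(valid, experiment)
        manifest["stages"]["retained_observers"] = int(
            retained["observer_id"].nunique()
        )
        manifest["stages"]["excluded_observers"] = len(exclusion_report["excluded"])
        (out_dir / "exclusions.json").write_text(
            json.dumps(exclusion_report, indent=2)
        )

        estimates = []
        if experiment == 1:
            estimates += analysis.proportion_correct(retained, boot)
        if experiment in (1, 3):
            estimates += analysis.proportion_less_ecc(retained, "continuous", False, boot)
        if experiment == 2:
            estimates += analysis.proportion_less_ecc(retained, "selected", False, boot)
            estimates += analysis.proportion_less_ecc(retained, "selected", True, boot)
            estimates += analysis.proportion_reported_continuous(retained, boot)
        props = pd.DataFrame([e.as_dict() for e in estimates])
        props.to_csv(out_dir / "proportions.csv", index=False)

        results: dict = {"proportions": estimates, "exclusions": exclusion_report}

        if experiment in (1, 2):
            prediction_table(experiment).to_csv(
                out_dir / "predictions.csv", index=False
            )
            metric = "continuous" if experiment == 1 else "selected"
            outcome = "chose_less_ecc" if experiment == 1 else "selected_less_ecc"
            additivity = _additivity_by_lighting(retained, metric, boot)
            (out_dir / "additivity.json").write_text(
                json.dumps(additivity, indent=2)
            )
            results["additivity"] = additivity

            series = analysis.trend_series(retained, outcome)
            trend = stats.trend_regression(series.to_numpy(), series.index.to_numpy())
            trend_dict = dataclasses.asdict(trend)
            (out_dir / "trend.json").write_text(json.dumps(trend_dict, indent=2))
            results["trend"] = trend

        manifest["status"] = "complete"
        return results
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _additivity_by_lighting(
    trials: pd.DataFrame, metric: str, boot: stats.BootstrapConfig
) -> dict:
    """Additivity comparison of the ambiguous (CC) biases per lighting."""
    df = analysis.add_grouping(trials)
    outcome = "chose_less_ecc" if metric == "continuous" else "selected_less_ecc"
    response_col = (
        "reported_continuous" if metric == "continuous" else "response_selection"
    )
    cc = df[
        ~df["same_ecc"]
        & (df["type_low"] == "C")
        & (df["type_high"] == "C")
        & df[response_col].isin(["first", "second"])
    ]
    out = {}
    for lighting, sub in cc.groupby("lighting"):
        mat = sub.groupby(["observer_id", "ecc_low", "ecc_high"])[outcome].mean()
        try:
            p04 = mat.xs((0.0, 4.0), level=(1, 2))
            p48 = mat.xs((4.0, 8.0), level=(1, 2))
            p08 = mat.xs((0.0, 8.0), level=(1, 2))
        except KeyError:
            continue
        common = p04.index.intersection(p48.index).intersection(p08.index)
        if len(common) < 2:
            continue
        res = stats.additivity_test(
            p04.loc[common], p48.loc[common], p08.loc[common], boot
        )
        out[lighting] = {
            "summed_logit": res.summed_logit,
            "observed_logit": res.observed_logit,
            "mean_diff": res.mean_diff,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "covers_zero": res.covers_zero,
            "n_observers": int(len(common)),
        }
    return out
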
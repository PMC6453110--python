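"""Generative observer models for the comparison/selection/appearance tasks.

Each simulated observer is a small stochastic perception + decision model:

1. *Perception*.  A stimulus at retinal eccentricity 0, 4 or 8 deg yields a
   percept (CONTINUOUS, DISCONTINUOUS or GAP).  Away from the scotopic
   fovea the percept is veridical with per-eccentricity probability
   ``a(lighting, ecc)``.  Inside the scotopic foveal scotoma (0 deg under
   scotopic viewing) rods are absent, so the true center is invisible:
   a *filling-in* observer perceives the stimulus as continuous with
   probability ``p_fill`` regardless of its true type, while a
   *perceptual-gap* observer obtains a distinguished GAP percept carrying
   no appearance information.
2. *Decision*.  In the comparison task, an interval whose percept uniquely
   matches the instructed target (continuous or discontinuous) is chosen;
   ties are broken by relative trust in the two locations: the stimulus at
   the lower eccentricity is judged the better exemplar of "continuous"
   with probability sigma(r(e_low) - r(e_high)), the standard logistic of
   the reliability difference.  This makes the central-vision choice bias
   additive on the logit scale by construction.  A GAP percept contributes
   no evidence: the decision is carried by the other interval alone.
3. *Selection* (type-2 judgment) uses the same logistic trust difference
   plus a per-observer log-odds bonus ``type_pref`` for stimuli that
   currently look continuous; a perceptual-gap observer never selects the
   GAP interval.
4. *Report* (type-1 judgment) repeats the percept; lapses (rate ``lapse``)
   replace any response with a uniform guess.

Fixation breaks (deviation > 2 deg, probability ``p_break`` per trial) are
simulated so the analysis chain's validity filtering has work to do.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Schedule, build_sessions

VALID_ECCENTRICITIES = (0.0, 4.0, 8.0)


class Percept(Enum):
    CONTINUOUS = "continuous"
    DISCONTINUOUS = "discontinuous"
    GAP = "gap"


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# calibration: the generative defaults reproduce the headline group
# statistics of the study the simulator stands in for (docs/methods.md
# derives them).  Reliabilities are anchored at r(8 deg) = 0; the pairwise
# differences are chosen so that the *observable* ambiguous-condition (CC)
# proportions -- which perception errors dilute toward the unique-match
# rule -- land on the reported group values.
_DEFAULT_ACCURACY = {
    ("scotopic", 0.0): 1.0,  # veridicality of the rare *unfilled* foveal percept
    ("scotopic", 4.0): 0.95,
    ("scotopic", 8.0): 0.97,
    ("photopic", 0.0): 0.98,
    ("photopic", 4.0): 0.98,
    ("photopic", 8.0): 0.98,
}
_DEFAULT_PFILL = 0.9
_DEFAULT_LAPSE = 0.02


def _invert_comparison_bias(
    p_target: float, a_lo: float, a_hi: float, lapse: float
) -> float:
    """Reliability difference whose observable CC bias equals ``p_target``.

    In a CC trial the tie bias sigma(dr) surfaces only when both percepts
    are continuous (or both discontinuous); a lone misperceived stimulus
    triggers the unique-match rule:
    p = (1-lapse) * [q sigma + w] + lapse/2 with q = a_lo a_hi +
    (1-a_lo)(1-a_hi) and w = a_lo (1-a_hi).
    """
    q = a_lo * a_hi + (1.0 - a_lo) * (1.0 - a_hi)
    w = a_lo * (1.0 - a_hi)
    s = ((p_target - lapse / 2.0) / (1.0 - lapse) - w) / q
    return _logit(s)


def _comparison_reliability(targets: dict) -> dict:
    """Anchor r(8)=0 and stack the inverted pair differences."""
    rel = {}
    for lighting, (p04, p48) in targets.items():
        # effective P(percept continuous | true C) at the scotopic fovea is 1
        # (filled in, or a veridical glimpse of the continuous center)
        a0 = 1.0 if lighting == "scotopic" else _DEFAULT_ACCURACY[(lighting, 0.0)]
        d04 = _invert_comparison_bias(
            p04, a0, _DEFAULT_ACCURACY[(lighting, 4.0)], _DEFAULT_LAPSE
        )
        d48 = _invert_comparison_bias(
            p48,
            _DEFAULT_ACCURACY[(lighting, 4.0)],
            _DEFAULT_ACCURACY[(lighting, 8.0)],
            _DEFAULT_LAPSE,
        )
        rel[(lighting, 0.0)] = d04 + d48
        rel[(lighting, 4.0)] = d48
        rel[(lighting, 8.0)] = 0.0
    return rel


def _selection_reliability(targets: dict) -> dict:
    """Selection has no unique-match rule; only the lapse dilutes sigma."""
    rel = {}
    for lighting, (p04, p48) in targets.items():
        d04 = _logit((p04 - _DEFAULT_LAPSE / 2.0) / (1.0 - _DEFAULT_LAPSE))
        d48 = _logit((p48 - _DEFAULT_LAPSE / 2.0) / (1.0 - _DEFAULT_LAPSE))
        rel[(lighting, 0.0)] = d04 + d48
        rel[(lighting, 4.0)] = d48
        rel[(lighting, 8.0)] = 0.0
    return rel


# reported CC biases: (0|4, 4|8) per lighting
_EXP1_RELIABILITY = _comparison_reliability(
    {"scotopic": (0.709, 0.631), "photopic": (0.825, 0.737)}
)
_EXP2_RELIABILITY = _selection_reliability(
    {"scotopic": (0.810, 0.781), "photopic": (0.769, 0.747)}
)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated observer.

    Parameters
    ----------
    accuracy
        ``(lighting, retinal_ecc) -> P(veridical percept)`` outside the
        scotopic foveal scotoma.
    p_fill
        Probability that a stimulus inside the scotopic foveal scotoma is
        perceived as continuous irrespective of its true type (filling-in
        observers); with probability ``1 - p_fill`` filling-in fails and the
        percept reflects the true center with probability
        ``a(scotopic, 0)``.
    reliability
        ``(lighting, retinal_ecc) -> r``, the trust score whose pairwise
        differences set the logistic tie-break bias.
    lapse
        Probability of a uniformly random response, applied at the decision
        stage.
    type_pref
        Log-odds bonus for selecting a perceived-continuous stimulus in the
        selection task.
    p_break
        Per-trial probability of a fixation deviation larger than 2 deg.
    scotoma_mode
        ``"filling_in"`` or ``"gap"``: what happens at (scotopic, 0 deg).
    instruction
        ``"continuity"`` or ``"discontinuity"`` (comparison task framing);
        assigned per observer, as in the study design.
    pair_bonus
        Optional extra logit bias toward the less eccentric stimulus in tie
        trials, keyed by the eccentricity pair ``(ecc_low, ecc_high)``.
        A bonus attached to a *single* pair breaks logit additivity (used to
        give the additivity test something to detect); note that a uniform
        foveal bonus applied to every pair containing 0 deg cancels in the
        additivity comparison and leaves the data perfectly additive.
    rng_seed
        Seed of this observer's private random stream.
    """

    observer_id: str = "obs"
    accuracy: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(_DEFAULT_ACCURACY)
    )
    p_fill: float = _DEFAULT_PFILL
    reliability: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(_EXP1_RELIABILITY)
    )
    lapse: float = _DEFAULT_LAPSE
    type_pref: float = 0.0
    p_break: float = 0.02
    scotoma_mode: str = "filling_in"
    instruction: str = "continuity"
    pair_bonus: Mapping[tuple[float, float], float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fill <= 1.0:
            raise ValueError("p_fill must lie in [0, 1]")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if not 0.0 <= self.p_break <= 1.0:
            raise ValueError("p_break must lie in [0, 1]")
        if self.scotoma_mode not in ("filling_in", "gap"):
            raise ValueError(f"unknown scotoma_mode {self.scotoma_mode!r}")
        if self.instruction not in ("continuity", "discontinuity"):
            raise ValueError(f"unknown instruction {self.instruction!r}")

    def a(self, lighting: str, ecc: float) -> float:
        return self.accuracy[(lighting, float(ecc))]

    def r(self, lighting: str, ecc: float) -> float:
        return self.reliability[(lighting, float(ecc))]

    def tie_bias(self, lighting: str, e1: float, e2: float) -> float:
        """P(interval 1 judged the more continuous) in a tie trial."""
        d = self.r(lighting, e1) - self.r(lighting, e2)
        if e1 != e2:
            lo, hi = min(e1, e2), max(e1, e2)
            bonus = self.pair_bonus.get((lo, hi), 0.0)
            d += bonus if e1 < e2 else -bonus
        return _logistic(d)

    # -- factory helpers ---------------------------------------------------

    @classmethod
    def calibrated(
        cls,
        experiment: int = 1,
        observer_id: str = "obs",
        instruction: str = "continuity",
        rng_seed: int = 0,
        **overrides,
    ) -> "ObserverParams":
        """Defaults reproducing the study's group-level statistics."""
        rel = _EXP2_RELIABILITY if experiment == 2 else _EXP1_RELIABILITY
        kwargs = dict(
            observer_id=observer_id,
            reliability=dict(rel),
            instruction=instruction,
            rng_seed=rng_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def ideal(
        cls,
        hypothesis: str,
        observer_id: str = "obs",
        instruction: str = "continuity",
        rng_seed: int = 0,
        **overrides,
    ) -> "ObserverParams":
        """Noise-free observer embodying one decision-rule hypothesis.

        ``perceptual_gap``: GAP at the scotopic fovea, equal trust elsewhere.
        ``filling_in``: certain filling-in, equal trust at all eccentricities.
        ``photopic_veridical``: perfect percepts, equal trust.
        """
        if hypothesis not in ("perceptual_gap", "filling_in", "photopic_veridical"):
            raise ValueError(f"unknown hypothesis {hypothesis!r}")
        flat_r = {(l, e): 0.0 for l in ("scotopic", "photopic") for e in VALID_ECCENTRICITIES}
        perfect_a = {(l, e): 1.0 for l in ("scotopic", "photopic") for e in VALID_ECCENTRICITIES}
        kwargs = dict(
            observer_id=observer_id,
            accuracy=perfect_a,
            reliability=flat_r,
            p_fill=1.0,
            lapse=0.0,
            type_pref=0.0,
            p_break=0.0,
            scotoma_mode="gap" if hypothesis == "perceptual_gap" else "filling_in",
            instruction=instruction,
            rng_seed=rng_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def additive_cohort(
    n_observers: int,
    master_seed: int,
    r0_minus_r4: float = 0.6,
    r4_minus_r8: float = 0.3,
    pair_bonus: Mapping[tuple[float, float], float] | None = None,
    **overrides,
) -> list[ObserverParams]:
    """Cohort of noise-free logit-additive observers.

    Percepts are perfectly veridical (and certainly filled in at the
    scotoma), so every ambiguous trial is a tie resolved by the logistic
    reliability bias: the central-vision bias is then logit-additive across
    eccentricity pairs by construction.  ``pair_bonus`` injects a
    pair-specific bias to create detectably non-additive data.
    """
    rel = {
        (l, 0.0): r0_minus_r4 + r4_minus_r8
        for l in ("scotopic", "photopic")
    }
    rel.update({(l, 4.0): r4_minus_r8 for l in ("scotopic", "photopic")})
    rel.update({(l, 8.0): 0.0 for l in ("scotopic", "photopic")})
    master = np.random.default_rng(master_seed)
    return [
        ObserverParams.ideal(
            "filling_in",
            observer_id=f"obs{i + 1:02d}",
            instruction="continuity" if i % 2 == 0 else "discontinuity",
            reliability=rel,
            pair_bonus=dict(pair_bonus or {}),
            rng_seed=int(master.integers(0, 2**31 - 1)),
            **overrides,
        )
        for i in range(n_observers)
    ]


def default_cohort(
    experiment: int,
    n_observers: int,
    master_seed: int,
    type_pref_sd: float = 3.0,
    **overrides,
) -> list[ObserverParams]:
    """A cohort of calibrated observers with per-observer streams.

    The comparison-task instruction alternates between observers (half
    continuity, half discontinuity, as in the study); experiment-2 observers
    additionally draw an idiosyncratic stimulus-type preference from
    ``N(0, type_pref_sd)``.  The default spread is large: individual
    preferences for judging continuous versus discontinuous stimuli are
    strong enough to obscure eccentricity preferences in single mixed-type
    conditions, which is why the sequence-averaged selection metric exists.
    """
    if n_observers < 1:
        raise ValueError("need at least one observer")
    master = np.random.default_rng(master_seed)
    cohort = []
    for i in range(n_observers):
        extra = dict(overrides)
        if experiment == 2 and "type_pref" not in extra:
            extra["type_pref"] = float(master.normal(0.0, type_pref_sd))
        cohort.append(
            ObserverParams.calibrated(
                experiment=experiment,
                observer_id=f"obs{i + 1:02d}",
                instruction="continuity" if i % 2 == 0 else "discontinuity",
                rng_seed=int(master.integers(0, 2**31 - 1)),
                **extra,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# perception


def perceive(
    params: ObserverParams,
    lighting: str,
    retinal_ecc: float,
    true_type: str,
    rng: np.random.Generator,
) -> Percept:
    """Draw the percept of one stimulus.

    At (scotopic, 0 deg) the scotoma rules apply; elsewhere the percept is
    veridical with probability ``a(lighting, ecc)`` and inverted otherwise.
    """
    ecc = float(retinal_ecc)
    if ecc not in VALID_ECCENTRICITIES:
        raise ValueError(
            f"retinal eccentricity {retinal_ecc!r} outside the calibrated set "
            f"{VALID_ECCENTRICITIES}"
        )
    if true_type not in ("C", "D"):
        raise ValueError(f"unknown stimulus type {true_type!r}")
    veridical = Percept.CONTINUOUS if true_type == "C" else Percept.DISCONTINUOUS
    opposite = Percept.DISCONTINUOUS if true_type == "C" else Percept.CONTINUOUS
    if lighting == "scotopic" and ecc == 0.0:
        if params.scotoma_mode == "gap":
            return Percept.GAP
        if rng.random() < params.p_fill:
            return Percept.CONTINUOUS
        # rare unfilled moments yield a glimpse of the true center, which is
        # what lifts foveal scotopic discrimination slightly above chance
        return veridical if rng.random() < params.a(lighting, ecc) else opposite
    return veridical if rng.random() < params.a(lighting, ecc) else opposite


# ---------------------------------------------------------------------------
# decisions


def decide_comparison(
    params: ObserverParams,
    percepts: tuple[Percept, Percept],
    ecc_pair: tuple[float, float],
    instruction: str,
    rng: np.random.Generator,
    lighting: str = "scotopic",
) -> str:
    """Choose the interval that best matches the instructed target.

    Returns ``"first"`` or ``"second"``: the interval reported as the
    continuous one (continuity instruction) or the discontinuous one
    (discontinuity instruction).  Ties -- both or neither percept matching
    the target -- resolve through the logistic reliability bias on *which
    interval is judged the more continuous*, so that recoding every response
    to "which appeared continuous" makes the two instructions statistically
    identical.
    """
    if instruction not in ("continuity", "discontinuity"):
        raise ValueError(f"unknown instruction {instruction!r}")
    p1, p2 = percepts
    e1, e2 = ecc_pair
    if rng.random() < params.lapse:
        return "first" if rng.random() < 0.5 else "second"
    if p1 is Percept.GAP and p2 is Percept.GAP:
        warnings.warn("both percepts GAP: uniform choice", RuntimeWarning)
        return "first" if rng.random() < 0.5 else "second"
    target = (
        Percept.CONTINUOUS if instruction == "continuity" else Percept.DISCONTINUOUS
    )
    if p1 is Percept.GAP or p2 is Percept.GAP:
        # the GAP interval carries no evidence: judge the other interval and
        # fall back on the GAP interval by two-alternative elimination
        gap_first = p1 is Percept.GAP
        other = p2 if gap_first else p1
        if other == target:
            return "second" if gap_first else "first"
        return "first" if gap_first else "second"
    m1, m2 = p1 == target, p2 == target
    if m1 != m2:
        return "first" if m1 else "second"
    # tie: judge which interval is the more continuous, then map to the task
    p_first_more_continuous = params.tie_bias(lighting, e1, e2)
    first_more_continuous = rng.random() < p_first_more_continuous
    if instruction == "continuity":
        return "first" if first_more_continuous else "second"
    return "second" if first_more_continuous else "first"


def decide_selection(
    params: ObserverParams,
    percepts: tuple[Percept, Percept],
    ecc_pair: tuple[float, float],
    rng: np.random.Generator,
    lighting: str = "scotopic",
) -> str:
    """Select which interval to judge (type-2 confidence decision)."""
    p1, p2 = percepts
    e1, e2 = ecc_pair
    if rng.random() < params.lapse:
        return "first" if rng.random() < 0.5 else "second"
    if p1 is Percept.GAP and p2 is Percept.GAP:
        warnings.warn("both percepts GAP: uniform selection", RuntimeWarning)
        return "first" if rng.random() < 0.5 else "second"
    if p1 is Percept.GAP:
        return "second"
    if p2 is Percept.GAP:
        return "first"
    d = params.r(lighting, e1) - params.r(lighting, e2)
    if e1 != e2:
        lo, hi = min(e1, e2), max(e1, e2)
        bonus = params.pair_bonus.get((lo, hi), 0.0)
        d += bonus if e1 < e2 else -bonus
    d += params.type_pref * (
        float(p1 is Percept.CONTINUOUS) - float(p2 is Percept.CONTINUOUS)
    )
    return "first" if rng.random() < _logistic(d) else "second"


def report_appearance(
    params: ObserverParams, percept: Percept, rng: np.random.Generator
) -> str:
    """Report the selected interval's appearance (type-1 judgment)."""
    if rng.random() < params.lapse or percept is Percept.GAP:
        return "continuous" if rng.random() < 0.5 else "discontinuous"
    return "continuous" if percept is Percept.CONTINUOUS else "discontinuous"


# ---------------------------------------------------------------------------
# closed-form expectations (independent of the trial-level simulation path)


def _percept_dist(
    params: ObserverParams, lighting: str, ecc: float, true_type: str
) -> dict[Percept, float]:
    """Exact percept distribution, mirroring :func:`perceive`."""
    if lighting == "scotopic" and ecc == 0.0:
        if params.scotoma_mode == "gap":
            return {Percept.GAP: 1.0}
        a0 = params.a(lighting, 0.0)
        p_true_c = float(true_type == "C")
        p_cont = params.p_fill + (1.0 - params.p_fill) * (
            a0 * p_true_c + (1.0 - a0) * (1.0 - p_true_c)
        )
        return {Percept.CONTINUOUS: p_cont, Percept.DISCONTINUOUS: 1.0 - p_cont}
    a = params.a(lighting, ecc)
    p_cont = a if true_type == "C" else 1.0 - a
    return {Percept.CONTINUOUS: p_cont, Percept.DISCONTINUOUS: 1.0 - p_cont}


def expected_proportion(
    params: ObserverParams,
    lighting: str,
    ecc_low: float,
    ecc_high: float,
    type_low: str,
    type_high: str,
    metric: str = "continuous",
) -> float:
    """Analytic per-trial outcome probability for one grouped condition.

    Enumerates the joint percept distribution and applies the decision
    rules in closed form; used as the generating value in parameter
    recovery.  ``metric``: ``"continuous"`` = P(less-eccentric reported
    continuous), ``"selected"`` = P(less-eccentric selected), ``"correct"``
    = P(correct) for same-eccentricity conditions (then ``type_low``/
    ``type_high`` are the temporal sequence).
    """
    if metric not in ("continuous", "selected", "correct"):
        raise ValueError(f"unknown metric {metric!r}")
    bias = params.tie_bias(lighting, ecc_low, ecc_high)
    total = 0.0
    d_lo = _percept_dist(params, lighting, ecc_low, type_low)
    d_hi = _percept_dist(params, lighting, ecc_high, type_high)
    for p_lo, w_lo in d_lo.items():
        for p_hi, w_hi in d_hi.items():
            w = w_lo * w_hi
            if w == 0.0:
                continue
            if metric == "selected":
                if p_lo is Percept.GAP and p_hi is Percept.GAP:
                    p = 0.5
                elif p_lo is Percept.GAP:
                    p = 0.0
                elif p_hi is Percept.GAP:
                    p = 1.0
                else:
                    d = params.r(lighting, ecc_low) - params.r(lighting, ecc_high)
                    if ecc_low != ecc_high:
                        d += params.pair_bonus.get((ecc_low, ecc_high), 0.0)
                    d += params.type_pref * (
                        float(p_lo is Percept.CONTINUOUS)
                        - float(p_hi is Percept.CONTINUOUS)
                    )
                    p = _logistic(d)
            else:
                # which interval ends up reported as continuous
                if p_lo is Percept.GAP and p_hi is Percept.GAP:
                    p = 0.5
                elif p_lo is Percept.GAP:
                    p = 0.0 if p_hi is Percept.CONTINUOUS else 1.0
                elif p_hi is Percept.GAP:
                    p = 1.0 if p_lo is Percept.CONTINUOUS else 0.0
                elif (p_lo is Percept.CONTINUOUS) != (p_hi is Percept.CONTINUOUS):
                    p = 1.0 if p_lo is Percept.CONTINUOUS else 0.0
                else:
                    p = bias
                if metric == "correct":
                    # probability that the C stimulus is the one reported
                    # continuous; for same-eccentricity pairs bias = 0.5
                    if type_low != "C":
                        p = 1.0 - p
            total += w * p
    return (1.0 - params.lapse) * total + params.lapse * 0.5


# ---------------------------------------------------------------------------
# full experiment simulation

TRIAL_COLUMNS = [
    "observer_id",
    "experiment",
    "lighting",
    "trial_index",
    "ecc_first",
    "ecc_second",
    "fixation_pos",
    "type_first",
    "type_second",
    "side",
    "orientation",
    "instruction",
    "response_comparison",
    "response_selection",
    "response_appearance",
    "max_fixation_deviation",
    "valid",
]


def simulate_experiment(
    schedules: Schedule | Sequence[Schedule],
    observers: Sequence[ObserverParams],
) -> pd.DataFrame:
    """Simulate every observer running every scheduled session.

    Returns one tidy row per trial per observer.  Each observer uses a
    private random stream seeded by their ``rng_seed``, so the table is
    fully reproducible from the parameter set.
    """
    if isinstance(schedules, Schedule):
        schedules = [schedules]
    if len(observers) == 0:
        raise ValueError("empty observer list")
    records: list[dict] = []
    for params in observers:
        rng = np.random.default_rng(params.rng_seed)
        for schedule in schedules:
            lighting = schedule.lighting
            experiment = schedule.experiment
            for row in schedule.trials.itertuples(index=False):
                rec = {
                    "observer_id": params.observer_id,
                    "experiment": experiment,
                    "lighting": lighting,
                    "trial_index": row.trial_index,
                    "ecc_first": row.ecc_first,
                    "ecc_second": row.ecc_second,
                    "fixation_pos": row.fixation_pos,
                    "type_first": row.type_first,
                    "type_second": row.type_second,
                    "side": row.side,
                    "orientation": row.orientation,
                    "instruction": params.instruction,
                    "response_comparison": "",
                    "response_selection": "",
                    "response_appearance": "",
                }
                e1 = abs(row.ecc_first - row.fixation_pos)
                e2 = abs(row.ecc_second - row.fixation_pos)
                broke = rng.random() < params.p_break
                rec["max_fixation_deviation"] = float(
                    2.0 + 6.0 * rng.random() if broke else 2.0 * rng.random()
                )
                rec["valid"] = not broke
                percepts = (
                    perceive(params, lighting, e1, row.type_first, rng),
                    perceive(params, lighting, e2, row.type_second, rng),
                )
                if experiment in (1, 3):
                    rec["response_comparison"] = decide_comparison(
                        params, percepts, (e1, e2), params.instruction, rng, lighting
                    )
                else:
                    sel = decide_selection(params, percepts, (e1, e2), rng, lighting)
                    rec["response_selection"] = sel
                    sel_percept = percepts[0] if sel == "first" else percepts[1]
                    rec["response_appearance"] = report_appearance(
                        params, sel_percept, rng
                    )
                records.append(rec)
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def simulate_cohort(
    experiment: int,
    n_observers: int,
    master_seed: int,
    observers: Sequence[ObserverParams] | None = None,
    **overrides,
) -> pd.DataFrame:
    """Convenience wrapper: schedules + cohort + simulation in one call."""
    schedules = build_sessions(experiment, master_seed)
    if observers is None:
        observers = default_cohort(experiment, n_observers, master_seed, **overrides)
    return simulate_experiment(schedules, observers)
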
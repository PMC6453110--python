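"""Factorial condition sets and randomized trial schedules.

Three two-interval forced-choice experiments on central versus peripheral
vision:

* Experiment 1 (comparison task): two center-surround grating stimuli are
  shown consecutively at the same eccentricity (0, 4 or 8 deg; objective
  discrimination) or at two different eccentricities (0|4, 0|8, 4|8;
  relative weighting), under scotopic or photopic viewing, and the observer
  reports which interval appeared continuous (or discontinuous).
* Experiment 2 (selection + appearance task): different-eccentricity
  conditions only; the observer first selects which interval to judge and
  then reports its appearance.
* Experiment 3 (fixation manipulation, photopic only): fixation is placed at
  -4, 0 or +4 deg from screen center so that the same retinal eccentricities
  (0 and 4 deg) arise from different screen positions.

Screen positions are signed degrees (negative = left of screen center);
retinal eccentricity is ``abs(screen_position - fixation_pos)``.  Reversed
temporal sequences and screen sides are merged for analysis by
:func:`normalize_condition`, which recodes every condition to the
lower-eccentricity-first ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ECCENTRICITIES = (0.0, 4.0, 8.0)
ECC_PAIRS = ((0.0, 4.0), (0.0, 8.0), (4.0, 8.0))
#: ordered stimulus-type sequences; DD never occurs in any design cell
TYPE_SEQUENCES = (("C", "C"), ("C", "D"), ("D", "C"))
LIGHTINGS = ("scotopic", "photopic")
SIDES = ("left", "right")
ORIENTATIONS = ("vertical", "horizontal")

#: nominal trial timing, recorded as metadata only (never enacted)
TIMING = {
    "fixation_jitter_s": (1.0, 1.5),
    "stimulus_duration_s": 0.300,
    "interstimulus_interval_s": 0.700,
    "fixation_window_ms": 1320,
}

SCHEDULE_COLUMNS = [
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
    "seed",
]


@dataclass(frozen=True)
class Condition:
    """One experimental condition: where, what and in which order.

    ``ecc_first``/``ecc_second`` are signed screen positions in degrees of
    visual angle; ``fixation_pos`` is the fixation point in the same
    coordinates (nonzero only in experiment 3).
    """

    experiment: int
    lighting: str
    ecc_first: float
    ecc_second: float
    type_first: str
    type_second: str
    fixation_pos: float = 0.0
    side: str = "right"
    orientation: str = "vertical"

    def __post_init__(self) -> None:
        if (self.type_first, self.type_second) == ("D", "D"):
            raise ValueError("DD stimulus pairs are not part of any design")

    @property
    def retinal_first(self) -> float:
        return abs(self.ecc_first - self.fixation_pos)

    @property
    def retinal_second(self) -> float:
        return abs(self.ecc_second - self.fixation_pos)

    @property
    def same_ecc(self) -> bool:
        return self.retinal_first == self.retinal_second

    @property
    def design_label(self) -> str:
        """Condition label with sides/orientations/repetitions collapsed.

        Retinal eccentricities in temporal order plus the type sequence;
        distinct labels count the interleaved conditions of the design
        (24 in experiment 1, 18 in experiment 2, 36 in experiment 3 --
        where fixation position remains part of the label).
        """
        if self.experiment == 3:
            # signed retinal offsets: left/right placement is a real design
            # cell here (it is what distinguishes the 0|4 and 0|-4 cells)
            off1 = self.ecc_first - self.fixation_pos
            off2 = self.ecc_second - self.fixation_pos
            return (
                f"fix{self.fixation_pos:+g} {off1:+g}|{off2:+g} "
                f"{self.type_first}{self.type_second}"
            )
        return (
            f"{self.retinal_first:g}|{self.retinal_second:g} "
            f"{self.type_first}{self.type_second}"
        )


@dataclass(frozen=True)
class GroupedCondition:
    """A condition after merging sides and reversed temporal sequences.

    Eccentricities are absolute retinal eccentricities ordered
    lower-eccentricity first; ``type_low``/``type_high`` are the stimulus
    types at the lower/higher eccentricity.  Same-eccentricity groups pool
    the CD and DC sequences, so their types are ``None``.
    """

    lighting: str
    ecc_low: float
    ecc_high: float
    type_low: str | None = None
    type_high: str | None = None

    @property
    def same_ecc(self) -> bool:
        return self.ecc_low == self.ecc_high

    @property
    def label(self) -> str:
        types = (
            "pooled"
            if self.type_low is None
            else f"{self.type_low}|{self.type_high}"
        )
        return f"{self.lighting} {self.ecc_low:g}|{self.ecc_high:g} {types}"


@dataclass(frozen=True)
class Schedule:
    """An ordered randomized trial list for one experimental session."""

    experiment: int
    lighting: str
    seed: int
    trials: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path, observer_id: str = "") -> None:
        df = self.trials.copy()
        df.insert(0, "observer_id", observer_id)
        df["seed"] = self.seed
        df[SCHEDULE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# condition construction


def conditions_for(experiment: int, lighting: str) -> list[Condition]:
    """Enumerate the interleaved conditions of one session (one per label)."""
    if lighting not in LIGHTINGS:
        raise ValueError(f"unknown lighting {lighting!r}")
    conds: list[Condition] = []
    if experiment == 1:
        # 3 same-eccentricity cells x 2 type sequences (CD, DC)
        for ecc in ECCENTRICITIES:
            for t1, t2 in (("C", "D"), ("D", "C")):
                conds.append(
                    Condition(1, lighting, ecc, ecc, t1, t2)
                )
        conds.extend(_different_ecc_conditions(1, lighting))
    elif experiment == 2:
        conds.extend(_different_ecc_conditions(2, lighting))
    elif experiment == 3:
        if lighting != "photopic":
            raise ValueError("experiment 3 was run under photopic viewing only")
        for fix in (-4.0, 0.0, 4.0):
            for offsets in ((0.0, 4.0), (0.0, -4.0)):
                for order in (offsets, offsets[::-1]):
                    for t1, t2 in TYPE_SEQUENCES:
                        conds.append(
                            Condition(
                                3,
                                lighting,
                                fix + order[0],
                                fix + order[1],
                                t1,
                                t2,
                                fixation_pos=fix,
                                side="right" if max(order) > 0 else "left",
                            )
                        )
    else:
        raise ValueError(f"unknown experiment {experiment!r}; expected 1, 2 or 3")
    return conds


def _different_ecc_conditions(experiment: int, lighting: str) -> list[Condition]:
    # 3 eccentricity pairs x 2 location orders x 3 type sequences = 18
    conds = []
    for lo, hi in ECC_PAIRS:
        for order in ((lo, hi), (hi, lo)):
            for t1, t2 in TYPE_SEQUENCES:
                conds.append(
                    Condition(experiment, lighting, order[0], order[1], t1, t2)
                )
    return conds


def build_schedule(
    experiment: int, seed: int, lighting: str | None = None
) -> Schedule:
    """Build the full randomized trial schedule of one session.

    Each condition is expanded over its repetition factors (repetitions x
    side x orientation for experiments 1-2; repetitions x orientation for
    experiment 3, where the signed screen offsets already carry the side),
    and the complete trial list is shuffled with ``numpy``'s default
    generator seeded by ``seed``.  Identical seeds give identical schedules;
    different seeds permute order only, never counts.
    """
    if experiment not in (1, 2, 3):
        raise ValueError(f"unknown experiment {experiment!r}; expected 1, 2 or 3")
    if lighting is None:
        lighting = "photopic" if experiment == 3 else "scotopic"
    conds = conditions_for(experiment, lighting)
    n_reps = {1: 3, 2: 4, 3: 6}[experiment]
    rows: list[Condition] = []
    for cond in conds:
        if experiment in (1, 2):
            for _rep, side, orient in itertools.product(
                range(n_reps), SIDES, ORIENTATIONS
            ):
                sign = -1.0 if side == "left" else 1.0
                rows.append(
                    replace(
                        cond,
                        ecc_first=sign * cond.ecc_first,
                        ecc_second=sign * cond.ecc_second,
                        side=side,
                        orientation=orient,
                    )
                )
        else:
            for _rep, orient in itertools.product(range(n_reps), ORIENTATIONS):
                rows.append(replace(cond, orientation=orient))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    shuffled = [rows[i] for i in order]
    df = pd.DataFrame(
        {
            "experiment": experiment,
            "lighting": lighting,
            "trial_index": np.arange(1, len(shuffled) + 1),
            "ecc_first": [c.ecc_first for c in shuffled],
            "ecc_second": [c.ecc_second for c in shuffled],
            "fixation_pos": [c.fixation_pos for c in shuffled],
            "type_first": [c.type_first for c in shuffled],
            "type_second": [c.type_second for c in shuffled],
            "side": [c.side for c in shuffled],
            "orientation": [c.orientation for c in shuffled],
        }
    )
    return Schedule(experiment=experiment, lighting=lighting, seed=seed, trials=df)


def build_sessions(experiment: int, seed: int) -> list[Schedule]:
    """All sessions of an experiment (scotopic + photopic for 1-2)."""
    if experiment in (1, 2):
        return [
            build_schedule(experiment, seed * 2 + k, lighting)
            for k, lighting in enumerate(LIGHTINGS)
        ]
    return [build_schedule(experiment, seed, "photopic")]


# ---------------------------------------------------------------------------
# sequence/side normalization


def normalize_condition(
    condition: Condition, choice: str | None = None
) -> tuple[GroupedCondition, str | None]:
    """Merge sides and reversed sequences into the grouped condition.

    Different-eccentricity conditions are recoded to the
    lower-retinal-eccentricity-first ordering; a ``choice`` of ``"first"`` or
    ``"second"`` (which interval the response refers to) is recoded to
    ``"less-ecc"``/``"more-ecc"``.  Same-eccentricity conditions map onto
    themselves with the CD/DC sequences pooled; their choice recoding is
    meaningless and returned unchanged.
    """
    e1, e2 = condition.retinal_first, condition.retinal_second
    if condition.same_ecc:
        group = GroupedCondition(condition.lighting, e1, e2)
        return group, choice
    if e1 < e2:
        group = GroupedCondition(
            condition.lighting, e1, e2, condition.type_first, condition.type_second
        )
        first_is_low = True
    else:
        group = GroupedCondition(
            condition.lighting, e2, e1, condition.type_second, condition.type_first
        )
        first_is_low = False
    if choice is None:
        return group, None
    if choice not in ("first", "second"):
        raise ValueError(f"unknown choice {choice!r}")
    chose_first = choice == "first"
    less = chose_first == first_is_low
    return group, "less-ecc" if less else "more-ecc"
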
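"""Analytic predictions of the competing decision-rule hypotheses.

Three idealized, unbiased observers are enumerated exactly (no simulation):

* ``perceptual_gap`` -- the scotopic foveal scotoma yields no percept (or
  the observer distrusts the filled-in percept): decisions rest on the
  peripheral stimulus alone, and foveal stimuli are never selected.
* ``filling_in`` -- the scotoma is filled in from the surround and the
  inferred percept is trusted as much as veridical peripheral input: any
  foveal stimulus looks continuous, and ties split evenly.
* ``photopic_veridical`` -- daylight viewing with veridical percepts at
  every eccentricity and equal weighting.

Predictions are stated for the grouped different-eccentricity conditions:
experiment 1 predicts P(less-eccentric stimulus reported continuous),
experiment 2 predicts P(less-eccentric stimulus selected).  All predicted
values are exact rationals in {0, 1/2, 1}.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .design import ECC_PAIRS

HYPOTHESES = ("perceptual_gap", "filling_in", "photopic_veridical")
#: (type at lower ecc, type at higher ecc) of the grouped conditions
TYPE_ASSIGNMENTS = (("C", "C"), ("C", "D"), ("D", "C"))


def _veridical_equal_weight(type_low: str, type_high: str) -> float:
    # both percepts veridical, equal trust: unique continuous wins, CC ties
    if type_low == type_high:
        return 0.5
    return 1.0 if type_low == "C" else 0.0


def predicted_proportion(
    hypothesis: str,
    experiment: int,
    lighting: str,
    ecc_pair: tuple[float, float],
    stim_types: tuple[str, str],
) -> float:
    """Predicted grouped-condition proportion under one hypothesis.

    ``ecc_pair`` is the grouped (lower, higher) retinal eccentricity pair
    and ``stim_types`` the (type at lower, type at higher) assignment.
    The scotoma hypotheses are defined for scotopic viewing only and the
    veridical rule for photopic viewing only; the scotopic 4|8 pair, which
    never touches the scotoma, follows the veridical equal-weight rule
    under either scotoma hypothesis.
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if experiment not in (1, 2):
        raise ValueError("predictions are defined for experiments 1 and 2")
    lo, hi = ecc_pair
    if (lo, hi) not in ECC_PAIRS:
        raise ValueError(f"unknown eccentricity pair {ecc_pair!r}")
    t_lo, t_hi = stim_types
    if (t_lo, t_hi) not in TYPE_ASSIGNMENTS:
        raise ValueError(f"unknown stimulus-type assignment {stim_types!r}")
    if hypothesis == "photopic_veridical":
        if lighting != "photopic":
            raise ValueError("the veridical rule applies to photopic viewing")
    elif lighting != "scotopic":
        raise ValueError(f"{hypothesis} applies to scotopic viewing")

    if experiment == 2:
        # selection task: P(less-eccentric stimulus selected)
        if hypothesis == "perceptual_gap" and lo == 0.0:
            return 0.0  # never select the scotoma stimulus
        return 0.5  # no preference under filling-in or veridical viewing

    # experiment 1, comparison task: P(less-eccentric reported continuous)
    if hypothesis == "photopic_veridical" or lo != 0.0:
        return _veridical_equal_weight(t_lo, t_hi)
    if hypothesis == "perceptual_gap":
        # decision carried by the peripheral percept alone
        return 1.0 if t_hi == "D" else 0.0
    # filling_in: the foveal stimulus always looks continuous
    return 1.0 if t_hi == "D" else 0.5


def prediction_table(experiment: int) -> pd.DataFrame:
    """Exhaustive prediction table for the grouped conditions of Figs. of
    the comparison (experiment 1) or selection (experiment 2) task."""
    rows = []
    for hypothesis in HYPOTHESES:
        lighting = "photopic" if hypothesis == "photopic_veridical" else "scotopic"
        for (lo, hi), (t_lo, t_hi) in itertools.product(
            ECC_PAIRS, TYPE_ASSIGNMENTS
        ):
            rows.append(
                {
                    "hypothesis": hypothesis,
                    "experiment": experiment,
                    "lighting": lighting,
                    "ecc_low": lo,
                    "ecc_high": hi,
                    "type_low": t_lo,
                    "type_high": t_hi,
                    "predicted": predicted_proportion(
                        hypothesis, experiment, lighting, (lo, hi), (t_lo, t_hi)
                    ),
                }
            )
    return pd.DataFrame(rows)
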
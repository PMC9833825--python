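"""Phenotype classification on normalized two-channel fluorescence.

Populations (and single cells) land in four regions of the
(yfp_norm, cfp_norm) plane:

* ANCESTRAL — neither channel elevated;
* YFP_PLUS — expression up at single-copy CFP (promoter point mutants);
* YFP_CFP_PLUS — both channels up together, YFP/CFP near the amplification
  diagonal (pure copy-number mutants);
* MIXED — CFP up and YFP elevated beyond the amplification diagonal,
  the signature of combination mutants (or of a mixture of the two pure
  mutant types within one population).

The real experiment drew these boundaries by eye; the thresholds here are
explicit, configurable and reported alongside any output.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .model_core import AlleleParams
from .reporter import ReporterParams, population_fluorescence

__all__ = [
    "FractionLabel",
    "Thresholds",
    "classify_population",
    "classify_values",
    "classify_events",
    "detect_combination",
    "fraction_table",
]


class FractionLabel(str, Enum):
    ANCESTRAL = "ancestral"
    YFP_PLUS = "yfp_plus"
    YFP_CFP_PLUS = "yfp_cfp_plus"
    MIXED = "mixed"


@dataclass(frozen=True)
class Thresholds:
    """Gating cutoffs on ancestral-normalized fluorescence.

    theta_y / theta_c: elevation cutoffs for YFP and CFP (fold over
    ancestral).  rho: YFP/CFP ratio separating pure amplification from the
    mixed fraction.  detection_floor: minimum subpopulation frequency
    callable from single-cell events.
    """

    theta_y: float = 1.5
    theta_c: float = 1.5
    rho: float = 1.5
    detection_floor: float = 0.01

    def __post_init__(self) -> None:
        if min(self.theta_y, self.theta_c, self.rho) <= 1:
            raise ValueError("theta_y, theta_c and rho must be > 1")
        if not 0 < self.detection_floor < 0.5:
            raise ValueError("detection_floor must be in (0, 0.5)")


def classify_values(
    yfp_norm: np.ndarray, cfp_norm: np.ndarray, t: Thresholds
) -> np.ndarray:
    """Vectorized four-way rule; returns an object array of FractionLabel.

    cfp <= theta_c: ANCESTRAL if yfp <= theta_y else YFP_PLUS.
    cfp >  theta_c: YFP_CFP_PLUS if yfp/cfp <= rho else MIXED.
    The four rules partition the positive quadrant exactly.
    """
    yfp = np.asarray(yfp_norm, dtype=float)
    cfp = np.asarray(cfp_norm, dtype=float)
    if np.any(yfp <= 0) or np.any(cfp <= 0):
        raise ValueError("normalized fluorescence must be > 0")
    out = np.empty(yfp.shape, dtype=object)
    low_c = cfp <= t.theta_c
    out[low_c & (yfp <= t.theta_y)] = FractionLabel.ANCESTRAL
    out[low_c & (yfp > t.theta_y)] = FractionLabel.YFP_PLUS
    ratio = yfp / cfp
    out[~low_c & (ratio <= t.rho)] = FractionLabel.YFP_CFP_PLUS
    out[~low_c & (ratio > t.rho)] = FractionLabel.MIXED
    return out


def classify_population(yfp_norm: float, cfp_norm: float, t: Thresholds) -> FractionLabel:
    """Classify one population's bulk normalized fluorescence."""
    return classify_values(np.array([yfp_norm]), np.array([cfp_norm]), t)[0]


def classify_events(
    events: pd.DataFrame,
    ancestral_ref: pd.DataFrame,
    t: Thresholds,
) -> tuple[np.ndarray, dict[FractionLabel, float]]:
    """Per-cell classification of an event table against an ancestral control.

    Events are normalized channel-wise by the medians of the ancestral
    reference sample (median, not mean, for outlier robustness), then run
    through the population rule per event.  Returns (labels, frequencies);
    frequencies cover all four labels and sum to 1.
    """
    if len(events) == 0 or len(ancestral_ref) == 0:
        raise ValueError("event tables must be non-empty")
    y_med = float(ancestral_ref["yfp"].median())
    c_med = float(ancestral_ref["cfp"].median())
    labels = classify_values(events["yfp"].to_numpy() / y_med, events["cfp"].to_numpy() / c_med, t)
    n = len(labels)
    freqs = {lab: sum(1 for x in labels if x is lab) / n for lab in FractionLabel}
    return labels, freqs


def detect_combination(
    events: pd.DataFrame, ancestral_ref: pd.DataFrame, t: Thresholds
) -> bool:
    """True iff the MIXED (combination-mutant) fraction reaches the floor."""
    _, freqs = classify_events(events, ancestral_ref, t)
    return freqs[FractionLabel.MIXED] >= t.detection_floor


def fraction_table(
    trajectories,
    a: AlleleParams,
    p: ReporterParams,
    t: Thresholds,
    condition: str = "default",
) -> pd.DataFrame:
    """Replicate counts per fraction label, per day.

    Applies bulk fluorescence then the four-way rule to every snapshot of
    every trajectory.  Returns a tidy DataFrame (condition, day, label,
    count); counts over labels sum to the number of replicates for each day.
    Deterministic given its inputs (bulk fluorescence is noiseless).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    rows = []
    for traj in trajectories:
        for st in traj.states:
            yn, cn = population_fluorescence(st, a, p)
            rows.append((st.day, classify_population(yn, cn, t)))
    df = pd.DataFrame(rows, columns=["day", "label"])
    counts = (
        df.groupby(["day", "label"], observed=False).size().reset_index(name="count")
    )
    full = []
    for day in sorted(df["day"].unique()):
        for lab in FractionLabel:
            sel = counts[(counts["day"] == day) & (counts["label"] == lab)]
            full.append((condition, int(day), lab.value, int(sel["count"].sum())))
    return pd.DataFrame(full, columns=["condition", "day", "label", "count"])
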
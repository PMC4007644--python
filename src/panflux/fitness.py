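"""Mutant-fitness evaluation of model growth predictions.

Pooled transposon-mutant experiments yield a fitness z-score per mutant
per experiment; strongly negative scores mean the mutant failed to
compete, i.e. could not grow.  A cutoff of -3.5 separates growth from
no-growth calls.  Experiments map many-to-one onto conditions the models
can simulate; replicate experiments for the same condition are combined
by majority vote, and exact ties are left undetermined and excluded from
scoring.  Model knockout predictions are then scored against the calls
as overall accuracy, false-positive rate (model grows, data does not)
and false-negative rate (model does not grow, data does), and the
sensitivity of these rates to the cutoff can be swept.

Also provides the plate-reader growth-curve reductions used for wet-lab
comparison: exponential growth rate as the slope of ln(OD) vs time, and
biomass yield as stationary-minus-initial OD per mmol of substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFF",
    "GrowthCall",
    "EvaluationSummary",
    "call_growth",
    "call_growth_table",
    "evaluate_predictions",
    "cutoff_sensitivity",
    "read_fitness_table",
    "read_condition_map",
    "apply_condition_map",
    "growth_rate",
    "biomass_yield",
]

#: Fitness z-score below which a mutant is considered unable to grow.
DEFAULT_CUTOFF = -3.5

GROWTH = "growth"
NO_GROWTH = "no_growth"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class GrowthCall:
    gene: str
    condition: str
    call: str  # growth | no_growth | undetermined


@dataclass
class EvaluationSummary:
    """Confusion summary over compared (non-undetermined) calls.

    Percentages are of compared calls, so accuracy + false_positive +
    false_negative = 100 whenever anything was compared.
    """

    n_compared: int
    accuracy: float
    false_positive: float
    false_negative: float
    n_undetermined: int = 0
    n_missing_prediction: int = 0

    @property
    def empty(self) -> bool:
        return self.n_compared == 0


def call_growth(z_scores: Sequence[float], cutoff: float = DEFAULT_CUTOFF) -> str:
    """Combine replicate z-scores for one mutant x condition into a call.

    Majority of replicates above the cutoff means growth, majority below
    means no growth, an exact tie is undetermined.  A score exactly at
    the cutoff counts on the growth side (the rule is strict on both
    sides of the cutoff; equality has to land somewhere).
    """
    scores = list(z_scores)
    if not scores:
        raise ValueError("need at least one z-score")
    above = sum(1 for z in scores if z >= cutoff)
    below = len(scores) - above
    if above > below:
        return GROWTH
    if below > above:
        return NO_GROWTH
    return UNDETERMINED


def call_growth_table(
    records: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> List[GrowthCall]:
    """Growth calls for every (gene, condition) in a fitness record table.

    *records* needs columns ``gene``, ``condition``, ``z``.
    """
    calls = []
    for (gene, condition), group in records.groupby(["gene", "condition"],
                                                    sort=True):
        calls.append(GrowthCall(
            gene=gene, condition=condition,
            call=call_growth(group["z"].to_numpy(), cutoff),
        ))
    return calls


def evaluate_predictions(
    predictions: Mapping[Tuple[str, str], bool],
    calls: Sequence[GrowthCall],
) -> EvaluationSummary:
    """Score model growth predictions against experimental calls.

    Undetermined calls are excluded; calls without a matching prediction
    are counted in ``n_missing_prediction`` and skipped.  False positive:
    model predicts growth, data says no growth.  False negative: the
    opposite.
    """
    n_correct = n_fp = n_fn = n_und = n_missing = 0
    for call in calls:
        if call.call == UNDETERMINED:
            n_und += 1
            continue
        key = (call.gene, call.condition)
        if key not in predictions:
            n_missing += 1
            continue
        predicted = predictions[key]
        observed = call.call == GROWTH
        if predicted == observed:
            n_correct += 1
        elif predicted and not observed:
            n_fp += 1
        else:
            n_fn += 1
    n_compared = n_correct + n_fp + n_fn
    if n_compared == 0:
        return EvaluationSummary(0, 0.0, 0.0, 0.0, n_und, n_missing)
    return EvaluationSummary(
        n_compared=n_compared,
        accuracy=100.0 * n_correct / n_compared,
        false_positive=100.0 * n_fp / n_compared,
        false_negative=100.0 * n_fn / n_compared,
        n_undetermined=n_und,
        n_missing_prediction=n_missing,
    )


def cutoff_sensitivity(
    records: pd.DataFrame,
    predictions: Mapping[Tuple[str, str], bool],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Prediction-error rates as a function of the z-score cutoff.

    One :func:`evaluate_predictions` summary per cutoff, with growth
    calls re-derived at that cutoff.  Returns a DataFrame indexed by
    cutoff with columns ``n_compared``, ``accuracy``, ``false_positive``,
    ``false_negative``.
    """
    rows = []
    for cutoff in cutoffs:
        calls = call_growth_table(records, cutoff)
        summary = evaluate_predictions(predictions, calls)
        rows.append({
            "cutoff": cutoff,
            "n_compared": summary.n_compared,
            "accuracy": summary.accuracy,
            "false_positive": summary.false_positive,
            "false_negative": summary.false_negative,
        })
    return pd.DataFrame(rows).set_index("cutoff")


# ---------------------------------------------------------------------------
# tabular I/O

def read_fitness_table(path: str) -> pd.DataFrame:
    """Read a TSV of fitness scores with columns gene, experiment, z."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "experiment": str})
    missing = {"gene", "experiment", "z"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(frame["z"]).all():
        raise ValueError(f"{path}: non-finite z-scores")
    return frame


def read_condition_map(path: str) -> pd.DataFrame:
    """Read the experiment -> simulatable-condition mapping TSV.

    Columns: ``experiment``, ``condition``, ``include`` (0/1 flag;
    experiments excluded from evaluation — e.g. stationary-phase or
    rich-supplement runs — carry 0).
    """
    frame = pd.read_csv(path, sep="\t",
                        dtype={"experiment": str, "condition": str})
    missing = {"experiment", "condition", "include"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def apply_condition_map(records: pd.DataFrame,
                        condition_map: pd.DataFrame) -> pd.DataFrame:
    """Attach condition ids to fitness records, dropping excluded experiments."""
    keep = condition_map[condition_map["include"].astype(int) == 1]
    merged = records.merge(keep[["experiment", "condition"]], on="experiment",
                           how="inner")
    return merged


# ---------------------------------------------------------------------------
# growth curves

def growth_rate(
    times: Sequence[float],
    od: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
    window_fraction: float = 0.3,
) -> float:
    """Exponential growth rate (1/h): slope of ln(OD) against time.

    With an explicit ``window`` (t_start, t_end) the fit uses those
    points; otherwise a sliding window covering *window_fraction* of the
    readings picks the maximal-slope stretch of the curve.  At least
    three points are required and OD must be positive on the fitted
    window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and OD must be 1-D and the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    def fit(idx) -> float:
        if np.any(y[idx] <= 0):
            raise ValueError("non-positive OD reading in the fitted window")
        slope, _ = np.polyfit(t[idx], np.log(y[idx]), 1)
        return float(slope)

    if window is not None:
        idx = np.where((t >= window[0]) & (t <= window[1]))[0]
        if idx.size < 3:
            raise ValueError("fewer than 3 points in the requested window")
        return fit(idx)
    size = max(3, int(round(window_fraction * t.size)))
    if t.size < 3:
        raise ValueError("need at least 3 readings")
    best = -np.inf
    for start in range(0, t.size - size + 1):
        best = max(best, fit(np.arange(start, start + size)))
    return best


def biomass_yield(
    times: Sequence[float],
    od: Sequence[float],
    substrate_mmol: float,
    plateau_fraction: float = 0.2,
    plateau_tolerance: float = 0.02,
) -> float:
    """Biomass yield in OD units per mmol of substrate.

    Stationary-phase OD (mean of the trailing *plateau_fraction* of
    readings, which must vary by less than *plateau_tolerance* in OD,
    relative to the curve's range) minus starting OD, divided by the
    substrate amount supplied.
    """
    if substrate_mmol <= 0:
        raise ValueError("substrate amount must be positive")
    y = np.asarray(od, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    n_tail = max(2, int(round(plateau_fraction * y.size)))
    tail = y[-n_tail:]
    span = y.max() - y.min()
    if span > 0 and (tail.max() - tail.min()) > plateau_tolerance * max(span, 1e-12):
        raise ValueError("no stationary-phase plateau detected at the curve's end")
    return float((tail.mean() - y[0]) / substrate_mmol)
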
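"""Group-level statistics and reporting.

Single-vesicle parameters are summarized hierarchically: the median of
each parameter is taken per cell (medians are robust to the long-tailed
event distributions amperometry produces) and cells are then averaged,
with cells contributing fewer than a minimum number of events excluded.
Also here: empirical cumulative distributions for event-level displays,
ordinary least-squares regression of kinetic parameters against TMD
beta-branched content, and the intensity-weighted Mander's colocalization
coefficient used for sorting analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellSummary",
    "ColocResult",
    "GroupSummary",
    "mean_of_medians",
    "cumulative_distribution",
    "composition_correlation",
    "manders_weighted",
]

MIN_EVENTS_DEFAULT = 20     # cells need strictly more events than this


@dataclass
class CellSummary:
    cell_id: str
    construct: str
    n_events: int
    median_per_parameter: dict[str, float]


class GroupSummary(NamedTuple):
    mean: float
    sem: float          # nan when only one qualifying cell
    n_cells: int


@dataclass
class ColocResult:
    coefficient: float
    threshold_sd_multiple: float


def mean_of_medians(events: pd.DataFrame, parameter: str,
                    cell_column: str = "cell_id",
                    min_events: int = MIN_EVENTS_DEFAULT) -> GroupSummary:
    """Mean +/- SEM across cells of the per-cell parameter median.

    A cell qualifies only with strictly more than ``min_events`` events
    (the default reproduces the ">20 events" inclusion rule). SEM is
    undefined (nan) with a single qualifying cell.
    """
    if parameter not in events.columns:
        raise KeyError(f"no column {parameter!r} in events table")
    counts = events.groupby(cell_column)[parameter].count()
    qualifying = counts[counts > min_events].index
    if len(qualifying) == 0:
        raise ValueError(
            f"no cell has more than {min_events} events")
    medians = (events[events[cell_column].isin(qualifying)]
               .groupby(cell_column)[parameter].median())
    n = len(medians)
    sem = float(medians.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(mean=float(medians.mean()), sem=sem, n_cells=n)


def cumulative_distribution(values) -> np.ndarray:
    """ECDF point set: (sorted value, cumulative fraction) rows.

    Uses the i/n convention with ties sharing the fraction of their last
    occurrence, so the ECDF is right-continuous, non-decreasing, and ends
    at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build an ECDF from no values")
    x = np.sort(values)
    frac = np.searchsorted(x, x, side="right") / x.size
    return np.column_stack([x, frac])


class Regression(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def composition_correlation(x, y) -> Regression:
    """OLS line of a kinetic parameter against beta-branched content.

    Quantifies the proportionality between fusion-pore kinetics and the
    number of V/I residues across constructs. Requires >= 3 points and
    nonzero x-variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:  # flat response: zero slope, nothing explained
        return Regression(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return Regression(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=float(res.rvalue ** 2))


def manders_weighted(intensity_a: np.ndarray, intensity_b: np.ndarray,
                     background_sd: float, threshold_multiple: float = 6.0,
                     threshold_a: bool = True) -> ColocResult:
    """Intensity-weighted Mander's colocalization of channel a with b.

    Channel b is thresholded at ``threshold_multiple x background_sd``
    (default 6x the background sd); the coefficient is the summed channel-a
    intensity on above-threshold b pixels divided by the total channel-a
    intensity. With ``threshold_a`` (default) channel a is thresholded the
    same way on both sides of the ratio, so only genuine a-signal enters.
    """
    a = np.asarray(intensity_a, dtype=float)
    b = np.asarray(intensity_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("intensity arrays must have the same shape")
    if background_sd <= 0:
        raise ValueError("background_sd must be positive")
    thr = threshold_multiple * background_sd
    mask_b = b > thr
    support_a = (a > thr) if threshold_a else np.ones_like(mask_b)
    denom = float(a[support_a].sum())
    if denom == 0:
        raise ValueError("no channel-a signal above threshold")
    numer = float(a[mask_b & support_a].sum())
    return ColocResult(coefficient=numer / denom,
                       threshold_sd_multiple=threshold_multiple)


def events_to_frame(analyzed, cell_id: str = "") -> pd.DataFrame:
    """Flatten (SpikeEvent, FootSignal) pairs into one row per event."""
    rows = []
    for ev, foot in analyzed:
        row = {
            "cell_id": ev.cell_id or cell_id,
            "peak_time_s": ev.peak_time,
            "amplitude_pA": ev.amplitude,
            "charge_fC": ev.charge,
            "rise_time_us": ev.rise_time_50_90,
            "half_width_ms": ev.half_width,
            "unreliable": ev.unreliable,
        }
        if foot is not None:
            row.update({
                "foot_duration_ms": foot.duration,
                "foot_amplitude_pA": foot.amplitude,
                "foot_charge_fC": foot.charge,
                "fluct_pos": foot.fluct_pos,
                "fluct_neg": foot.fluct_neg,
                "fluct_frequency_per_ms": foot.fluct_frequency,
                "deriv_rms_pA_per_ms": foot.deriv_rms,
            })
        rows.append(row)
    return pd.DataFrame(rows)
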
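"""Amperometric spike and prespike-foot analysis.

Carbon-fiber amperometry resolves catecholamine discharge from single
vesicles as a current spike, often preceded by a low-amplitude "foot"
plateau reporting flux through the narrow initial fusion pore. This module
detects events on a current trace and computes the standard single-event
statistics:

* main spike: baseline-subtracted amplitude, charge, 50-90% rise time,
  half width;
* prespike foot: onset/end, duration, mean amplitude, charge;
* fusion-pore jitter: the number of suprathreshold excursions of the
  low-pass-filtered current derivative during the foot, divided by the
  foot duration (fluctuation frequency), and the threshold-independent rms
  of the mean-subtracted derivative.

Default thresholds follow standard practice for chromaffin-cell
recordings: signals acquired at 25 kHz and filtered at 2 kHz; events kept
for frequency analysis when the charge lies in 10-5000 fC and the peak
amplitude exceeds 4 pA, with a stricter 7 pA cut for single-spike
characteristics; feet analyzed for fluctuations when longer than 2 ms,
with the derivative additionally filtered at 1.2 kHz and counted against a
+/-6 pA/ms threshold (about 4x the baseline derivative noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import Trace, gaussian_lowpass

__all__ = [
    "SpikeEvent",
    "FootSignal",
    "DetectionConfig",
    "lowpass",
    "estimate_baseline",
    "detect_events",
    "spike_params",
    "detect_foot",
    "foot_fluctuations",
    "foot_rms_derivative",
    "event_frequency",
    "analyze_trace",
]


@dataclass
class DetectionConfig:
    """Event-selection and filter settings (all units as documented)."""

    lowpass_cutoff: float = 2000.0      # Hz, acquisition-equivalent low pass
    deriv_cutoff: float = 1200.0        # Hz, extra filtering of the derivative
    amp_threshold_freq: float = 4.0     # pA, selection for frequency analysis
    amp_threshold_spike: float = 7.0    # pA, selection for spike characteristics
    charge_min: float = 10.0            # fC
    charge_max: float = 5000.0          # fC
    deriv_threshold: float = 6.0        # pA/ms, foot fluctuation threshold
    foot_min_duration: float = 2.0      # ms, minimum foot for fluctuation stats
    min_events_per_cell: int = 20       # cells need > this many events
    foot_onset_sd_multiple: float = 4.0  # foot onset crossing level, x baseline sd
    min_event_width_ms: float = 0.3     # reject narrower threshold crossings
    min_split_separation_ms: float = 2.0  # peaks closer than this never split
    edge_margin_ms: float = 0.5         # foot interior margin for derivative stats
    # Open choices surfaced as switches:
    foot_summary_on_spike_amplitude: bool = True   # 7 pA cut on spike (not foot)
    rise_time_max_us: float | None = None          # optional rise-time cut, off

    def __post_init__(self) -> None:
        if not self.charge_min < self.charge_max:
            raise ValueError("charge_min must be < charge_max")
        for name in ("lowpass_cutoff", "deriv_cutoff", "amp_threshold_freq",
                     "amp_threshold_spike", "deriv_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpikeEvent:
    """One amperometric fusion event's main-spike parameters."""

    peak_time: float                # s
    amplitude: float                # pA, baseline-subtracted peak
    charge: float                   # fC, integral over the event window
    event_window: tuple[int, int]   # [start, end) sample indices
    baseline: float                 # pA
    rise_time_50_90: float | None = None   # microseconds
    half_width: float | None = None        # ms
    cell_id: str = ""
    unreliable: bool = False        # peak at window edge etc.

    @property
    def peak_index(self) -> int:
        return self._peak_index

    _peak_index: int = field(default=0, repr=False)


@dataclass
class FootSignal:
    """Prespike-foot parameters of one event."""

    onset_time: float               # s
    end_time: float                 # s
    duration: float                 # ms
    amplitude: float                # pA, mean plateau above baseline
    charge: float                   # fC
    fluct_pos: int | None = None
    fluct_neg: int | None = None
    fluct_frequency: float | None = None    # excursions per ms
    deriv_rms: float | None = None          # pA/ms
    fluct_applicable: bool = True   # False when duration < minimum


# ---------------------------------------------------------------------------
# filtering and baseline
# ---------------------------------------------------------------------------

def lowpass(trace: Trace, cutoff: float) -> Trace:
    """Zero-phase Gaussian low-pass copy of a trace (-3 dB at ``cutoff``)."""
    filtered = gaussian_lowpass(trace.samples, trace.fs, cutoff)
    out = trace.copy_with(filtered)
    out.meta["lowpass_cutoff"] = cutoff
    return out


def estimate_baseline(trace: Trace,
                      window: tuple[float, float]) -> tuple[float, float]:
    """Robust baseline level and noise sd of an event-free window.

    The window is linearly detrended; the level is the median and the sd a
    MAD-based estimate of the residuals, both robust to drift and to any
    stray event contaminating the window.
    """
    seg = trace.segment(*window)
    if seg.size < 2:
        raise ValueError("baseline window too short")
    x = np.arange(seg.size)
    slope, intercept = np.polyfit(x, seg, 1)
    resid = seg - (slope * x + intercept)
    level = float(np.median(seg))
    sd = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    return level, sd


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(trace: Trace, cfg: DetectionConfig | None = None,
                  baseline: tuple[float, float] | None = None,
                  cell_id: str = "") -> list[SpikeEvent]:
    """Detect amperometric events on a low-pass-filtered current trace.

    Candidate events are maximal disjoint regions where the signal exceeds
    baseline by the detection amplitude criterion; windows are then grown
    outward to the re-crossing of baseline + 1 sd, and adjacent events
    sharing a window are split at the local minimum between peaks. Each
    event's charge is the baseline-subtracted trapezoidal integral over
    its window. Events failing the amplitude (>4 pA) or charge
    (10-5000 fC) selection are dropped.

    ``baseline`` is (level, sd); when omitted it is estimated from the
    quietest stretch of the trace.
    """
    cfg = cfg or DetectionConfig()
    if trace.kind != "current":
        raise ValueError("event detection requires a current trace")
    if trace.meta.get("lowpass_cutoff") is None:
        raise ValueError(
            "trace must be low-pass filtered first (see lowpass())")
    x = trace.samples
    if baseline is None:
        baseline = _auto_baseline(trace)
    level, sd = baseline

    detect_level = level + max(cfg.amp_threshold_freq, 3.0 * sd)
    grow_level = level + sd
    min_width = max(1, int(round(cfg.min_event_width_ms * 1e-3 * trace.fs)))

    above_grow = x > grow_level
    windows: list[tuple[int, int]] = []
    for s, e in _regions(x > detect_level):
        if e - s < min_width:
            continue
        while s > 0 and above_grow[s - 1]:
            s -= 1
        while e < x.size and above_grow[e]:
            e += 1
        if windows and s <= windows[-1][1]:
            ps, pe = windows[-1]
            if e > pe:
                windows[-1] = (ps, e)
        else:
            windows.append((s, e))

    min_prominence = detect_level - level
    min_sep = max(1, int(round(cfg.min_split_separation_ms * 1e-3 * trace.fs)))
    events: list[SpikeEvent] = []
    for s, e in windows:
        for ws, we in _split_at_minima(x, s, e, detect_level, min_prominence,
                                       min_sep):
            events.append(_make_event(trace, ws, we, level, cell_id))

    kept = [ev for ev in events
            if ev.amplitude > cfg.amp_threshold_freq
            and cfg.charge_min <= ev.charge <= cfg.charge_max]
    kept.sort(key=lambda ev: ev.peak_time)
    return kept


def _auto_baseline(trace: Trace) -> tuple[float, float]:
    """Baseline from the quietest 200 ms stretch (lowest spread)."""
    n_win = max(2, int(round(0.2 * trace.fs)))
    best, best_spread = None, np.inf
    for s in range(0, trace.n - n_win + 1, n_win // 2 or 1):
        seg = trace.samples[s:s + n_win]
        spread = np.percentile(seg, 99) - np.percentile(seg, 1)
        if spread < best_spread:
            best_spread, best = spread, (s, s + n_win)
    t0 = trace.t0
    return estimate_baseline(
        trace, (t0 + best[0] / trace.fs, t0 + best[1] / trace.fs))


def _split_at_minima(x: np.ndarray, s: int, e: int, detect_level: float,
                     min_prominence: float,
                     min_separation: int) -> list[tuple[int, int]]:
    """Split a window holding several overlapping spikes at local minima.

    Peaks qualify only with prominence at least the detection amplitude,
    and two peaks are separated only when the valley between them drops
    below 25% of the lower peak and the peaks lie at least the minimum
    separation apart: a prespike foot, a flicker apex or a noise dip on a
    flank never splits an event, while clearly resolved overlapping
    spikes are cut at the minimum between their peaks.
    """
    from scipy.signal import find_peaks

    sub = x[s:e]
    peaks, _ = find_peaks(sub, height=detect_level,
                          prominence=min_prominence)
    if peaks.size <= 1:
        return [(s, e)]
    base = detect_level - min_prominence  # baseline level
    cuts = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        valley = sub[a:b + 1].min()
        lower_peak = min(sub[a], sub[b])
        if (b - a >= min_separation
                and valley - base < 0.25 * (lower_peak - base)):
            cuts.append(int(a + np.argmin(sub[a:b + 1])))
    if not cuts:
        return [(s, e)]
    bounds = [s] + [s + c for c in cuts] + [e]
    return list(zip(bounds[:-1], bounds[1:]))


def _make_event(trace: Trace, s: int, e: int, level: float,
                cell_id: str) -> SpikeEvent:
    x = trace.samples
    seg = x[s:e]
    pk = s + int(np.argmax(seg))
    t = trace.times
    # 1 pA*ms = 1 fC, so integrate with dx in ms
    charge = float(np.trapezoid(x[s:e] - level, dx=trace.dt * 1e3))
    ev = SpikeEvent(
        peak_time=float(t[pk]),
        amplitude=float(x[pk] - level),
        charge=charge,
        event_window=(s, e),
        baseline=level,
        cell_id=cell_id,
        unreliable=(pk <= s or pk >= e - 1),
    )
    ev._peak_index = pk
    return ev


# ---------------------------------------------------------------------------
# spike parametrization
# ---------------------------------------------------------------------------

def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool = True, last: bool = False) -> float | None:
    """Linearly interpolated time of a crossing of ``level``.

    Returns the first matching crossing, or the last one when ``last`` is
    set (used for the rising phase, where the crossing adjacent to the
    peak is the relevant one).
    """
    above = y >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    if last:
        idx = idx[::-1]
    for i in idx:
        if (rising and y[i + 1] > y[i]) or (not rising and y[i + 1] < y[i]):
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def spike_params(trace: Trace, event: SpikeEvent) -> SpikeEvent:
    """Complete an event with rise time (50-90%, us) and half width (ms).

    Both are computed by linear interpolation between samples on the
    baseline-subtracted waveform: the rise time on the rising phase from
    50% to 90% of the peak amplitude, the half width as the full width at
    half-maximal amplitude. An event whose peak sits at the window edge is
    flagged unreliable and excluded from summaries.
    """
    s, e = event.event_window
    pk = event._peak_index
    if pk <= s or pk >= e - 1:
        return replace(event, unreliable=True)
    t = trace.times
    y = trace.samples - event.baseline
    amp = event.amplitude

    t50 = _interp_crossing(t[s:pk + 1], y[s:pk + 1], 0.5 * amp, last=True)
    t90 = _interp_crossing(t[s:pk + 1], y[s:pk + 1], 0.9 * amp, last=True)
    rise_us = None
    if t50 is not None and t90 is not None and t90 >= t50:
        rise_us = (t90 - t50) * 1e6

    # half width: last upward crossing before peak, first downward after
    up = _interp_crossing(t[s:pk + 1], y[s:pk + 1], 0.5 * amp, last=True)
    down = _interp_crossing(t[pk:e], y[pk:e], 0.5 * amp, rising=False)
    hw_ms = None
    if up is not None and down is not None:
        hw_ms = (down - up) * 1e3

    out = replace(event, rise_time_50_90=rise_us, half_width=hw_ms)
    out._peak_index = pk
    return out


# ---------------------------------------------------------------------------
# prespike foot
# ---------------------------------------------------------------------------

def detect_foot(trace: Trace, event: SpikeEvent,
                cfg: DetectionConfig | None = None,
                baseline_sd: float | None = None) -> FootSignal | None:
    """Locate the prespike foot of a detected event.

    Foot onset is the last upward crossing of baseline + 4x(baseline sd)
    preceding the spike with sustained elevation up to the spike rise.
    The foot end (= spike onset) is found by back-extrapolating the
    maximal-slope line of the spike rising phase down to the foot plateau
    level. Returns None when the event has no resolvable plateau (duration
    under one sample, or the putative plateau is not distinct from the
    spike rise).
    """
    cfg = cfg or DetectionConfig()
    s, e = event.event_window
    pk = event._peak_index
    x = trace.samples
    t = trace.times
    if baseline_sd is None:
        _, baseline_sd = _auto_baseline(trace)
    level = event.baseline
    onset_level = level + cfg.foot_onset_sd_multiple * max(baseline_sd, 1e-12)

    # maximal slope sample of the rising phase
    if pk - s < 2:
        return None
    d = np.gradient(x[s:pk + 1], t[s:pk + 1])
    m = s + int(np.argmax(d))
    max_slope = float(d[m - s])
    if max_slope <= 0:
        return None

    # onset: walk back from the max-slope point to the last sustained
    # upward crossing of the 4-sd level. Sub-threshold dips shorter than
    # 0.3 ms are noise, not a return to baseline, and are stepped over.
    allow = max(1, int(round(0.3e-3 * trace.fs)))
    i = m
    below_run = 0
    while i > 0:
        if x[i - 1] > onset_level:
            below_run = 0
        else:
            below_run += 1
            if below_run > allow:
                break
        i -= 1
    if i == 0 and below_run <= allow:
        return None  # trace elevated from the start: onset not locatable
    onset_idx = i + below_run - 1  # first above-level sample after the gap
    if onset_idx >= m or onset_idx < 1:
        return None
    onset_time = _interp_crossing(t[i - 1:i + 1], x[i - 1:i + 1], onset_level)
    if onset_time is None:
        onset_time = float(t[onset_idx])

    # plateau level: median of the stretch between onset and the start of
    # the spike's steep rise. The rise start is the beginning of the
    # contiguous run of steep slope (>20% of max) attached to the
    # max-slope point — scanning backward avoids mistaking the foot's own
    # onset step (or a flicker limb) for the spike rise.
    if m <= onset_idx + 1:
        return None
    d_win = np.gradient(x[onset_idx:m + 1], t[onset_idx:m + 1])
    j = m
    while j > onset_idx + 1 and d_win[j - 1 - onset_idx] > 0.2 * max_slope:
        j -= 1
    rise_start = j
    if rise_start <= onset_idx + 1:
        return None
    plateau = float(np.median(x[onset_idx:rise_start]))

    # foot end: intersection of the max-slope line with the plateau level
    t_end = float(t[m]) - (float(x[m]) - plateau) / max_slope
    duration_ms = (t_end - onset_time) * 1e3
    if duration_ms < 1e3 / trace.fs:
        return None

    end_idx = max(trace.index_at(t_end), onset_idx + 1)
    seg = x[onset_idx:end_idx]
    amplitude = float(np.mean(seg) - level)
    charge = float(np.trapezoid(seg - level, dx=trace.dt * 1e3))  # fC
    return FootSignal(
        onset_time=onset_time,
        end_time=t_end,
        duration=duration_ms,
        amplitude=amplitude,
        charge=charge,
    )


def _foot_derivative(trace: Trace, foot: FootSignal,
                     cfg: DetectionConfig) -> np.ndarray:
    """1.2 kHz-filtered current derivative (pA/ms) over the foot window.

    The derivative is computed and filtered on a padded window so filter
    edge effects do not leak into the foot segment.
    """
    pad = int(round(5e-3 * trace.fs))  # 5 ms of context on each side
    i0 = max(trace.index_at(foot.onset_time) - pad, 0)
    i1 = min(trace.index_at(foot.end_time) + pad, trace.n)
    seg = trace.samples[i0:i1]
    d = np.gradient(seg, trace.dt * 1e3)  # pA/ms
    d = gaussian_lowpass(d, trace.fs, cfg.deriv_cutoff)
    # Trim the filter-spread of the foot-onset step and of the spike rise:
    # only flux fluctuations inside the plateau are pore jitter.
    margin = int(round(cfg.edge_margin_ms * 1e-3 * trace.fs))
    j0 = trace.index_at(foot.onset_time) - i0 + margin
    j1 = trace.index_at(foot.end_time) - i0 - margin
    if j1 - j0 < 2:  # very short foot: fall back to the untrimmed window
        j0, j1 = j0 - margin, j1 + margin
    return d[j0:j1]


def foot_fluctuations(trace: Trace, foot: FootSignal,
                      cfg: DetectionConfig | None = None) -> FootSignal:
    """Count suprathreshold derivative excursions during the foot.

    The current derivative over the foot is low-pass filtered at
    ``cfg.deriv_cutoff`` (1.2 kHz); each contiguous excursion above
    +threshold or below -threshold counts once. The fluctuation frequency
    is (positive + negative counts) / foot duration, in excursions per ms.
    Feet shorter than ``cfg.foot_min_duration`` (2 ms) are marked not
    applicable.
    """
    cfg = cfg or DetectionConfig()
    if foot.duration < cfg.foot_min_duration:
        return replace(foot, fluct_applicable=False)
    d = _foot_derivative(trace, foot, cfg)
    thr = cfg.deriv_threshold
    pos = len(_regions(d > thr))
    neg = len(_regions(d < -thr))
    return replace(foot,
                   fluct_pos=pos,
                   fluct_neg=neg,
                   fluct_frequency=(pos + neg) / foot.duration,
                   fluct_applicable=True)


def foot_rms_derivative(trace: Trace, foot: FootSignal,
                        cfg: DetectionConfig | None = None) -> float | None:
    """Rms of the mean-subtracted filtered derivative over the foot (pA/ms).

    A threshold-independent measure of fusion-pore jitter; None for feet
    shorter than the minimum duration.
    """
    cfg = cfg or DetectionConfig()
    if foot.duration < cfg.foot_min_duration:
        return None
    d = _foot_derivative(trace, foot, cfg)
    d = d - d.mean()
    return float(np.sqrt(np.mean(d ** 2)))


def check_derivative_threshold(trace: Trace, cfg: DetectionConfig,
                               baseline_window: tuple[float, float]) -> float:
    """Cross-check the fluctuation threshold against baseline derivative noise.

    Returns 4x the measured sd of the filtered derivative over an
    event-free window and warns when the configured threshold deviates
    from it by more than a factor of two (the threshold is meant to sit at
    about 4x the baseline derivative noise).
    """
    seg = trace.segment(*baseline_window)
    d = np.gradient(seg, trace.dt * 1e3)
    d = gaussian_lowpass(d, trace.fs, cfg.deriv_cutoff)
    four_sd = 4.0 * float(np.std(d))
    ratio = cfg.deriv_threshold / four_sd if four_sd > 0 else np.inf
    if ratio > 2.0 or ratio < 0.5:
        warnings.warn(
            f"fluctuation threshold {cfg.deriv_threshold} pA/ms deviates "
            f">2x from 4x the measured baseline derivative sd "
            f"({four_sd:.2f} pA/ms)", stacklevel=2)
    return four_sd


# ---------------------------------------------------------------------------
# rates and batch analysis
# ---------------------------------------------------------------------------

def event_frequency(events: list[SpikeEvent], window: float) -> float:
    """Qualifying events per second over an observation window (Hz)."""
    if window <= 0:
        raise ValueError("window must be positive")
    return len(events) / window


def analyze_trace(trace: Trace, cfg: DetectionConfig | None = None,
                  cell_id: str = "") -> list[tuple[SpikeEvent,
                                                   FootSignal | None]]:
    """Full per-trace pipeline: filter, detect, parametrize spikes and feet."""
    cfg = cfg or DetectionConfig()
    filt = lowpass(trace, cfg.lowpass_cutoff)
    level, sd = _auto_baseline(filt)
    events = detect_events(filt, cfg, baseline=(level, sd), cell_id=cell_id)
    out = []
    for ev in events:
        ev = spike_params(filt, ev)
        foot = detect_foot(filt, ev, cfg, baseline_sd=sd)
        if foot is not None:
            foot = foot_fluctuations(filt, foot, cfg)
            if foot.fluct_applicable:
                foot = replace(
                    foot, deriv_rms=foot_rms_derivative(filt, foot, cfg))
        out.append((ev, foot))
    return out
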
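"""Synthetic data with known ground truth.

Three generators emulate the raw material of a single-vesicle exocytosis
study so that every analysis stage is testable without recordings:

* amperometric current traces — fusion events consisting of a prespike
  "foot" plateau (transmitter leaking through the narrow initial fusion
  pore, optionally with sawtooth flicker emulating pore-conductance
  fluctuations) followed by a main spike, on Gaussian baseline noise at
  25 kHz;
* flash-evoked capacitance responses — a double exponential (rapidly and
  slowly releasable pools) plus a linear sustained component, starting
  after a secretory delay;
* alpha-helical C-alpha trajectories — an ideal helix with per-residue
  Gaussian jitter plus rigid-body motion of each frame, emulating the
  flexibility contrast between helix-stabilized and helix-destabilized
  transmembrane domains.

All stochastic draws in a generator call flow from its single integer
seed, so identical seeds give bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "EventTruth",
    "CapTruth",
    "HelixTruth",
    "gen_amperometric_trace",
    "gen_capacitance_trace",
    "gen_helix_trajectory",
    "capacitance_model",
]


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class EventTruth:
    """Ground truth for one amperometric fusion event.

    Times and durations are in milliseconds, currents in pA, charge in fC.
    ``spike_charge`` is required for the rectangular spike kernel (it sets
    the pulse width); for the bi-exponential kernel it may be left None and
    the realized charge is reported in the generator's truth table.
    """

    onset_time: float               # ms from trace start
    foot_duration: float = 0.0      # ms; 0 means no foot
    foot_amplitude: float = 0.0     # pA above baseline
    n_flicker: int = 0              # sawtooth oscillations inserted in the foot
    spike_amplitude: float = 20.0   # pA at peak
    spike_charge: float | None = None   # fC; required for kernel='rect'
    rise_tau: float = 0.1           # ms
    decay_tau: float = 1.0          # ms
    kernel: str = "biexp"           # 'biexp' or 'rect'
    flicker_slope: float = 20.0     # |dI/dt| of each sawtooth limb, pA/ms

    def __post_init__(self) -> None:
        if self.foot_duration < 0:
            raise ValueError("foot_duration must be >= 0")
        if self.spike_amplitude <= 0:
            raise ValueError("spike_amplitude must be > 0")
        if self.n_flicker < 0:
            raise ValueError("n_flicker must be >= 0")
        if self.kernel not in ("biexp", "rect"):
            raise ValueError(f"unknown spike kernel {self.kernel!r}")
        if self.kernel == "rect":
            if self.spike_charge is None or self.spike_charge <= 0:
                raise ValueError("rect kernel requires spike_charge > 0")
        if self.kernel == "biexp" and not (0 < self.rise_tau < self.decay_tau):
            raise ValueError("biexp kernel requires 0 < rise_tau < decay_tau")

    @property
    def spike_onset(self) -> float:
        """Start of the main spike (= end of the foot), ms."""
        return self.onset_time + self.foot_duration

    def kernel_duration(self) -> float:
        """Total support of the event kernel in ms."""
        if self.kernel == "rect":
            spike = self.spike_charge / self.spike_amplitude
        else:
            spike = 10.0 * self.decay_tau
        return self.foot_duration + spike


@dataclass
class CapTruth:
    """Parameters of the flash-evoked capacitance model.

    C(t) = A0                                        for t < flash + delay
    C(t) = A0 + A1(1-e^(-s/tau1)) + A2(1-e^(-s/tau2)) + k*s   afterwards,

    with s = t - (flash_time + delay). A1/tau1 describe the rapidly
    releasable pool, A2/tau2 the slowly releasable pool, k the sustained
    rate of release. ``delay`` is the secretory delay in ms.
    """

    A0: float = 5000.0      # fF
    A1: float = 50.0        # fF
    tau1: float = 0.02      # s
    A2: float = 80.0        # fF
    tau2: float = 0.25      # s
    k: float = 20.0         # fF/s
    delay: float = 3.0      # ms
    flash_time: float = 0.1  # s
    noise_sd: float = 0.0   # fF

    def __post_init__(self) -> None:
        if not self.tau1 < self.tau2:
            raise ValueError("tau1 must be < tau2 (pool identifiability)")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("pool amplitudes must be >= 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    @property
    def onset(self) -> float:
        return self.flash_time + self.delay * 1e-3


@dataclass
class HelixTruth:
    """Parameters of a jittered alpha-helix trajectory.

    ``jitter_sd`` is the per-axis Gaussian displacement sd in nm, scalar or
    one value per residue. ``rigid_motion`` is None (static frames),
    'random' (a random proper rotation + translation per frame), or an
    explicit list of (3x3 rotation, 3-translation-in-nm) pairs.
    """

    n_residues: int = 30
    jitter_sd: float | np.ndarray = 0.02   # nm per axis per residue
    n_frames: int = 100
    frame_dt: float = 0.1                  # ns
    rigid_motion: object = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        sd = np.broadcast_to(np.asarray(self.jitter_sd, dtype=float),
                             (self.n_residues,))
        if np.any(sd < 0):
            raise ValueError("jitter_sd must be >= 0 elementwise")


# ---------------------------------------------------------------------------
# amperometric traces
# ---------------------------------------------------------------------------

def _spike_kernel(event: EventTruth, t_ms: np.ndarray) -> np.ndarray:
    """Spike waveform on times t_ms measured from the spike onset."""
    if event.kernel == "rect":
        width = event.spike_charge / event.spike_amplitude  # ms
        return np.where((t_ms >= 0) & (t_ms < width),
                        event.spike_amplitude, 0.0)
    tr, td = event.rise_tau, event.decay_tau
    # peak of e^(-t/td) - e^(-t/tr) is at t* = tr*td/(td-tr) * ln(td/tr)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    y = np.where(t_ms >= 0,
                 np.exp(-np.maximum(t_ms, 0) / td)
                 - np.exp(-np.maximum(t_ms, 0) / tr), 0.0)
    return event.spike_amplitude * y / peak


def _foot_kernel(event: EventTruth, t_ms: np.ndarray) -> np.ndarray:
    """Foot plateau with optional sawtooth flicker, on times from foot onset."""
    d = event.foot_duration
    y = np.where((t_ms >= 0) & (t_ms < d), event.foot_amplitude, 0.0)
    k = event.n_flicker
    if k > 0 and d > 0:
        # k symmetric triangles evenly spaced in the central 80% of the foot
        # (clear of the onset step and the spike rise); each limb has
        # |slope| = flicker_slope, so each oscillation yields exactly one
        # positive and one negative derivative excursion. The limb width is
        # capped so flicker amplitudes stay small relative to the spike.
        usable = 0.8 * d
        start = 0.1 * d
        half = min(usable / (2 * k), 0.4)   # ms per limb
        amp = event.flicker_slope * half    # pA at the triangle apex
        centers = start + (np.arange(k) + 0.5) * usable / k
        flick = np.zeros_like(t_ms)
        for c in centers:
            flick += np.clip(1.0 - np.abs(t_ms - c) / half, 0.0, None)
        y = y + amp * flick
    return y


def event_kernel(event: EventTruth, t_ms: np.ndarray) -> np.ndarray:
    """Noise-free waveform of one event on absolute trace times (ms)."""
    rel = t_ms - event.onset_time
    return _foot_kernel(event, rel) + _spike_kernel(event,
                                                    rel - event.foot_duration)


def gen_amperometric_trace(
    schedule: list[EventTruth],
    duration: float,
    fs: float = 25_000.0,
    baseline_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Trace, pd.DataFrame]:
    """Render a schedule of fusion events onto Gaussian baseline noise.

    Parameters
    ----------
    schedule : list of EventTruth
        Events to insert; flagged ``overlapping`` in the truth table when
        their kernel supports intersect.
    duration : float
        Trace length in seconds.
    fs : float
        Sampling rate in Hz (>= 10 kHz; default 25 kHz, the gap-free
        digitization rate of carbon-fiber amperometry).
    baseline_sd : float
        White Gaussian baseline noise sd in pA. The acquisition low-pass
        (2 kHz) is applied downstream by the analysis, not here.

    Returns
    -------
    (trace, truth) where ``truth`` has one row per event including its
    realized charge (numeric integral of the noise-free kernel, fC).
    """
    if duration <= 0 or fs <= 0 or baseline_sd < 0:
        raise ValueError("duration and fs must be positive, baseline_sd >= 0")
    if fs < 10_000:
        raise ValueError("amperometric sampling rate must be >= 10 kHz")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt_ms = 1e3 / fs
    clean = np.zeros(n)

    rows = []
    spans = [(e.onset_time, e.onset_time + e.kernel_duration())
             for e in schedule]
    for i, event in enumerate(schedule):
        # render only on the kernel's local support
        i0 = max(int(np.floor(spans[i][0] / dt_ms)) - 1, 0)
        i1 = min(int(np.ceil(spans[i][1] / dt_ms)) + 2, n)
        t_loc = np.arange(i0, i1) * dt_ms
        y = event_kernel(event, t_loc)
        clean[i0:i1] += y
        charge_fc = float(np.trapezoid(y, t_loc))  # pA*ms = fC
        overlapping = any(
            j != i and spans[i][0] < spans[j][1] and spans[j][0] < spans[i][1]
            for j in range(len(schedule)))
        row = asdict(event)
        row["realized_charge_fC"] = charge_fc
        row["overlapping"] = overlapping
        rows.append(row)

    samples = clean
    if baseline_sd > 0:
        samples = samples + rng.normal(0.0, baseline_sd, size=n)
    trace = Trace(samples=samples, fs=fs, kind="current",
                  meta={"baseline_sd": baseline_sd, "seed": seed})
    truth = pd.DataFrame(rows)
    return trace, truth


# ---------------------------------------------------------------------------
# capacitance traces
# ---------------------------------------------------------------------------

def capacitance_model(t: np.ndarray, A0: float, A1: float, tau1: float,
                      A2: float, tau2: float, k: float,
                      onset: float) -> np.ndarray:
    """Noise-free flash-evoked capacitance response.

    Double exponential plus line, all components starting jointly at
    ``onset``; constant A0 before.
    """
    t = np.asarray(t, dtype=float)
    s = np.maximum(t - onset, 0.0)
    return (A0 + A1 * (1.0 - np.exp(-s / tau1))
            + A2 * (1.0 - np.exp(-s / tau2)) + k * s)


def gen_capacitance_trace(truth: CapTruth, duration: float,
                          fs: float = 2000.0, seed: int = 0) -> Trace:
    """Sample the capacitance model with Gaussian noise of ``truth.noise_sd``."""
    if duration <= truth.flash_time:
        raise ValueError("duration must exceed flash_time")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = capacitance_model(t, truth.A0, truth.A1, truth.tau1,
                              truth.A2, truth.tau2, truth.k, truth.onset)
    samples = clean
    if truth.noise_sd > 0:
        samples = samples + rng.normal(0.0, truth.noise_sd, size=n)
    return Trace(samples=samples, fs=fs, kind="capacitance",
                 meta={"truth": asdict(truth), "seed": seed})


# ---------------------------------------------------------------------------
# helix trajectories
# ---------------------------------------------------------------------------

def gen_helix_trajectory(truth: HelixTruth, seed: int = 0):
    """Jittered ideal-helix C-alpha trajectory with rigid-body frame motion.

    Frame f = R_f @ (helix + jitter_f) + t_f, with jitter drawn per residue
    and axis from N(0, jitter_sd^2) (sd in nm, coordinates in Angstrom).
    Atom ordering is identical in every frame.
    """
    from scipy.spatial.transform import Rotation

    from .helixflex import Trajectory, ideal_helix

    rng = np.random.default_rng(seed)
    ref = ideal_helix(truth.n_residues)                   # (n, 3) Angstrom
    sd_A = 10.0 * np.broadcast_to(
        np.asarray(truth.jitter_sd, dtype=float),
        (truth.n_residues,))[:, None]                     # nm -> Angstrom

    motions = truth.rigid_motion
    if motions == "random":
        rots = Rotation.random(truth.n_frames, rng=rng).as_matrix()
        trans = rng.uniform(-50.0, 50.0, size=(truth.n_frames, 3))
    elif motions is None:
        rots = np.broadcast_to(np.eye(3), (truth.n_frames, 3, 3))
        trans = np.zeros((truth.n_frames, 3))
    else:
        rots = np.asarray([np.asarray(r, dtype=float) for r, _ in motions])
        trans = np.asarray([np.asarray(t, dtype=float) * 10.0
                            for _, t in motions])         # nm -> Angstrom
        if len(rots) != truth.n_frames:
            raise ValueError("rigid_motion must give one transform per frame")

    coords = np.empty((truth.n_frames, truth.n_residues, 3))
    for f in range(truth.n_frames):
        jitter = rng.normal(0.0, 1.0, size=ref.shape) * sd_A
        coords[f] = (ref + jitter) @ rots[f].T + trans[f]
    return Trajectory(coords=coords, frame_dt=truth.frame_dt,
                      residue_ids=np.arange(1, truth.n_residues + 1))
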
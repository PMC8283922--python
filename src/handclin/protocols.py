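"""Task stimuli and signal conditioning for the robotic hand-assessment battery.

The assessment battery acts on the index-finger metacarpophalangeal (MCP)
joint through a one degree-of-freedom end-effector. This module is the single
source of truth for the task protocols that both the synthetic simulator and
the metric-extraction code share:

* the multi-sine target trajectories of the trajectory-following task,
* the randomized 21-angle sequence of the gauge position-matching task,
* the fixed start/target pairs of the fast target-reaching task,
* the first-order Butterworth low-pass conditioning applied to velocity and
  force channels before any metric is extracted.

Sign convention (shared by every module): MCP neutral = 0 deg, flexion
positive, extension negative. Simulated positions are saturated to the device
workspace of [-30, +60] deg from neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("handclin")

#: Device sampling rate (Hz).
DEVICE_FS_HZ = 1000.0
#: Cutoff of the real-time low-pass filter on velocity/force channels (Hz).
FILTER_CUTOFF_HZ = 20.0
#: Device workspace around the MCP neutral position (deg): 30 deg extension
#: to 60 deg flexion.
WORKSPACE_DEG = (-30.0, 60.0)

#: Component frequencies of the slow / fast tracking trajectories (Hz).
SLOW_FREQS_HZ = (0.03, 0.07, 0.13)
FAST_FREQS_HZ = (0.10, 0.20, 0.40)
#: Center (start) angle of the tracking trajectories (deg flexion).
TRAJECTORY_CENTER_DEG = 15.0
#: Tracking trial duration (s).
TRAJECTORY_DURATION_S = 30.0

#: Position-matching target angles: integer degrees of flexion, 10..30.
MATCHING_ANGLES_DEG = tuple(range(10, 31))

#: Fast-reaching protocol: (start, target) in deg, and the response window.
REACHING_ENDPOINTS_DEG = {
    "flexion": (-10.0, 30.0),
    "extension": (30.0, -10.0),
}
REACHING_WINDOW_S = 4.0


# ---------------------------------------------------------------------------
# Stimulus types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Multi-sine target trajectory for the trajectory-following task.

    The displayed trajectory is a sum of three sine components around a fixed
    center angle. ``component_amp_deg`` holds the amplitude of each component;
    the default presets split the protocol's total 15 deg amplitude equally
    across the three components (5 deg each) so the summed excursion stays
    within the device workspace. ``strict_amplitude=True`` in
    :func:`trajectory_preset` gives the literal 15 deg-per-component reading
    instead (the summed stimulus is then saturated downstream).
    """

    component_freqs_hz: tuple[float, ...]
    component_amp_deg: tuple[float, ...]
    center_deg: float = TRAJECTORY_CENTER_DEG
    duration_s: float = TRAJECTORY_DURATION_S
    label: str = "slow"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("trajectory duration must be positive")
        if len(self.component_freqs_hz) != len(self.component_amp_deg):
            raise ValueError("one amplitude per frequency component required")
        if any(f <= 0 for f in self.component_freqs_hz):
            raise ValueError("component frequencies must be positive")


def trajectory_preset(label: str, strict_amplitude: bool = False) -> TrajectorySpec:
    """Return the slow or fast tracking-trajectory preset.

    Parameters
    ----------
    label : {"slow", "fast"}
    strict_amplitude : bool
        If True, each sine component carries the full 15 deg amplitude
        (literal protocol reading, peak excursion up to 45 deg around the
        center); if False (default), the 15 deg is split equally across the
        three components, keeping the stimulus inside the workspace.
    """
    if label == "slow":
        freqs = SLOW_FREQS_HZ
    elif label == "fast":
        freqs = FAST_FREQS_HZ
    else:
        raise ValueError(f"unknown trajectory label: {label!r}")
    amp = 15.0 if strict_amplitude else 15.0 / 3.0
    return TrajectorySpec(
        component_freqs_hz=freqs,
        component_amp_deg=(amp,) * len(freqs),
        label=label,
    )


@dataclass(frozen=True)
class AngleSequence:
    """Presented-angle order of one position-matching assessment.

    Exactly 21 angles, the integers 10..30 deg flexion, each presented once in
    a seeded random order.
    """

    angles_deg: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if sorted(self.angles_deg) != list(MATCHING_ANGLES_DEG):
            raise ValueError(
                "angle sequence must be a permutation of the integers 10..30"
            )


@dataclass(frozen=True)
class ReachingStimulus:
    """Start/target pair of one fast-reaching direction, with response window."""

    direction: str
    start_deg: float
    target_deg: float
    window_s: float = REACHING_WINDOW_S


@dataclass
class TrialTrace:
    """Uniformly sampled kinematic/kinetic signals of one trial.

    All present channels share the same length and sampling rate. ``force_n``
    is only recorded in the maximum-force task and is ``None`` elsewhere.
    """

    fs_hz: float = DEVICE_FS_HZ
    position_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    velocity_degps: np.ndarray | None = None
    force_n: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.position_deg)
        for name in ("velocity_degps", "force_n"):
            chan = getattr(self, name)
            if chan is not None and len(chan) != n:
                raise ValueError(f"{name} length differs from position channel")

    @property
    def time_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.position_deg)) / self.fs_hz


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------

def generate_target_trajectory(
    spec: TrajectorySpec, fs_hz: float = DEVICE_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the multi-sine target trajectory of one tracking trial.

    Returns ``(t, y)`` with ``y(t) = center + sum_i amp_i * sin(2*pi*f_i*t)``
    sampled at ``fs_hz`` over ``[0, duration_s]`` (endpoint included).
    Deterministic: the stimulus carries no randomness.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(spec.duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    y = np.full(n, float(spec.center_deg))
    for f, a in zip(spec.component_freqs_hz, spec.component_amp_deg):
        y += a * np.sin(2.0 * np.pi * f * t)
    return t, y


def generate_angle_sequence(seed: int) -> AngleSequence:
    """Seeded random order of the 21 position-matching target angles."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(MATCHING_ANGLES_DEG))
    return AngleSequence(angles_deg=tuple(int(a) for a in order), seed=int(seed))


def reaching_stimulus(direction: str) -> ReachingStimulus:
    """Fixed start/target pair of the fast target-reaching task.

    Flexion trials start at -10 deg and target +30 deg; extension trials start
    at +30 deg and target -10 deg; 4 s are given to respond.
    """
    try:
        start, target = REACHING_ENDPOINTS_DEG[direction]
    except KeyError:
        raise ValueError(
            f"unknown reaching direction {direction!r}; "
            "expected 'flexion' or 'extension'"
        ) from None
    return ReachingStimulus(direction=direction, start_deg=start, target_deg=target)


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------

def lowpass(
    x: np.ndarray,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    fs_hz: float = DEVICE_FS_HZ,
    zero_phase: bool = False,
) -> np.ndarray:
    """First-order Butterworth low-pass, as applied on-device to velocity/force.

    The filter realizes the exact first-order Butterworth transfer function
    H(jf) = 1 / (1 + j f/fc): unit DC gain, -3 dB at the cutoff and the
    analytic 1/sqrt(1 + (f/fc)^2) magnitude roll-off at every frequency (a
    bilinear-transform IIR would warp the response near the Nyquist rate).
    It is applied spectrally with zero padding covering several filter time
    constants, keeping the causal phase lag of the analog prototype;
    ``zero_phase=True`` applies the squared magnitude with zero phase
    instead (forward-backward equivalent, for offline analysis).
    """
    x = np.asarray(x, dtype=float)
    if fs_hz <= 0 or cutoff_hz <= 0:
        raise ValueError("sampling rate and cutoff must be positive")
    if cutoff_hz >= fs_hz / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    n = x.size
    if n == 0:
        return x.copy()
    # edge-value padding over ~20 filter time constants: removes block-edge
    # discontinuities and makes the periodic wraparound negligible
    pad = int(np.ceil(20.0 * fs_hz / (2.0 * np.pi * cutoff_hz))) + 1
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    freqs = np.fft.rfftfreq(xp.size, d=1.0 / fs_hz)
    h = 1.0 / (1.0 + 1j * freqs / cutoff_hz)
    if zero_phase:
        h = np.abs(h) ** 2
    y = np.fft.irfft(np.fft.rfft(xp) * h, n=xp.size)
    return y[pad:pad + n]


def saturate_position(position_deg: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip a position signal to the device workspace.

    Returns the clipped signal and the number of saturated samples; saturation
    events are logged because they distort reaching/tracking metrics near the
    mechanical stops.
    """
    position_deg = np.asarray(position_deg, dtype=float)
    lo, hi = WORKSPACE_DEG
    clipped = np.clip(position_deg, lo, hi)
    n_clipped = int(np.count_nonzero(clipped != position_deg))
    if n_clipped:
        logger.debug("workspace saturation: %d samples clipped", n_clipped)
    return clipped, n_clipped
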
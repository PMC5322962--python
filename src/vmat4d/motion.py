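"""Rigid breathing trajectories.

A trajectory is the uniformly sampled 3D displacement (mm, axes SI/AP/LR) of
the moving phantom relative to its mid-respiration reference position, with
t = 0 at 'beam on'.  Generated scenarios start at the mid-respiration zero
displacement and use a sine (not cosine) phase convention so that t = 0 is
the mid-respiration state; positive SI is the inhale direction.

Scenario registry: five sinusoids (varying period and motion axes) and two
cycle-jittered "patient-like" scenarios whose per-cycle peak-to-peak
amplitude and period statistics follow stated means +/- SDs — one regular,
one irregular.  The irregular model draws amplitude and period per breathing
cycle (matching how such statistics are reported) rather than using an
autoregressive process.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_DT = 0.04  # s, trajectory sampling resolution
MIN_PERIOD = 0.5   # s, physical lower bound for drawn cycle lengths


@dataclass(frozen=True)
class ScenarioSpec:
    """Breathing scenario parameters.

    ``amplitude`` entries are peak-to-peak (mm) per axis (SI, AP, LR);
    ``amplitude_sd`` and ``period_sd`` add per-cycle Gaussian jitter for
    ``kind='irregular'``.  ``max_amplitude`` truncates drawn amplitudes.
    """

    kind: str                                   # sine | irregular
    amplitude: tuple[float, float, float]       # peak-to-peak mm (SI, AP, LR)
    period: float                               # mean cycle length s
    amplitude_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    period_sd: float = 0.0
    max_amplitude: tuple[float, float, float] | None = None
    seed: int | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("sine", "irregular"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if any(a < 0 for a in self.amplitude):
            raise ValueError("amplitudes must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")


#: Motion scenario registry: peak-to-peak amplitudes (SI, AP, LR) in mm and
#: breathing period in s.  Cases 2a/2b are synthetic cycle-jittered analogues
#: of regular/irregular patient tumor trajectories (per-cycle mean +/- SD
#: amplitude and period); their AP component is assumed in phase with SI.
SCENARIOS: dict[str, ScenarioSpec] = {
    "static": ScenarioSpec("sine", (0.0, 0.0, 0.0), 4.5, label="static"),
    "1a": ScenarioSpec("sine", (20.0, 10.0, 0.0), 3.1, label="1a"),
    "1b": ScenarioSpec("sine", (20.0, 10.0, 0.0), 4.5, label="1b"),
    "1c": ScenarioSpec("sine", (20.0, 10.0, 0.0), 5.8, label="1c"),
    "1d": ScenarioSpec("sine", (20.0, 0.0, 0.0), 4.5, label="1d"),
    "1e": ScenarioSpec("sine", (20.0, 10.0, 10.0), 4.5, label="1e"),
    "2a": ScenarioSpec("irregular", (12.8, 9.4, 0.0), 4.8,
                       amplitude_sd=(3.3, 3.3, 0.0), period_sd=0.8,
                       max_amplitude=(16.3, 11.8, 0.0), seed=20, label="2a"),
    "2b": ScenarioSpec("irregular", (13.0, 13.6, 0.0), 4.4,
                       amplitude_sd=(5.2, 5.5, 0.0), period_sd=1.0,
                       max_amplitude=(22.5, 23.9, 0.0), seed=21, label="2b"),
}


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled rigid displacement vs. time.

    ``samples[k]`` is the (SI, AP, LR) displacement (mm) at ``t = k * dt``.
    """

    dt: float
    samples: np.ndarray          # shape (n, 3), mm
    label: str = ""

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
            raise ValueError("samples must be an (n>=2, 3) array")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def displacement(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated displacement at time(s) t, shape (..., 3)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.duration + 1e-9):
            raise ValueError(
                f"time outside trajectory [0, {self.duration:.2f}] s requested"
            )
        tt = self.times
        return np.stack(
            [np.interp(t, tt, self.samples[:, k]) for k in range(3)], axis=-1
        )


def make_sinusoid(spec: ScenarioSpec, duration: float, dt: float = DEFAULT_DT
                  ) -> Trajectory:
    """Sinusoidal trajectory: d_k(t) = (A_k / 2) sin(2 pi t / T).

    Peak-to-peak excursion per axis equals the spec amplitude; displacement
    is zero (mid-respiration) at t = 0.
    """
    if spec.kind != "sine":
        raise ValueError("make_sinusoid requires a spec of kind 'sine'")
    if duration < spec.period:
        warnings.warn(
            f"duration {duration} s is shorter than one breathing period "
            f"{spec.period} s; phase-sweep experiments need full cycles",
            stacklevel=2,
        )
    t = np.arange(int(np.floor(duration / dt)) + 1) * dt
    amp = np.asarray(spec.amplitude, dtype=float) / 2.0
    samples = amp[None, :] * np.sin(2.0 * np.pi * t / spec.period)[:, None]
    return Trajectory(dt=dt, samples=samples, label=spec.label or "sine")


def make_irregular(spec: ScenarioSpec, duration: float, dt: float = DEFAULT_DT
                   ) -> Trajectory:
    """Cycle-jittered breathing: concatenated sine cycles with per-cycle
    period ~ N(T, sd_T) and per-cycle peak-to-peak amplitude ~ N(A_k, sd_Ak),
    truncated at physical bounds.  Reproducible under a fixed seed."""
    if spec.kind != "irregular":
        raise ValueError("make_irregular requires a spec of kind 'irregular'")
    if spec.seed is None:
        raise ValueError("irregular scenarios require a seed")
    rng = np.random.default_rng(spec.seed)
    amp_mean = np.asarray(spec.amplitude, dtype=float)
    amp_sd = np.asarray(spec.amplitude_sd, dtype=float)
    amp_max = (np.asarray(spec.max_amplitude, dtype=float)
               if spec.max_amplitude is not None else np.inf * np.ones(3))

    t = np.arange(int(np.floor(duration / dt)) + 1) * dt
    samples = np.zeros((len(t), 3))
    t0 = 0.0
    truncated = 0
    while t0 <= duration:
        period = float(rng.normal(spec.period, spec.period_sd))
        if period < MIN_PERIOD:
            period = MIN_PERIOD
            truncated += 1
        amps = rng.normal(amp_mean, amp_sd)
        amps = np.clip(amps, 0.0, amp_max)
        in_cycle = (t >= t0 - 1e-12) & (t < t0 + period - 1e-12)
        phase = 2.0 * np.pi * (t[in_cycle] - t0) / period
        samples[in_cycle] = (amps / 2.0)[None, :] * np.sin(phase)[:, None]
        t0 += period
    if truncated:
        log.warning("%d drawn cycle lengths fell below %.1f s and were truncated",
                    truncated, MIN_PERIOD)
    return Trajectory(dt=dt, samples=samples, label=spec.label or "irregular")


def make_trajectory(spec: ScenarioSpec, duration: float, dt: float = DEFAULT_DT
                    ) -> Trajectory:
    """Dispatch on the scenario kind."""
    if spec.kind == "sine":
        return make_sinusoid(spec, duration, dt)
    return make_irregular(spec, duration, dt)


def shift_start_phase(traj: Trajectory, delta_t: float) -> Trajectory:
    """Trajectory whose time t equals the original at t + delta_t.

    The shifted window must remain covered by the original samples, so
    trajectories meant for phase sweeps should be generated with margin.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    if delta_t == 0.0:
        return traj
    n_shift = delta_t / traj.dt
    if delta_t > traj.duration - traj.dt:
        raise ValueError(
            f"phase offset {delta_t} s exceeds trajectory coverage "
            f"({traj.duration} s)"
        )
    new_times = np.arange(len(traj.samples)) * traj.dt + delta_t
    keep = new_times <= traj.duration + 1e-9
    samples = traj.displacement(new_times[keep])
    return Trajectory(dt=traj.dt, samples=samples, label=traj.label)


# ---------------------------------------------------------------------------
# CSV exchange: columns t, SI, AP, LR in s / mm.
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    data = np.column_stack([traj.times, traj.samples])
    header = f"t,SI,AP,LR  # s, mm; label={traj.label}"
    np.savetxt(path, data, delimiter=",", header=header, fmt="%.6f")


def read_trajectory(path: str | Path, label: str = "") -> Trajectory:
    """Read a trajectory CSV.  A non-uniform time column is resampled to the
    median step by linear interpolation with a warning."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"unreadable trajectory file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty trajectory file: {path}")
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns t,SI,AP,LR, got {data.shape[1]}")
    t = data[:, 0]
    steps = np.diff(t)
    if len(steps) == 0:
        raise ValueError(f"{path}: trajectory needs at least 2 samples")
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=0, atol=1e-6):
        warnings.warn(
            f"{path}: non-uniform time column; resampled to dt={dt:.4f} s",
            stacklevel=2,
        )
        tt = np.arange(int(np.floor((t[-1] - t[0]) / dt)) + 1) * dt + t[0]
        data = np.column_stack(
            [tt] + [np.interp(tt, t, data[:, k]) for k in range(1, 4)]
        )
    if not label:
        with path.open() as fh:
            first = fh.readline()
        if "label=" in first:
            label = first.split("label=")[1].strip()
    return Trajectory(dt=dt, samples=data[:, 1:4], label=label)


def itv_half_extents(spec: ScenarioSpec, ctv_size_mm: float = 20.0) -> np.ndarray:
    """Half extents (mm, SI/AP/LR) of the ITV: the CTV expanded by half the
    (maximum) peak-to-peak motion amplitude per axis."""
    amp = np.asarray(spec.max_amplitude if spec.max_amplitude is not None
                     else spec.amplitude, dtype=float)
    return ctv_size_mm / 2.0 + amp / 2.0
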
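"""Virtual voltage-clamp protocols and peak-current measurement.

Six double- or multi-pulse protocols characterize a sodium channel:

``activation``
    2 ms at -120 mV, then a 14 ms test step swept from -90 to +60 mV in
    5 mV increments (31 sweeps).  Peak test currents give the
    conductance-voltage curve.
``deactivation``
    0.5 ms at -120 mV, 0.5 ms at -10 mV to open channels, then a 5 ms
    repolarization swept from -100 to -30 mV in 10 mV steps; the decaying
    tail currents give the deactivation time constants.
``availability``
    500 ms conditioning swept from -120 to 0 mV in 5 mV steps, then a
    20 ms test pulse at -10 mV (steady-state availability / fast
    inactivation curve).
``fast_repriming``
    30 ms conditioning pulse (P1) at -20 mV, a recovery interval at
    -120 mV (default; exposed as an override for -110/-100/-90 mV
    variants) of duration swept logarithmically 0.1-1000 ms, then a 20 ms
    probe (P2) at -20 mV.  P2/P1 peak ratios trace recovery from fast
    inactivation.
``slow_repriming``
    As fast repriming with a 1000 ms P1 and intervals up to 7000 ms.
``slow_onset``
    P1 at -20 mV of duration swept logarithmically 10 ms-10 s, 30 ms
    repolarization at -120 mV, then a 20 ms test pulse at -20 mV
    (development of slow inactivation).

Execution is an ideal voltage clamp: the command potential is imposed
exactly, so no capacitive transient exists (equivalently, capacitive
currents are already subtracted) and no leak is added.  Each sweep starts
from the equilibrium state at the holding potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import (
    ChannelSpec,
    ChannelState,
    current_trace,
    propagate_epoch,
    steady_state,
)

__all__ = [
    "Epoch",
    "ProtocolSpec",
    "EpochTrace",
    "Sweep",
    "SweepSet",
    "ProtocolError",
    "PROTOCOL_NAMES",
    "make_protocol",
    "run_protocol",
    "peak_current",
    "log_grid",
]

#: Sentinel marking the swept quantity inside an epoch definition.
SWEEP = "sweep"

PROTOCOL_NAMES = (
    "activation",
    "deactivation",
    "availability",
    "fast_repriming",
    "slow_repriming",
    "slow_onset",
)


class ProtocolError(ValueError):
    """Raised for malformed protocol specifications."""


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant voltage epoch; ``None`` marks the swept field."""

    V: float | None
    duration: float | None


@dataclass(frozen=True)
class ProtocolSpec:
    """A sweep family of voltage epochs with exactly one swept variable.

    ``measure`` names the epochs whose currents are analysed downstream
    (``{"test": i}`` or ``{"p1": i, "p2": j}``).
    """

    name: str
    holding_V: float
    epochs: tuple[Epoch, ...]
    sweep_epoch: int
    sweep_variable: str  # "level" | "duration"
    sweep_values: tuple[float, ...]
    measure: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sweep_variable not in ("level", "duration"):
            raise ProtocolError("sweep_variable must be 'level' or 'duration'")
        if not (0 <= self.sweep_epoch < len(self.epochs)):
            raise ProtocolError("sweep_epoch out of range")
        vals = np.asarray(self.sweep_values, float)
        if vals.size < 2 or not np.all(np.isfinite(vals)):
            raise ProtocolError("sweep values must be finite, length >= 2")
        if not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
            raise ProtocolError("sweep values must be strictly monotone")
        if self.sweep_variable == "duration" and np.any(vals <= 0):
            raise ProtocolError("swept durations must be positive")
        for i, ep in enumerate(self.epochs):
            if i == self.sweep_epoch:
                want_none = "V" if self.sweep_variable == "level" else "duration"
                if getattr(ep, want_none) is not None:
                    raise ProtocolError(
                        f"epoch {i} is swept; its {want_none} must be None"
                    )
            if ep.duration is not None and ep.duration <= 0:
                raise ProtocolError(f"epoch {i}: duration must be positive")

    def resolve(self, value: float) -> list[tuple[float, float]]:
        """Concrete ``(V, duration)`` list for one sweep value."""
        out = []
        for i, ep in enumerate(self.epochs):
            V, dur = ep.V, ep.duration
            if i == self.sweep_epoch:
                if self.sweep_variable == "level":
                    V = value
                else:
                    dur = value
            out.append((float(V), float(dur)))
        return out

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_values)


def log_grid(lo: float, hi: float, per_decade: int = 8) -> tuple[float, ...]:
    """Logarithmically spaced grid, ``per_decade`` points per decade,
    endpoints included."""
    decades = math.log10(hi / lo)
    n = int(round(decades * per_decade)) + 1
    return tuple(np.logspace(math.log10(lo), math.log10(hi), n))


def _level_grid(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(lo + step * np.arange(n))


def make_protocol(name: str, **overrides) -> ProtocolSpec:
    """Build one of the six preset protocols, optionally overridden.

    Recognized overrides: ``sweep_values``, ``holding_V``, and for the
    repriming protocols ``recovery_V`` (the repolarization level sampled
    at -120/-110/-100/-90 mV in the reference data) and ``p1_duration``.
    """
    if name not in PROTOCOL_NAMES:
        raise ProtocolError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
    hold = float(overrides.pop("holding_V", -120.0))
    recovery_V = float(overrides.pop("recovery_V", -120.0))
    p1 = overrides.pop("p1_duration", None)
    if p1 is not None and name not in ("fast_repriming", "slow_repriming"):
        raise ProtocolError("p1_duration override only applies to repriming")

    if name == "activation":
        spec = ProtocolSpec(
            name, hold,
            epochs=(Epoch(-120.0, 2.0), Epoch(None, 14.0)),
            sweep_epoch=1, sweep_variable="level",
            sweep_values=_level_grid(-90.0, 60.0, 5.0),
            measure={"test": 1},
        )
    elif name == "deactivation":
        spec = ProtocolSpec(
            name, hold,
            epochs=(Epoch(-120.0, 0.5), Epoch(-10.0, 0.5), Epoch(None, 5.0)),
            sweep_epoch=2, sweep_variable="level",
            sweep_values=_level_grid(-100.0, -30.0, 10.0),
            measure={"tail": 2},
        )
    elif name == "availability":
        spec = ProtocolSpec(
            name, hold,
            epochs=(Epoch(None, 500.0), Epoch(-10.0, 20.0)),
            sweep_epoch=0, sweep_variable="level",
            sweep_values=_level_grid(-120.0, 0.0, 5.0),
            measure={"test": 1},
        )
    elif name == "fast_repriming":
        spec = ProtocolSpec(
            name, hold,
            epochs=(
                Epoch(-20.0, 30.0 if p1 is None else float(p1)),
                Epoch(recovery_V, None),
                Epoch(-20.0, 20.0),
            ),
            sweep_epoch=1, sweep_variable="duration",
            sweep_values=log_grid(0.1, 1000.0),
            measure={"p1": 0, "p2": 2},
        )
    elif name == "slow_repriming":
        spec = ProtocolSpec(
            name, hold,
            epochs=(
                Epoch(-20.0, 1000.0 if p1 is None else float(p1)),
                Epoch(recovery_V, None),
                Epoch(-20.0, 20.0),
            ),
            sweep_epoch=1, sweep_variable="duration",
            sweep_values=log_grid(0.1, 7000.0),
            measure={"p1": 0, "p2": 2},
        )
    else:  # slow_onset
        spec = ProtocolSpec(
            name, hold,
            epochs=(Epoch(-20.0, None), Epoch(-120.0, 30.0), Epoch(-20.0, 20.0)),
            sweep_epoch=0, sweep_variable="duration",
            sweep_values=log_grid(10.0, 10000.0),
            measure={"p1": 0, "p2": 2},
        )

    if "sweep_values" in overrides:
        spec = replace(spec, sweep_values=tuple(overrides.pop("sweep_values")))
    if overrides:
        raise ProtocolError(f"unknown overrides: {sorted(overrides)}")
    return spec


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

@dataclass
class EpochTrace:
    """Sampled trajectory of one epoch of one sweep."""

    V: float
    t: np.ndarray        # absolute time, ms
    states: np.ndarray   # (n_samples, n_states)
    I: np.ndarray        # mA/cm2


@dataclass
class Sweep:
    value: float
    epochs: list[EpochTrace]

    @property
    def t(self) -> np.ndarray:
        return np.concatenate([e.t for e in self.epochs])

    @property
    def I(self) -> np.ndarray:
        return np.concatenate([e.I for e in self.epochs])

    @property
    def V(self) -> np.ndarray:
        return np.concatenate([np.full(e.t.shape, e.V) for e in self.epochs])


@dataclass
class SweepSet:
    """All simulated sweeps of one protocol for one channel."""

    protocol: ProtocolSpec
    channel: ChannelSpec
    dt: float
    sweeps: list[Sweep]

    @property
    def sweep_values(self) -> np.ndarray:
        return np.array([s.value for s in self.sweeps])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (sweep_id, epoch, t_ms, V_mV, I_mA_cm2, states)."""
        labels = self.channel.state_labels
        parts = []
        for si, sw in enumerate(self.sweeps):
            for ei, ep in enumerate(sw.epochs):
                df = pd.DataFrame({
                    "sweep_id": si,
                    "sweep_value": sw.value,
                    "epoch": ei,
                    "t_ms": ep.t,
                    "V_mV": ep.V,
                    "I_mA_cm2": ep.I,
                })
                for j, lab in enumerate(labels):
                    df[lab] = ep.states[:, j]
                parts.append(df)
        return pd.concat(parts, ignore_index=True)


def _epoch_times(duration: float, dt: float, fine_window: float = 50.0,
                 coarse_samples: int = 400) -> np.ndarray:
    """Sampling instants for one epoch (relative, including 0 and end).

    Epochs up to ``fine_window`` ms are sampled uniformly at ``dt``; longer
    epochs keep the fine grid over the initial window (where peaks live)
    and continue with ``coarse_samples`` uniform points.  Propagation is
    closed form, so sampling density only affects the recorded trace,
    never the solution.
    """
    if duration <= fine_window:
        n = int(np.ceil(duration / dt - 1e-9))
        grid = np.minimum(np.arange(n + 1) * dt, duration)
        if grid[-1] < duration:
            grid = np.append(grid, duration)
        return grid
    fine = np.arange(int(fine_window / dt)) * dt
    coarse = np.linspace(fine_window, duration, coarse_samples + 1)
    return np.concatenate([fine, coarse])


def run_protocol(
    channel: ChannelSpec, protocol: ProtocolSpec, dt: float = 0.025
) -> SweepSet:
    """Simulate every sweep of ``protocol`` under ideal voltage clamp.

    Each sweep starts from ``steady_state(holding_V)``; epochs are
    propagated exactly and concatenated, and the Ohmic current density is
    recorded at every sample.
    """
    hold = steady_state(channel, protocol.holding_V)
    sweeps = []
    for value in protocol.sweep_values:
        state = hold
        t0 = 0.0
        epochs = []
        for V, dur in protocol.resolve(value):
            times = _epoch_times(dur, dt)
            _, states = propagate_epoch(channel, state, V, dur, times=times)
            I = current_trace(channel, states, V)
            epochs.append(EpochTrace(V=V, t=t0 + times, states=states, I=I))
            state = ChannelState(states[-1], channel.state_labels)
            t0 += dur
        sweeps.append(Sweep(value=float(value), epochs=epochs))
    return SweepSet(protocol=protocol, channel=channel, dt=dt, sweeps=sweeps)


def peak_current(
    sweep: Sweep, epoch_index: int
) -> tuple[float, float, bool]:
    """Extremum of largest magnitude within an epoch.

    Returns ``(I_peak, t_peak, flagged)`` with ``I_peak`` signed (inward
    currents negative), ``t_peak`` in ms relative to epoch start, and
    ``flagged=True`` for an all-zero trace (in which case (0, 0) is
    returned).  The first sample after the voltage step is excluded as a
    discontinuity guard.
    """
    ep = sweep.epochs[epoch_index]
    if len(ep.I) < 2:
        raise ProtocolError("epoch too short to measure a peak")
    I = ep.I[1:]
    t = ep.t[1:] - ep.t[0]
    if np.all(I == 0.0):
        return 0.0, 0.0, True
    k = int(np.argmax(np.abs(I)))
    return float(I[k]), float(t[k]), False
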
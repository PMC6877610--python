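"""Single-compartment current-clamp membrane model.

A minimal conductance-based compartment demonstrating that either sodium
channel family supports action potentials when paired with a leak and a
generic delayed-rectifier potassium conductance:

    Cm dV/dt = -g_L (V - E_L) - g_Na(V) (V - E_Na) - g_K(V) (V - E_K) + I_stim

The potassium conductance is the classic n^4 delayed rectifier (squid
parameters) -- a generic repolarizing mechanism, since the focus here is
the sodium channel.  Spiking in this compartment is a qualitative check
of model suitability, not a quantitative target: the geometry is a single
isopotential cylinder (area 10,000 um^2, Cm 1 uF/cm^2), not a detailed
multicompartment neuron.

Integration uses operator splitting with exponential updates on both
sides: channel states advance one exact constant-voltage step per dt,
then V advances by the exact solution of the resulting linear membrane
equation at frozen conductances.  Halving dt from 0.025 ms leaves spike
times within 0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ChannelSpec,
    ChannelState,
    HHChannelSpec,
    HHGate,
    _open_fraction,
    propagate_to,
    steady_state,
)
from .ratelaws import RateLaw, TemperatureSpec

__all__ = [
    "MembraneSpec",
    "MembraneError",
    "default_k_gate",
    "simulate_current_clamp",
    "count_spikes",
]


class MembraneError(RuntimeError):
    """Raised on numerical blow-up of the membrane integration."""


def default_k_gate(T: float = 24.0) -> HHChannelSpec:
    """Generic n^4 delayed-rectifier potassium conductance (squid rates)."""
    alpha_n = RateLaw("linoid", {"A": 0.01, "V_half": -55.0, "k": 10.0})
    beta_n = RateLaw("exponential", {"A": 0.125, "V_half": -65.0, "k": -80.0})
    return HHChannelSpec(
        gates=(HHGate("n", 4, alpha_n, beta_n),),
        gbar=0.036,
        E_rev=-77.0,
        temperature=TemperatureSpec(T=T, T_base=6.3, q10_base=3.0),
        name="k_dr",
    )


@dataclass
class MembraneSpec:
    """Isopotential compartment: capacitance, leak, Na and K conductances.

    ``area`` in um^2 converts injected current (nA) to density (mA/cm^2).
    The default resting potential of -100 mV suits the hyperpolarized
    availability range of NaV1.5.
    """

    sodium: ChannelSpec
    Cm: float = 1.0                 # uF/cm2
    area: float = 10_000.0          # um2
    g_L: float = 0.0003             # S/cm2
    E_L: float = -100.0             # mV
    potassium: HHChannelSpec | None = field(default_factory=default_k_gate)
    V0: float = -100.0              # mV

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.area <= 0:
            raise ValueError("Cm and area must be positive")


def simulate_current_clamp(
    membrane: MembraneSpec,
    stimulus: list[tuple[float, float]],
    duration: float,
    dt: float = 0.025,
) -> dict[str, np.ndarray]:
    """Integrate the membrane equation under a piecewise-constant stimulus.

    ``stimulus`` is a list of ``(t_start_ms, amplitude_nA)`` pairs: the
    amplitude holds from each start time until the next (0 nA before the
    first).  Returns arrays ``t`` (ms), ``V`` (mV), ``I_stim`` (nA) plus
    the channel open fractions.  Aborts with :class:`MembraneError` if
    |V| exceeds 500 mV.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    area_cm2 = membrane.area * 1e-8  # um2 -> cm2
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    stim = np.zeros(n + 1)
    for t0, amp in sorted(stimulus):
        stim[t >= t0 - 1e-12] = amp
    # nA -> mA/cm2 : 1 nA = 1e-6 mA
    stim_density = stim * 1e-6 / area_cm2

    V = np.empty(n + 1)
    V[0] = membrane.V0
    na_state = steady_state(membrane.sodium, membrane.V0)
    k_state = (
        steady_state(membrane.potassium, membrane.V0)
        if membrane.potassium is not None else None
    )
    p_na = np.empty(n + 1)
    p_k = np.empty(n + 1)
    p_na[0] = _open_fraction(membrane.sodium, na_state.values)[0]
    p_k[0] = (
        _open_fraction(membrane.potassium, k_state.values)[0]
        if k_state is not None else 0.0
    )

    for i in range(n):
        v = V[i]
        # channel states: exact step at frozen voltage
        na_state = propagate_to(membrane.sodium, na_state, v, dt)
        if k_state is not None:
            k_state = propagate_to(membrane.potassium, k_state, v, dt)
        g_na = membrane.sodium.gbar * _open_fraction(
            membrane.sodium, na_state.values)[0]
        g_k = (
            membrane.potassium.gbar * _open_fraction(
                membrane.potassium, k_state.values)[0]
            if k_state is not None else 0.0
        )
        # membrane: exact update at frozen conductances
        # Cm dV/dt = -g_tot (V - E_eff) + I ;  rates in ms^-1 need the
        # 1e3 factor (S/cm2 * mV = mA/cm2, Cm in uF/cm2)
        g_tot = membrane.g_L + g_na + g_k
        E_eff = (
            membrane.g_L * membrane.E_L
            + g_na * membrane.sodium.E_rev
            + g_k * (membrane.potassium.E_rev if k_state is not None else 0.0)
            + stim_density[i + 1]
        ) / g_tot
        rate = 1e3 * g_tot / membrane.Cm  # ms^-1
        V[i + 1] = E_eff + (v - E_eff) * np.exp(-rate * dt)
        if not np.isfinite(V[i + 1]) or abs(V[i + 1]) > 500.0:
            raise MembraneError(
                f"membrane potential blew up at t={t[i+1]:.3f} ms "
                f"(V={V[i+1]:.1f} mV)"
            )
        p_na[i + 1] = _open_fraction(membrane.sodium, na_state.values)[0]
        p_k[i + 1] = p_k[0] if k_state is None else _open_fraction(
            membrane.potassium, k_state.values)[0]

    return {"t": t, "V": V, "I_stim": stim, "p_open_na": p_na, "p_open_k": p_k}


def count_spikes(
    trace: dict[str, np.ndarray] | np.ndarray,
    threshold: float = -20.0,
    refractory: float = 1.0,
    dt: float | None = None,
) -> int:
    """Count upward threshold crossings separated by a refractory guard.

    Accepts the dict returned by :func:`simulate_current_clamp` (using its
    time base) or a bare voltage array with ``dt`` given.
    """
    if isinstance(trace, dict):
        V = np.asarray(trace["V"])
        t = np.asarray(trace["t"])
    else:
        V = np.asarray(trace)
        if V.size == 0:
            raise ValueError("empty voltage trace")
        if dt is None:
            raise ValueError("dt required for a bare voltage array")
        t = np.arange(V.size) * dt
    if V.size == 0:
        raise ValueError("empty voltage trace")
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    count = 0
    last = -np.inf
    for k in crossings:
        if t[k] - last >= refractory:
            count += 1
            last = t[k]
    return count
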
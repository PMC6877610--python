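"""Voltage-dependent transition-rate laws and temperature (Q10) scaling.

Both channel families (Hodgkin-Huxley gate models and Markov kinetic
schemes) are driven by voltage-dependent rate "constants".  This module
provides the small algebra of functional forms those rates take:

``exponential``
    ``A * exp((V - V1/2) / k)`` -- the classic HH barrier-crossing form.
``linoid``
    ``A * (V - V1/2) / (1 - exp(-(V - V1/2) / k))`` -- linear-exponential
    form with a removable singularity at ``V = V1/2`` where it evaluates to
    ``A * k``.  With positive ``k`` this is positive and increasing in V,
    matching the conventional alpha_m of the squid axon sodium channel.
``sigmoid``
    ``A / (1 + exp((V - V1/2) / k))``.
``double_sigmoid``
    Sum of two opposed sigmoids, one rising toward hyperpolarized
    voltages (positive slope factor ``k_hyp``) and one toward depolarized
    voltages (negative ``k_dep``); either branch may be absent.  This is
    the form used for every transition of the NaV1.5 Markov scheme.
``offset_sigmoid``
    Sigmoid with a non-zero minimum asymptote,
    ``tau_min + tau_max / (1 + exp((V - V1/2) / k))`` (thermodynamic-style
    parameterization; supported but not used by the bundled presets).
``constant``
    Voltage-independent rate ``A``.

All voltages are in mV and all rates in ms^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "RateLaw",
    "TemperatureSpec",
    "RateLawError",
    "eval_rate_law",
    "q10_factor",
    "gate_infty_tau",
]

#: Required parameter names per functional form.
_FORM_PARAMS: dict[str, tuple[str, ...]] = {
    "exponential": ("A", "V_half", "k"),
    "linoid": ("A", "V_half", "k"),
    "sigmoid": ("A", "V_half", "k"),
    "double_sigmoid": (),  # at least one branch, validated separately
    "offset_sigmoid": ("tau_min", "tau_max", "V_half", "k"),
    "constant": ("A",),
}

_HYP_BRANCH = ("B_hyp", "V_hyp", "k_hyp")
_DEP_BRANCH = ("B_dep", "V_dep", "k_dep")


class RateLawError(ValueError):
    """Raised for malformed rate-law parameter sets."""


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent rate function.

    Parameters
    ----------
    form:
        One of ``exponential``, ``linoid``, ``sigmoid``, ``double_sigmoid``,
        ``offset_sigmoid``, ``constant``.
    params:
        Named real parameters for the chosen form (see module docstring).
        Voltages in mV, amplitudes in ms^-1 (ms^-1 mV^-1 for the linoid).
    """

    form: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in _FORM_PARAMS:
            raise RateLawError(f"unknown rate-law form {self.form!r}")
        object.__setattr__(self, "params", dict(self.params))
        if self.form == "double_sigmoid":
            has_hyp = all(p in self.params for p in _HYP_BRANCH)
            has_dep = all(p in self.params for p in _DEP_BRANCH)
            if not (has_hyp or has_dep):
                raise RateLawError(
                    "double_sigmoid requires the hyperpolarized branch "
                    "(B_hyp, V_hyp, k_hyp), the depolarized branch "
                    "(B_dep, V_dep, k_dep), or both"
                )
            for name in ("k_hyp", "k_dep"):
                if self.params.get(name) == 0:
                    raise RateLawError(f"{name} must be non-zero")
        else:
            missing = [p for p in _FORM_PARAMS[self.form] if p not in self.params]
            if missing:
                raise RateLawError(
                    f"{self.form} rate law missing parameters: {missing}"
                )
            if "k" in _FORM_PARAMS[self.form] and self.params["k"] == 0:
                raise RateLawError("slope factor k must be non-zero")

    def __call__(self, V: float) -> float:
        return eval_rate_law(self, V)

    def to_dict(self) -> dict:
        """Serializable ``{"form": ..., "params": {...}}`` representation."""
        return {"form": self.form, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateLaw":
        return cls(form=d["form"], params=dict(d["params"]))


@dataclass(frozen=True)
class TemperatureSpec:
    """Simulation temperature and the Q10 convention used to scale rates.

    ``factor() = q10_base ** ((T - T_base) / 10)`` multiplies every rate
    constant.  The kinetic NaV1.5 scheme uses ``T_base = 20`` C; the
    Hodgkin-Huxley presets were originally parameterized at 6.3 C and
    carry that base in their preset files.
    """

    T: float = 20.0
    T_base: float = 20.0
    q10_base: float = 3.0

    def __post_init__(self) -> None:
        if self.q10_base <= 0:
            raise RateLawError("q10_base must be positive")

    def factor(self) -> float:
        return q10_factor(self)


def _sigmoid_branch(V: float, B: float, V_half: float, k: float) -> float:
    x = (V - V_half) / k
    # exp overflow guard: the branch saturates at 0 or B.
    if x > 700.0:
        return 0.0
    return B / (1.0 + math.exp(x))


def eval_rate_law(law: RateLaw, V: float) -> float:
    """Evaluate a rate law at membrane potential ``V`` (mV) -> ms^-1.

    The linoid form uses its removable-singularity limit ``A * k`` at
    ``V = V1/2`` (L'Hopital), and is implemented in the sign convention
    that yields positive, increasing rates with positive ``k``.
    """
    if not math.isfinite(V):
        raise RateLawError(f"membrane potential must be finite, got {V}")
    p = law.params
    if law.form == "constant":
        return p["A"]
    if law.form == "exponential":
        return p["A"] * math.exp((V - p["V_half"]) / p["k"])
    if law.form == "sigmoid":
        return _sigmoid_branch(V, p["A"], p["V_half"], p["k"])
    if law.form == "linoid":
        x = V - p["V_half"]
        k = p["k"]
        if abs(x / k) < 1e-9:
            return p["A"] * k
        return p["A"] * x / (1.0 - math.exp(-x / k))
    if law.form == "double_sigmoid":
        rate = 0.0
        if "B_hyp" in p:
            rate += _sigmoid_branch(V, p["B_hyp"], p["V_hyp"], p["k_hyp"])
        if "B_dep" in p:
            rate += _sigmoid_branch(V, p["B_dep"], p["V_dep"], p["k_dep"])
        return rate
    if law.form == "offset_sigmoid":
        return p["tau_min"] + _sigmoid_branch(V, p["tau_max"], p["V_half"], p["k"])
    raise RateLawError(f"unknown rate-law form {law.form!r}")  # pragma: no cover


def q10_factor(spec: TemperatureSpec) -> float:
    """Temperature scaling factor ``q10_base ** ((T - T_base) / 10)``."""
    return spec.q10_base ** ((spec.T - spec.T_base) / 10.0)


def gate_infty_tau(
    alpha: RateLaw, beta: RateLaw, V: float, q10: float = 1.0
) -> tuple[float, float]:
    """Steady state and time constant of a first-order HH gate.

    ``x_inf = a / (a + b)`` (independent of temperature) and
    ``tau = 1 / ((a + b) * q10)`` in ms.  Raises :class:`RateLawError`
    when ``a + b`` vanishes (the gate has no defined relaxation).
    """
    a = eval_rate_law(alpha, V)
    b = eval_rate_law(beta, V)
    s = a + b
    if s == 0.0:
        raise RateLawError(f"alpha + beta = 0 at V={V} mV: gate kinetics degenerate")
    return a / s, 1.0 / (s * q10)
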
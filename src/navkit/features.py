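"""Curve fitting and per-protocol electrophysiological feature extraction.

The protocols yield families of current traces; the standard reductions
fitted here are:

* activation: peak currents -> conductance via ``G = I / (V - E_Na)``,
  normalized and fitted to a Boltzmann ``G/Gmax = (1 + exp((V - V1/2)/k))^-1``
  (V1/2, k free; k < 0 for activation).  Per-sweep time constants from the
  Hodgkin-Huxley transient ``y = A (1 - exp(-t/tau_m))^3 exp(-t/tau_h)``
  fitted over the whole test epoch.
* availability: normalized test-pulse peaks fitted to the offset Boltzmann
  ``I/Imax = A + (1 - A) (1 + exp((V - V1/2)/k))^-1`` (A = non-inactivating
  fraction; k > 0).
* deactivation: tail currents fitted per repolarization level to
  ``A exp(-t/tau)``.
* repriming: P2/P1 peak ratios vs recovery interval; single-exponential
  recovery ``A1 (1 - exp(-t/tau1))`` for the fast protocol, double
  ``A1 (1 - exp(-t/tau1)) + A2 (1 - exp(-t/tau2))`` for the slow one.
* slow-inactivation onset: P2/P1 vs conditioning duration fitted to
  ``A1 + A2 exp(-t/tau)``.

All fits are nonlinear least squares with a fixed, deterministic
multi-start grid (decade-spaced time-constant starts spanning the
abscissa range; amplitude starts from the data extremes), so identical
inputs always give identical results.  Non-convergence is flagged on the
result, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .protocols import SweepSet, peak_current

__all__ = [
    "FitResult",
    "FeatureSet",
    "FitError",
    "fit_curve",
    "activation_features",
    "availability_features",
    "deactivation_features",
    "repriming_features",
    "slow_onset_features",
    "FIT_MODELS",
]


class FitError(ValueError):
    """Raised for ill-posed fitting requests (bad model name, too few points)."""


@dataclass
class FitResult:
    """Least-squares fit outcome.

    ``ssr`` is the squared-residual norm between the data and the fitted
    curve (the "error value" reported alongside every feature); ``flagged``
    marks degenerate inputs (e.g. a flat availability curve with nothing
    to fit) in addition to ``converged``.
    """

    model: str
    params: dict[str, float]
    ssr: float
    converged: bool
    flagged: bool = False

    def __getitem__(self, key: str) -> float:
        return self.params[key]


@dataclass
class FeatureSet:
    """Extracted features of one protocol, each traceable to a FitResult."""

    protocol: str
    features: dict[str, float] = field(default_factory=dict)
    fits: dict[str, FitResult] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"protocol": self.protocol, "features": dict(self.features)}
        out["fits"] = {
            k: {"model": f.model, "params": f.params, "ssr": f.ssr,
                "converged": f.converged, "flagged": f.flagged}
            for k, f in self.fits.items()
        }
        return out


# ---------------------------------------------------------------------------
# Fit models
# ---------------------------------------------------------------------------

def _boltzmann(x, V_half, k):
    return 1.0 / (1.0 + np.exp(np.clip((x - V_half) / k, -500, 500)))


def _boltzmann_offset(x, A, V_half, k):
    return A + (1.0 - A) / (1.0 + np.exp(np.clip((x - V_half) / k, -500, 500)))


def _mono_exp(x, A, tau):
    return A * np.exp(-x / tau)


def _hh_m3h(x, A, tau_m, tau_h):
    return A * (1.0 - np.exp(-x / tau_m)) ** 3 * np.exp(-x / tau_h)


def _recovery_single(x, A1, tau1):
    return A1 * (1.0 - np.exp(-x / tau1))


def _slow_onset_exp(x, A1, A2, tau):
    return A1 + A2 * np.exp(-x / tau)


def _recovery_double(x, A1, tau1, A2, tau2):
    return A1 * (1.0 - np.exp(-x / tau1)) + A2 * (1.0 - np.exp(-x / tau2))


@dataclass(frozen=True)
class _ModelDef:
    func: Callable
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]


_INF = math.inf

FIT_MODELS: dict[str, _ModelDef] = {
    "boltzmann": _ModelDef(_boltzmann, ("V_half", "k"), (-_INF, -_INF), (_INF, _INF)),
    "boltzmann_offset": _ModelDef(
        _boltzmann_offset, ("A", "V_half", "k"), (0.0, -_INF, -_INF), (1.0, _INF, _INF)
    ),
    "mono_exp": _ModelDef(_mono_exp, ("A", "tau"), (-_INF, 1e-9), (_INF, _INF)),
    "hh_m3h": _ModelDef(
        _hh_m3h, ("A", "tau_m", "tau_h"), (0.0, 1e-9, 1e-9), (_INF, _INF, _INF)
    ),
    "recovery_single": _ModelDef(
        _recovery_single, ("A1", "tau1"), (0.0, 1e-9), (_INF, _INF)
    ),
    "slow_onset_exp": _ModelDef(
        _slow_onset_exp, ("A1", "A2", "tau"), (0.0, 0.0, 1e-9), (_INF, _INF, _INF)
    ),
    "recovery_double": _ModelDef(
        _recovery_double, ("A1", "tau1", "A2", "tau2"),
        (0.0, 1e-9, 0.0, 1e-9), (_INF, _INF, _INF, _INF),
    ),
}


def _tau_starts(x: np.ndarray) -> list[float]:
    """Decade-spaced time-constant starts spanning the abscissa range."""
    pos = x[x > 0]
    lo = float(pos.min()) if pos.size else 1e-3
    hi = float(x.max())
    lo = max(lo, hi * 1e-6)
    n = max(int(math.ceil(math.log10(hi / lo))) + 1, 2)
    return list(np.logspace(math.log10(lo), math.log10(hi), n))


def _start_grid(model: str, x: np.ndarray, y: np.ndarray) -> list[list[float]]:
    """Deterministic multi-start initial-guess grid per model."""
    ymax, ymin = float(y.max()), float(y.min())
    yspan = ymax - ymin
    xmid = float(np.median(x))
    if model not in ("boltzmann", "boltzmann_offset"):
        taus = _tau_starts(x)
    if model == "boltzmann":
        return [[xmid + dv, k] for dv in (-20.0, 0.0, 20.0) for k in (-8.0, 8.0)]
    if model == "boltzmann_offset":
        return [
            [a, xmid + dv, k]
            for a in (0.0, max(min(ymin, 1.0), 0.0))
            for dv in (-20.0, 0.0, 20.0)
            for k in (-8.0, 8.0)
        ]
    if model == "mono_exp":
        return [[a, t] for a in (ymax, y[0] if y[0] != 0 else ymax) for t in taus]
    if model == "hh_m3h":
        return [[max(ymax, 1e-12) * s, tm, th]
                for s in (1.0, 2.0)
                for tm in taus for th in taus if th >= tm]
    if model == "recovery_single":
        return [[max(ymax, 1e-12), t] for t in taus]
    if model == "slow_onset_exp":
        return [[max(ymin, 0.0), max(yspan, 1e-12), t] for t in taus]
    if model == "recovery_double":
        return [
            [0.8 * max(ymax, 1e-12), t1, 0.2 * max(ymax, 1e-12), t2]
            for t1 in taus for t2 in taus if t2 > t1
        ]
    raise FitError(f"unknown fit model {model!r}")  # pragma: no cover


def fit_curve(
    model: str,
    x: Sequence[float],
    y: Sequence[float],
    init: Sequence[float] | None = None,
) -> FitResult:
    """Deterministic multi-start nonlinear least-squares fit.

    ``init`` optionally replaces the built-in start grid with a single
    start.  Returns the best (lowest squared-residual-norm) converged
    start; a fit that never converges is flagged, not raised.
    """
    if model not in FIT_MODELS:
        raise FitError(f"unknown fit model {model!r}; choose from {sorted(FIT_MODELS)}")
    mdef = FIT_MODELS[model]
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be equal-length 1-D arrays")
    if x.size < len(mdef.param_names) + 1:
        raise FitError(
            f"{model} needs at least {len(mdef.param_names) + 1} points, got {x.size}"
        )
    starts = [list(init)] if init is not None else _start_grid(model, x, y)
    best = None
    for p0 in starts:
        p0 = np.clip(p0, mdef.lower, mdef.upper)
        try:
            sol = least_squares(
                lambda p: mdef.func(x, *p) - y,
                p0,
                bounds=(mdef.lower, mdef.upper),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        ssr = float(np.sum(sol.fun**2))
        if sol.success and (best is None or ssr < best[0] - 1e-15):
            best = (ssr, sol.x)
    if best is None:
        return FitResult(model, dict(zip(mdef.param_names, starts[0])),
                         ssr=float("inf"), converged=False, flagged=True)
    ssr, popt = best
    params = dict(zip(mdef.param_names, (float(v) for v in popt)))
    if model == "recovery_double" and params["tau1"] > params["tau2"]:
        params = {
            "A1": params["A2"], "tau1": params["tau2"],
            "A2": params["A1"], "tau2": params["tau1"],
        }
    return FitResult(model, params, ssr=ssr, converged=True)


# ---------------------------------------------------------------------------
# Per-protocol feature extraction
# ---------------------------------------------------------------------------

def _measure_epoch(sweeps: SweepSet, key: str) -> int:
    try:
        return sweeps.protocol.measure[key]
    except KeyError as exc:
        raise FitError(
            f"protocol {sweeps.protocol.name!r} has no {key!r} measurement epoch"
        ) from exc


def activation_features(sweeps: SweepSet, E_rev: float | None = None) -> FeatureSet:
    """Activation Boltzmann (V1/2, k) and per-sweep tau_m/tau_h tables.

    Peak test currents are converted to conductances through the driving
    force, normalized by the maximum, and fitted to the two-parameter
    Boltzmann.  Sweeps within 1 mV of the reversal potential are excluded
    from the G-V fit (driving-force singularity).  Each sweep's current
    transient is separately fitted to the m3h form for the tau_m(V) /
    tau_h(V) tables (sweeps with peaks below 1% of the largest are
    skipped: no transient to fit).
    """
    if E_rev is None:
        E_rev = sweeps.channel.E_rev
    ep = _measure_epoch(sweeps, "test")
    V = sweeps.sweep_values
    peaks = np.array([peak_current(s, ep)[0] for s in sweeps.sweeps])
    ok = np.abs(V - E_rev) >= 1.0
    G = peaks[ok] / (V[ok] - E_rev)
    Gn = G / G.max()
    fit = fit_curve("boltzmann", V[ok], Gn)

    rows = []
    pk_mag = np.abs(peaks)
    for sw, pk in zip(sweeps.sweeps, pk_mag):
        if pk < 0.01 * pk_mag.max():
            continue
        tr = sw.epochs[ep]
        t = tr.t - tr.t[0]
        y = np.abs(tr.I)
        f = fit_curve("hh_m3h", t[1:], y[1:])
        rows.append({
            "V_mV": sw.value, "tau_m_ms": f.params["tau_m"],
            "tau_h_ms": f.params["tau_h"], "ssr": f.ssr, "converged": f.converged,
        })
    table = pd.DataFrame(rows)

    fs = FeatureSet("activation")
    fs.fits["gv_boltzmann"] = fit
    fs.features["activation_v_half"] = fit.params["V_half"]
    fs.features["activation_k"] = fit.params["k"]
    fs.tables["time_constants"] = table
    return fs


def availability_features(sweeps: SweepSet) -> FeatureSet:
    """Steady-state availability: offset Boltzmann (V1/2, k, A)."""
    ep = _measure_epoch(sweeps, "test")
    V = sweeps.sweep_values
    peaks = np.abs([peak_current(s, ep)[0] for s in sweeps.sweeps])
    fs = FeatureSet("availability")
    if peaks.max() <= 0 or (peaks.max() - peaks.min()) < 1e-3 * peaks.max():
        # nothing inactivates: flat curve, no half-point to estimate
        fit = FitResult("boltzmann_offset",
                        {"A": 1.0, "V_half": float("nan"), "k": float("nan")},
                        ssr=0.0, converged=False, flagged=True)
    else:
        fit = fit_curve("boltzmann_offset", V, peaks / peaks.max())
    fs.fits["availability_boltzmann"] = fit
    fs.features["availability_v_half"] = fit.params["V_half"]
    fs.features["availability_k"] = fit.params["k"]
    fs.features["availability_offset"] = fit.params["A"]
    return fs


def deactivation_features(sweeps: SweepSet) -> FeatureSet:
    """Tail-current mono-exponential time constants per repolarization level.

    The fit starts one sample after the voltage step (discontinuity
    guard) and runs to the end of the tail epoch.
    """
    ep = _measure_epoch(sweeps, "tail")
    rows = []
    for sw in sweeps.sweeps:
        tr = sw.epochs[ep]
        t = tr.t[1:] - tr.t[1]
        y = np.abs(tr.I[1:])
        f = fit_curve("mono_exp", t, y)
        rows.append({
            "V_mV": sw.value, "tau_ms": f.params["tau"], "A": f.params["A"],
            "ssr": f.ssr, "converged": f.converged,
        })
    fs = FeatureSet("deactivation")
    fs.tables["tail_tau"] = pd.DataFrame(rows)
    return fs


def _p2_p1_ratios(sweeps: SweepSet) -> tuple[np.ndarray, np.ndarray]:
    e1 = _measure_epoch(sweeps, "p1")
    e2 = _measure_epoch(sweeps, "p2")
    p1 = np.abs([peak_current(s, e1)[0] for s in sweeps.sweeps])
    p2 = np.abs([peak_current(s, e2)[0] for s in sweeps.sweeps])
    if np.any(p1 == 0):
        raise FitError("conditioning pulse produced no current; P2/P1 undefined")
    return sweeps.sweep_values, p2 / p1


def repriming_features(sweeps: SweepSet, kind: str = "fast") -> FeatureSet:
    """Recovery from inactivation: P2/P1 vs recovery interval.

    ``kind="fast"`` fits the single-exponential recovery (tau1 and plateau
    A1); ``kind="slow"`` fits the double-exponential and reports both time
    constants with their fractional amplitudes A1/(A1+A2), A2/(A1+A2).
    """
    if kind not in ("fast", "slow"):
        raise FitError("kind must be 'fast' or 'slow'")
    t, ratio = _p2_p1_ratios(sweeps)
    fs = FeatureSet(sweeps.protocol.name)
    if kind == "fast":
        fit = fit_curve("recovery_single", t, ratio)
        fs.fits["recovery"] = fit
        fs.features["recovery_tau"] = fit.params["tau1"]
        fs.features["recovery_plateau"] = fit.params["A1"]
    else:
        fit = fit_curve("recovery_double", t, ratio)
        fs.fits["recovery"] = fit
        A1, A2 = fit.params["A1"], fit.params["A2"]
        fs.features["recovery_tau1"] = fit.params["tau1"]
        fs.features["recovery_tau2"] = fit.params["tau2"]
        fs.features["fractional_recovery_1"] = A1 / (A1 + A2)
        fs.features["fractional_recovery_2"] = A2 / (A1 + A2)
    return fs


def slow_onset_features(sweeps: SweepSet) -> FeatureSet:
    """Development of slow inactivation: P2/P1 vs conditioning duration.

    Fitted to ``A1 + A2 exp(-t/tau)``; ``A1`` is the plateau (the fraction
    of channels that never slow-inactivates at the conditioning voltage).
    A flat curve (slow inactivation absent) is flagged.
    """
    t, ratio = _p2_p1_ratios(sweeps)
    fs = FeatureSet(sweeps.protocol.name)
    if ratio.max() - ratio.min() < 1e-3:
        fit = FitResult("slow_onset_exp",
                        {"A1": float(ratio.mean()), "A2": 0.0, "tau": float("nan")},
                        ssr=0.0, converged=False, flagged=True)
    else:
        fit = fit_curve("slow_onset_exp", t, ratio)
    fs.fits["onset"] = fit
    fs.features["slow_onset_tau"] = fit.params["tau"]
    fs.features["slow_onset_plateau"] = fit.params["A1"]
    return fs
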
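"""Bundled channel presets and the experimental reference table.

Presets are YAML documents shipped with the package: the original squid
sodium channel, the staged NaV1.5 Hodgkin-Huxley tunings (rows ``a``
through ``h``, each stage refined against one electrophysiological
protocol), and the five-state NaV1.5 Markov scheme.  Three aliases expose
the alpha_h tunings discussed for the fast-inactivation conflict:

* ``nav15_hh_variant_a`` -- repriming-optimized alpha_h (row f, m3h);
* ``nav15_hh_variant_b`` -- availability-optimized alpha_h (row e, m3h);
* ``nav15_hh_variant_c`` -- trade-off alpha_h (m3h; the same alpha_h the
  final m3hs rows g/h carry).

The reference table bundles the published whole-cell patch-clamp feature
values (mean and, where reported, standard deviation) the models are
benchmarked against.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .channels import (
    ChannelSpec,
    HHChannelSpec,
    HHGate,
    MarkovSchemeSpec,
    MarkovTransition,
)
from .ratelaws import RateLaw, TemperatureSpec

__all__ = [
    "list_channels",
    "load_channel",
    "channel_from_dict",
    "load_reference_table",
    "CHANNEL_ALIASES",
]

CHANNEL_ALIASES: dict[str, str] = {
    "nav15_hh_variant_a": "nav15_hh_row_f",
    "nav15_hh_variant_b": "nav15_hh_row_e",
}

_PKG = "navkit.data"


def _preset_files() -> list[str]:
    return sorted(
        r.name[:-5]
        for r in resources.files(_PKG).iterdir()
        if r.name.endswith(".yaml")
    )


def list_channels() -> list[str]:
    """Names accepted by :func:`load_channel` (preset files plus aliases)."""
    return sorted(_preset_files() + list(CHANNEL_ALIASES))


def channel_from_dict(doc: Mapping) -> ChannelSpec:
    """Build a channel spec from the preset schema (parsed YAML/JSON)."""
    temp = TemperatureSpec(**doc.get("temperature", {}))
    common = dict(
        gbar=float(doc["gbar"]),
        E_rev=float(doc["E_rev"]),
        temperature=temp,
        name=doc.get("name", "channel"),
    )
    if doc["family"] == "hh":
        gates = tuple(
            HHGate(
                name=g["name"],
                exponent=int(g["exponent"]),
                alpha=RateLaw.from_dict(g["alpha"]),
                beta=RateLaw.from_dict(g["beta"]),
            )
            for g in doc["gates"]
        )
        return HHChannelSpec(gates=gates, **common)
    if doc["family"] == "markov":
        transitions = tuple(
            MarkovTransition(
                source=t["from"], target=t["to"], rate=RateLaw.from_dict(t["rate"])
            )
            for t in doc["transitions"]
        )
        return MarkovSchemeSpec(
            states=tuple(doc["states"]),
            open_state=doc["open_state"],
            transitions=transitions,
            **common,
        )
    raise ValueError(f"unknown channel family {doc['family']!r}")


def load_channel(name: str, T: float | None = None) -> ChannelSpec:
    """Load a bundled channel preset by name (aliases resolved).

    ``T`` optionally overrides the simulation temperature (C) while
    keeping the preset's Q10 base convention.
    """
    fname = CHANNEL_ALIASES.get(name, name)
    ref = resources.files(_PKG) / f"{fname}.yaml"
    if not ref.is_file():
        raise KeyError(
            f"unknown channel preset {name!r}; available: {list_channels()}"
        )
    doc = yaml.safe_load(ref.read_text())
    if name in CHANNEL_ALIASES:
        doc["name"] = name
    spec = channel_from_dict(doc)
    if T is not None:
        spec = spec.with_temperature(T=T)
    return spec


def load_reference_table() -> pd.DataFrame:
    """Experimental NaV1.5 reference values (indexed by ``feature_id``).

    ``exp_sd`` is NaN for rows where no standard deviation was published.
    """
    ref = resources.files(_PKG) / "reference_nav15.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("feature_id")
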
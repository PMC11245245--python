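"""Built-in parameter presets.

Amounts are in arbitrary consistent units (one BCHE-unit = one BCHE
molecule, one ACh-unit = one molecule of ACh / one occupied receptor),
time in minutes.

``canine-default`` is a nondimensional working point chosen for
testability: loop gain G*H = 2.5, unsaturated at a drive of 100
ACh-units/min (fixed point S* = 20, N* = 40, B* = 2).

``high-activity`` anchors the BCHE specific activity to the reported
catalytic rate of canine BCHE — at least 5000 molecules of ACh
hydrolyzed per second per molecule of enzyme.  Conversion:
5000 ACh/s * 60 s/min = 3.0e5 ACh-units per minute per BCHE-unit.
"""

from __future__ import annotations

from .model import ModelParameters

__all__ = ["PRESETS", "get_preset", "list_presets"]

PRESETS: dict[str, ModelParameters] = {
    "canine-default": ModelParameters(
        G=0.5,
        F=0.02,
        J=0.2,
        k_cat=50.0,
        N_max=1000.0,
        S_max=30.0,
        tau_syn=0.0,
        epsilon_h=1e-3,
    ),
    # k_cat = 5000 ACh/s per molecule * 60 = 3.0e5 ACh-units/min/BCHE-unit
    "high-activity": ModelParameters(
        G=0.5,
        F=0.02,
        J=0.2,
        k_cat=3.0e5,
        N_max=1000.0,
        S_max=30.0,
        tau_syn=0.0,
        epsilon_h=1e-3,
    ),
}


def get_preset(name: str) -> ModelParameters:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> dict[str, ModelParameters]:
    """Names and parameter sets of all built-in presets."""
    return dict(PRESETS)
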
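"""Synthetic DSC thermogram generation.

The excess heat capacity of each transition follows the two-state van't
Hoff model

    Cp_ex(T) = dH * dHvH / (R T^2) * K / (1 + K)^2,
    K(T) = exp[-(dHvH / R) * (1/T - 1/Tm)]

with T in kelvin. Integrating Cp_ex over a temperature window that brackets
the transition returns the calorimetric enthalpy dH (the model is the exact
derivative of dH times the converted fraction K/(1+K)).
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidGridError
from ..types import Thermogram, ThermogramParams

#: Gas constant in kcal / (mol K).
R_KCAL = 1.987204258640832e-3

CELSIUS_OFFSET = 273.15


def vant_hoff_excess_cp(t_degc: np.ndarray, tm_degc: float, dh: float, dhvh: float) -> np.ndarray:
    """Two-state excess heat capacity (kcal/mol/degC) on a Celsius grid."""
    t = np.asarray(t_degc, dtype=float) + CELSIUS_OFFSET
    tm = tm_degc + CELSIUS_OFFSET
    # exponent kept in log space to avoid overflow far from Tm
    ln_k = -(dhvh / R_KCAL) * (1.0 / t - 1.0 / tm)
    # K/(1+K)^2 = 1/(4 cosh^2(lnK/2)) is overflow-safe
    sech2 = 1.0 / np.cosh(np.clip(ln_k / 2.0, -350, 350)) ** 2
    return dh * dhvh / (R_KCAL * t**2) * 0.25 * sech2


def gen_thermogram(params: ThermogramParams) -> Thermogram:
    """Generate a noisy thermogram with baseline on the requested grid.

    Raises
    ------
    InvalidGridError
        If the temperature range and step produce fewer than 10 points.
    """
    params.validate()
    t0, t1 = params.t_range
    n = int(np.floor((t1 - t0) / params.t_step + 0.5)) + 1
    if n < 10:
        raise InvalidGridError(
            f"grid {params.t_range} at step {params.t_step} has only {n} points"
        )
    t = t0 + params.t_step * np.arange(n)

    cp = params.baseline_intercept + params.baseline_slope * t
    for tm, dh, dhvh in params.transitions:
        cp = cp + vant_hoff_excess_cp(t, tm, dh, dhvh)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        cp = cp + rng.normal(0.0, params.noise_sd, size=n)
    return Thermogram(temperature=t, cp=cp)
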
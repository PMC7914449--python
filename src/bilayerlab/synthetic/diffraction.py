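"""Synthetic small- and wide-angle diffraction patterns.

Lamellar patterns come from the same analytic model the fitting stage uses
(:mod:`bilayerlab.saxd`): a symmetric Gaussian electron-density profile
Fourier-transformed to a form factor, multiplied by a finite-stack
interference function with optional disorder damping, and a 1/s^2 powder
(Lorentz) factor. Inverted-hexagonal patterns are built directly from the
2D hexagonal peak-position law s_hk = sqrt(h^2 + hk + k^2) / d10.
"""

from __future__ import annotations

import numpy as np

from ..types import DiffractionPattern, LamellarModelParams

# (h, k) reflections used for synthetic HII patterns, lowest four orders.
HEX_INDICES = ((1, 0), (1, 1), (2, 0), (2, 1))


def hex_ratio(h: int, k: int) -> float:
    """Peak position multiplier sqrt(h^2 + hk + k^2) of the (h, k) reflection."""
    return float(np.sqrt(h * h + h * k + k * k))


def lamellar_intensity(s: np.ndarray, p: LamellarModelParams, scale: float = 1.0) -> np.ndarray:
    """Model intensity I(s) = scale * |F|^2 * S / s^2 for a lamellar stack."""
    from ..saxd import form_factor, structure_factor  # shared model, avoid cycle at import

    q = 2.0 * np.pi * np.asarray(s, dtype=float)
    f = form_factor(q, p.zH, p.sigmaH, p.sigmaC, p.rho_ratio)
    sf = structure_factor(q, p.d, p.n_lamellae, p.eta)
    return scale * f * f * sf / (s * s)


def gen_saxs_pattern(
    params: LamellarModelParams,
    s_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> DiffractionPattern:
    """Generate a multilamellar SAXD pattern on ``s_grid`` (1/Angstrom).

    Additive Gaussian noise of standard deviation ``noise_sd`` (in counts)
    is applied and the result clipped at zero so intensities stay
    non-negative. If the grid does not span the first Bragg order
    ``s = 1/d``, a warning flag is attached to the pattern.
    """
    params.validate()
    s = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s) <= 0) or np.any(s <= 0):
        raise ValueError("s_grid must be strictly increasing and positive")
    intensity = lamellar_intensity(s, params, scale=scale)
    warnings = []
    n_orders = sum(1 for h in range(1, 11) if s[0] <= h / params.d <= s[-1])
    if n_orders == 0:
        warnings.append(f"s_grid [{s[0]:g}, {s[-1]:g}] spans no Bragg order of d={params.d:g} A")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=s.size)
    intensity = np.clip(intensity, 0.0, None)
    return DiffractionPattern(s=s, intensity=intensity, region="SAXD", warnings=warnings)


def gen_hexagonal_pattern(
    d10: float,
    s_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1000.0,
    peak_width: float = 5e-4,
) -> DiffractionPattern:
    """Generate an inverted-hexagonal (HII) SAXD pattern.

    Gaussian peaks of width ``peak_width`` (1/A) are placed at
    ``s = sqrt(h^2+hk+k^2)/d10`` for the (10), (11), (20) and (21)
    reflections with geometrically decreasing amplitudes. A warning flag is
    attached when fewer than two reflections fall inside the grid window.
    """
    if d10 <= 0:
        raise ValueError("d10 must be positive")
    s = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s) <= 0) or np.any(s <= 0):
        raise ValueError("s_grid must be strictly increasing and positive")
    rel_amp = (1.0, 0.45, 0.30, 0.20)
    intensity = np.zeros_like(s)
    in_window = 0
    for (h, k), a in zip(HEX_INDICES, rel_amp):
        s_hk = hex_ratio(h, k) / d10
        if s[0] <= s_hk <= s[-1]:
            in_window += 1
        intensity += amplitude * a * np.exp(-0.5 * ((s - s_hk) / peak_width) ** 2)
    warnings = []
    if in_window < 2:
        warnings.append(
            f"s_grid [{s[0]:g}, {s[-1]:g}] spans {in_window} hexagonal reflection(s) of d10={d10:g} A"
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=s.size)
    intensity = np.clip(intensity, 0.0, None)
    return DiffractionPattern(s=s, intensity=intensity, region="SAXD", warnings=warnings)


def gen_waxd_pattern(
    peaks: list[tuple[float, float, float]],
    s_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DiffractionPattern:
    """Generate a wide-angle pattern from ``(d_A, height, width_invA)`` peaks.

    Convenience generator for chain-packing signatures: sharp peaks for gel
    phases, a broad hump for fluid chains. Peak positions are given as
    d-spacings in Angstrom and converted to s = 1/d.
    """
    s = np.asarray(s_grid, dtype=float)
    intensity = np.zeros_like(s)
    for d, height, width in peaks:
        intensity += height * np.exp(-0.5 * ((s - 1.0 / d) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=s.size)
    intensity = np.clip(intensity, 0.0, None)
    return DiffractionPattern(s=s, intensity=intensity, region="WAXD")


def default_saxd_grid(n: int = 640) -> np.ndarray:
    """Default SAXD s-grid covering 0.0075-0.07 1/A."""
    return np.linspace(0.0075, 0.07, n)


def default_waxd_grid(n: int = 400) -> np.ndarray:
    """Default WAXD s-grid covering 0.20-0.29 1/A."""
    return np.linspace(0.20, 0.29, n)
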
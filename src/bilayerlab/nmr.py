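"""31P powder-lineshape simulation/classification and NOESY
cross-relaxation analysis.

31P conventions
---------------
``delta_sigma`` is the residual chemical-*shielding* anisotropy in ppm; it
is negative for a phospholipid bilayer. Fast lateral diffusion around the
cylinders of an inverted-hexagonal phase averages the tensor further,
halving and sign-reversing the effective anisotropy. On the chemical-shift
axis (low field = larger ppm, plotted left) the shift-space anisotropy is
the negative of the shielding one, so a bilayer shows its intense
90-degree edge at high field with a low-field shoulder, and the hexagonal
phase the mirror image at half the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import signal

from .errors import MissingDiagonalError
from .types import (
    LIPID_GROUP_ORDER,
    CrossRelaxationProfile,
    NoesyVolumeTable,
    Spectrum31P,
)


# ---------------------------------------------------------------------------
# 31P lineshapes

def simulate_31p_lineshape(
    delta_sigma: float,
    phase: str = "lamellar",
    lb: float = 100.0,
    field_MHz: float = 242.9,
    iso_ppm: float = 0.0,
    ppm_window: Optional[tuple[float, float]] = None,
    n_points: int = 2048,
    theta_step_deg: float = 0.25,
) -> Spectrum31P:
    """Numerical powder average of an axially symmetric 31P lineshape.

    The orientation-dependent chemical shift is

        shift(t) = iso_ppm - (delta_eff / 3) * (3 cos^2 t - 1)

    where ``delta_eff`` is the effective shielding anisotropy:
    ``delta_sigma`` for the lamellar phase, ``-delta_sigma/2`` for the
    hexagonal phase (fast lateral diffusion around the cylinders halves
    and sign-reverses it) and 0 for isotropic; the minus sign converts
    shielding to shift. The edge-to-edge span of the powder pattern is
    exactly ``|delta_eff|``. Orientations are averaged on a uniform theta
    grid with sin(theta) weights, then convolved with a Lorentzian of
    ``lb`` Hz FWHM; the result is unit-area normalized.
    """
    if field_MHz <= 0:
        raise ValueError("field_MHz must be positive")
    if lb < 0:
        raise ValueError("lb must be >= 0")
    if phase == "lamellar":
        delta_eff = delta_sigma
    elif phase == "hexagonal":
        delta_eff = -delta_sigma / 2.0
    elif phase == "isotropic":
        delta_eff = 0.0
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if phase != "isotropic" and delta_sigma == 0:
        raise ValueError("delta_sigma must be nonzero for anisotropic phases")

    lb_ppm = lb / field_MHz if lb > 0 else 0.0
    if ppm_window is None:
        half = abs(delta_sigma) + 10.0 * max(lb_ppm, 0.5)
        ppm_window = (iso_ppm - half, iso_ppm + half)
    lo, hi = ppm_window
    edges = np.linspace(lo, hi, n_points + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dppm = centers[1] - centers[0]

    theta = np.deg2rad(np.arange(theta_step_deg / 2, 90.0, theta_step_deg))
    shifts = iso_ppm - (delta_eff / 3.0) * (3.0 * np.cos(theta) ** 2 - 1.0)
    weights = np.sin(theta)
    hist, _ = np.histogram(shifts, bins=edges, weights=weights)
    intensity = hist.astype(float)

    if lb_ppm > 0:
        gamma = lb_ppm / 2.0  # Lorentzian HWHM
        x = np.arange(-n_points + 1, n_points) * dppm
        kernel = gamma / (np.pi * (x * x + gamma * gamma))
        intensity = signal.fftconvolve(intensity, kernel, mode="same")
        intensity = np.clip(intensity, 0.0, None)
    elif delta_eff == 0:
        # a delta function needs at least minimal width to be a line
        intensity[np.argmin(np.abs(centers - iso_ppm))] += 1.0

    area = float(np.trapezoid(intensity, centers))
    if area > 0:
        intensity = intensity / area
    # store left-to-right: decreasing ppm
    return Spectrum31P(ppm=centers[::-1].copy(), intensity=intensity[::-1].copy())


class Classification31P(NamedTuple):
    phase: str                       # lamellar | hexagonal_II | isotropic | mixture
    edges: tuple[float, float]       # (low-field ppm, high-field ppm) crossings
    span: float                      # edge-to-edge width in ppm
    skewness: float
    indeterminate: bool              # SNR too low to tell isotropic from noise


def spectrum_edges(sp: Spectrum31P, frac: float = 0.05) -> tuple[float, float]:
    """Outermost crossings at ``frac`` of the maximum intensity (ppm)."""
    y = np.clip(sp.intensity, 0.0, None)
    thr = frac * y.max()
    above = np.nonzero(y >= thr)[0]
    if above.size == 0:
        return (float("nan"), float("nan"))
    return (float(sp.ppm[above[0]]), float(sp.ppm[above[-1]]))


def classify_31p(
    sp: Spectrum31P,
    skew_threshold: float = 0.15,
    edge_frac: float = 0.05,
    snr_threshold: float = 10.0,
    mixture_min_sep_frac: float = 0.2,
) -> Classification31P:
    """Classify a 31P powder spectrum by lineshape skew and apex structure.

    Skew about the first moment separates lamellar (positive: intense
    high-field edge, low-field tail) from hexagonal (negative); a near-zero
    skew is isotropic. Two resolvable apex components lying on opposite
    sides of the mean are reported as a mixture. Edges are located at
    ``edge_frac`` fractional-height crossings.
    """
    raw = sp.intensity
    ppm = sp.ppm
    n_tail = max(8, raw.size // 20)
    tails = np.concatenate([raw[:n_tail], raw[-n_tail:]])
    noise = float(np.std(tails))
    snr = raw.max() / noise if noise > 0 else np.inf

    # smooth the signed trace before anything else (clipping first would
    # leave a positive noise pedestal; spikes would dominate the 3rd moment)
    win = max(11, raw.size // 100) | 1
    ys = signal.savgol_filter(raw, win, 3)
    s_tails = np.concatenate([ys[:n_tail], ys[-n_tail:]])
    noise_s = float(np.std(s_tails))
    ys = np.clip(ys - float(np.median(s_tails)), 0.0, None)

    # moments over the contiguous signal region around the apex only:
    # detached noise islands elsewhere in the window otherwise enter the
    # third moment with cubed leverage
    thr_mask = max(3.0 * noise_s, 0.02 * ys.max())
    above = ys >= thr_mask
    i_apex = int(np.argmax(ys))
    gap = win
    lo_i = i_apex
    misses = 0
    while lo_i > 0 and misses < gap:
        lo_i -= 1
        misses = 0 if above[lo_i] else misses + 1
    hi_i = i_apex
    misses = 0
    while hi_i < ys.size - 1 and misses < gap:
        hi_i += 1
        misses = 0 if above[hi_i] else misses + 1
    region = np.zeros_like(above)
    region[lo_i:hi_i + 1] = True
    ym = np.where(region & above, ys, 0.0)
    if ym.sum() == 0:
        ym = ys
    w = ym / ym.sum()
    mean = float(np.dot(w, ppm))
    var = float(np.dot(w, (ppm - mean) ** 2))
    skew = float(np.dot(w, (ppm - mean) ** 3) / var**1.5) if var > 0 else 0.0
    edges = spectrum_edges(Spectrum31P(ppm=ppm, intensity=ys), edge_frac)
    span = abs(edges[0] - edges[1])

    if snr < snr_threshold:
        return Classification31P("isotropic", edges, span, skew, indeterminate=True)

    apex, _ = signal.find_peaks(ys, prominence=0.15 * ys.max())
    if apex.size >= 2:
        pos = ppm[apex]
        sep = pos.max() - pos.min()
        if sep > mixture_min_sep_frac * span and pos.min() < mean < pos.max():
            return Classification31P("mixture", edges, span, skew, indeterminate=False)

    if skew > skew_threshold:
        return Classification31P("lamellar", edges, span, skew, indeterminate=False)
    if skew < -skew_threshold:
        return Classification31P("hexagonal_II", edges, span, skew, indeterminate=False)
    return Classification31P("isotropic", edges, span, skew, indeterminate=False)


# ---------------------------------------------------------------------------
# NOESY cross-relaxation

def cross_relaxation_rates(t: NoesyVolumeTable,
                           group_order: tuple[str, ...] = LIPID_GROUP_ORDER,
                           ) -> CrossRelaxationProfile:
    """Cross-relaxation rates sigma_ij = A_ij / (A_jj * t_m) in 1/s.

    ``A_jj`` is the diagonal volume of the lipid group the cross peak
    references (the second pair element). Raises
    :class:`MissingDiagonalError` naming the group when its diagonal is
    absent. Exactly invariant to global volume rescaling and reciprocal in
    the mixing time.
    """
    rates: dict[tuple[str, str], float] = {}
    for (lig, lip), a_ij in t.cross.items():
        if lip not in t.diagonal:
            raise MissingDiagonalError(lip)
        rates[(lig, lip)] = a_ij / (t.diagonal[lip] * t.tm)
    return CrossRelaxationProfile(rates=rates, lipid_group_order=group_order)


class LocationProfile(NamedTuple):
    rankings: dict[str, list[tuple[str, float]]]  # per ligand, sigma-descending
    modal: dict[str, Optional[str]]               # argmax group (None if no contact)
    tied: dict[str, list[str]]                    # groups tied at the top


def location_profile(p: CrossRelaxationProfile) -> LocationProfile:
    """Rank lipid groups by cross-relaxation rate for each ligand proton.

    The modal location is the argmax group; exact ties are broken toward
    the group nearer the polar interface (later in ``lipid_group_order``)
    and reported in ``tied``. A ligand whose rates are all zero yields a
    ``None`` modal location (no-contact result).
    """
    per_ligand: dict[str, dict[str, float]] = {}
    for (lig, lip), r in p.rates.items():
        per_ligand.setdefault(lig, {})[lip] = r
    order = {g: i for i, g in enumerate(p.lipid_group_order)}

    rankings, modal, tied = {}, {}, {}
    for lig, by_group in per_ligand.items():
        if len(by_group) < 2:
            raise ValueError(f"ligand {lig!r} has rates for fewer than 2 lipid groups")
        ranked = sorted(
            by_group.items(),
            key=lambda kv: (-kv[1], -order.get(kv[0], -1)),
        )
        rankings[lig] = ranked
        top_rate = ranked[0][1]
        if top_rate == 0:
            modal[lig] = None
            tied[lig] = []
            continue
        ties = [g for g, r in ranked if r == top_rate]
        modal[lig] = ranked[0][0]
        tied[lig] = ties if len(ties) > 1 else []
    return LocationProfile(rankings=rankings, modal=modal, tied=tied)
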
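"""SAXD/WAXD analysis: peak picking, phase indexing, and the Gaussian
electron-density multilamellar model fit.

Conventions: scattering vector ``s = 2 sin(theta)/lambda = 1/d`` in
1/Angstrom (no 2*pi); internal model math uses ``q = 2*pi*s``. Derived
thicknesses follow ``dHH = 2 zH``, ``dB = 2 (zH + 2 sigmaH)`` and
``dw = d - dB``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import optimize, signal

from .errors import FitFailureError, NegativeWaterError
from .types import (
    DiffractionPattern,
    LamellarFit,
    LamellarModelParams,
    Peak,
    PeakList,
    PhaseAssignment,
)

HEX_RATIOS = {(1, 0): 1.0, (1, 1): np.sqrt(3.0), (2, 0): 2.0, (2, 1): np.sqrt(7.0)}

#: Default relative tolerance for accepting an indexing assignment.
RATIO_TOL = 0.03


# ---------------------------------------------------------------------------
# electron-density model

def form_factor(q: np.ndarray, zH: float, sigmaH: float, sigmaC: float,
                rho_ratio: float) -> np.ndarray:
    """Analytic form factor of the symmetric Gaussian bilayer profile.

    The electron-density contrast is modeled as two unit Gaussians at
    ``+/- zH`` (width ``sigmaH``) and a central Gaussian of relative
    amplitude ``rho_ratio`` (negative; methyl trough) and width ``sigmaC``.
    Its Fourier transform is real by symmetry.
    """
    q = np.asarray(q, dtype=float)
    root2pi = np.sqrt(2.0 * np.pi)
    head = 2.0 * sigmaH * root2pi * np.exp(-0.5 * (q * sigmaH) ** 2) * np.cos(q * zH)
    trough = rho_ratio * sigmaC * root2pi * np.exp(-0.5 * (q * sigmaC) ** 2)
    return head + trough


def structure_factor(q: np.ndarray, d: float, n_lamellae: int, eta: float,
                     size_spread: float = 0.5) -> np.ndarray:
    """Interference function of a polydisperse stack of ~``n_lamellae`` bilayers.

    The finite-lattice interference function N + 2 sum_k (N-k) cos(k q d)
    is averaged over stack sizes uniform in
    ``[N(1-size_spread), N(1+size_spread)]`` — multilamellar samples are
    polydisperse, and the averaging suppresses the subsidiary maxima of a
    single perfect stack while leaving Bragg maxima exactly at q = 2 pi h/d.
    Positive ``eta`` additionally damps the k-th neighbor correlation by
    exp(-eta * k * (q d / 2 pi)^2), a Caille-type stand-in in which higher
    diffraction orders broaden and lose intensity first; ``eta = 0`` is the
    pure (averaged) finite-lattice case.
    """
    q = np.asarray(q, dtype=float)
    n = int(n_lamellae)
    lo = max(1, int(round(n * (1.0 - size_spread))))
    hi = max(lo, int(round(n * (1.0 + size_spread))))
    sizes = np.arange(lo, hi + 1)
    # c_k = mean over stack sizes of max(N'-k, 0)
    k = np.arange(0, hi)
    c = np.maximum(sizes[:, None] - k[None, :], 0).mean(axis=0)
    sf = np.full_like(q, c[0])
    x = (q * d / (2.0 * np.pi)) ** 2
    for kk in range(1, hi):
        damp = np.exp(-eta * kk * x) if eta > 0 else 1.0
        sf += 2.0 * c[kk] * np.cos(kk * q * d) * damp
    return np.clip(sf, 0.0, None)


def model_intensity(s: np.ndarray, d: float, zH: float, sigmaH: float, sigmaC: float,
                    rho_ratio: float, n_lamellae: int, eta: float,
                    scale: float = 1.0) -> np.ndarray:
    """Powder intensity I(s) = scale |F(q)|^2 S(q) / s^2 with q = 2 pi s."""
    s = np.asarray(s, dtype=float)
    q = 2.0 * np.pi * s
    f = form_factor(q, zH, sigmaH, sigmaC, rho_ratio)
    return scale * f * f * structure_factor(q, d, n_lamellae, eta) / (s * s)


# ---------------------------------------------------------------------------
# peak picking

def pick_peaks(p: DiffractionPattern, min_prominence: Optional[float] = None) -> PeakList:
    """Locate diffraction peaks with sub-grid apex positions.

    Peaks are detected by prominence (default: 2% of the intensity range)
    and refined by parabolic interpolation through the apex and its two
    neighbors. Returns an empty list when nothing clears the threshold.
    """
    y = p.intensity
    if min_prominence is None:
        min_prominence = 0.02 * (y.max() - y.min()) if y.max() > y.min() else np.inf
    idx, props = signal.find_peaks(y, prominence=min_prominence)
    widths, _, lo, hi = signal.peak_widths(y, idx, rel_height=0.5)
    step = np.median(np.diff(p.s))
    peaks = []
    for j, i in enumerate(idx):
        s_peak = p.s[i]
        if 0 < i < y.size - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                s_peak = p.s[i] + 0.5 * (y0 - y2) / denom * step
        peaks.append(Peak(s_peak=float(s_peak), d=1.0 / float(s_peak),
                          height=float(y[i]), width=float(widths[j] * step)))
    return PeakList(peaks=peaks)


# ---------------------------------------------------------------------------
# indexing

class IndexingResult(NamedTuple):
    d: Optional[float]
    orders: tuple
    residual: float


def _ls_spacing(s_vals: np.ndarray, mult: np.ndarray) -> tuple[float, float]:
    """Least-squares 1/d for s_h ~ mult_h / d; returns (d, rms residual)."""
    inv_d = float(np.dot(mult, s_vals) / np.dot(mult, mult))
    resid = float(np.sqrt(np.mean((s_vals - mult * inv_d) ** 2)))
    return 1.0 / inv_d, resid


def index_lamellar(peaks: PeakList, tol: float = RATIO_TOL) -> IndexingResult:
    """Assign integer orders h to peaks and fit the lamellar spacing d.

    Orders are assigned greedily from the lowest-s peak (h = 1); each later
    peak takes the nearest integer order against the running least-squares
    estimate of d and its implied spacing ``h/s`` must agree with that
    estimate within ``tol`` relative tolerance, else the assignment is
    inconsistent and an indeterminate result (d = None, infinite residual)
    is returned. The running estimate absorbs the slight order-to-order
    drift real multilamellar patterns show.
    """
    if len(peaks) < 1:
        raise ValueError("need at least one peak")
    s = peaks.s_values
    orders: list[int] = []
    d_run = 1.0 / s[0]
    for sv in s:
        h = max(1, int(round(sv * d_run)))
        d_h = h / sv
        if abs(d_h - d_run) / d_run > tol or h in orders:
            return IndexingResult(None, (), float("inf"))
        orders.append(h)
        d_run, _ = _ls_spacing(s[: len(orders)], np.array(orders, dtype=float))
    mult = np.array(orders, dtype=float)
    d, resid = _ls_spacing(s, mult)
    return IndexingResult(d, tuple(orders), resid)


def index_hexagonal(peaks: PeakList, tol: float = RATIO_TOL) -> IndexingResult:
    """Fit the 2D hexagonal lattice law s_hk = sqrt(h^2+hk+k^2)/d10.

    Peaks are matched greedily against the (10), (11), (20), (21)
    reflections using a running least-squares estimate of d10 anchored on
    the first peak; requires at least two peaks.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two peaks for hexagonal indexing")
    s = peaks.s_values
    d_run = 1.0 / s[0]
    ratios = sorted(HEX_RATIOS.items(), key=lambda kv: kv[1])
    indices: list[tuple[int, int]] = []
    mult: list[float] = []
    for sv in s:
        best = min(ratios, key=lambda kv: abs(sv - kv[1] / d_run))
        hk, r = best
        d_hk = r / sv
        if abs(d_hk - d_run) / d_run > tol or hk in indices:
            return IndexingResult(None, (), float("inf"))
        indices.append(hk)
        mult.append(r)
        d_run, _ = _ls_spacing(s[: len(mult)], np.array(mult))
    d10_fit, resid = _ls_spacing(s, np.array(mult))
    return IndexingResult(d10_fit, tuple(indices), resid)


def classify_phase_saxd(peaks: PeakList, tol: float = RATIO_TOL) -> PhaseAssignment:
    """Classify a SAXD peak set as lamellar, hexagonal_II, or indeterminate.

    Both lattice laws are fit; the one with the smaller residual wins,
    provided its assignment is consistent at ``tol``. A single peak (or two
    peaks in the degenerate 1 : 1/2 ratio, which both lattices explain) is
    resolved toward the lamellar law only when the hexagonal fit fails.
    """
    if len(peaks) < 2:
        return PhaseAssignment(phase="indeterminate", evidence=[])
    lam = index_lamellar(peaks, tol)
    hexa = index_hexagonal(peaks, tol)
    if lam.d is None and hexa.d is None:
        return PhaseAssignment(phase="indeterminate", evidence=[])
    if hexa.d is None or (lam.d is not None and lam.residual <= hexa.residual):
        ratios = "/".join(f"{x:.3f}" for x in peaks.d_values / peaks.d_values[0])
        return PhaseAssignment(
            phase="lamellar",
            evidence=[f"d ratios {ratios} match 1:1/2:1/3 law, orders {lam.orders},"
                      f" rms residual {lam.residual:.2e} 1/A"],
        )
    ratios = "/".join(f"{x:.3f}" for x in peaks.d_values / peaks.d_values[0])
    return PhaseAssignment(
        phase="hexagonal_II",
        evidence=[f"d ratios {ratios} match 1:1/sqrt3:1/2:1/sqrt7 law, indices {hexa.orders},"
                  f" rms residual {hexa.residual:.2e} 1/A"],
    )


# ---------------------------------------------------------------------------
# wide-angle packing classification

@dataclass
class WaxdThresholds:
    """Decision thresholds for chain-packing classification (widths in 1/A)."""

    sharp_width: float = 0.006    # FWHM below this counts as a sharp reflection
    broad_width: float = 0.012    # FWHM above this counts as a fluid hump
    shoulder_rel_height: float = 0.08  # min relative prominence for a shoulder
    shoulder_max_sep: float = 0.02     # max s separation peak-to-shoulder


def _shoulder_components(p: DiffractionPattern, thr: WaxdThresholds) -> int:
    """Count merged components via minima of the smoothed second derivative.

    A shoulder that does not form its own maximum still produces a distinct
    negative-curvature lobe; counting those lobes resolves partially merged
    reflections.
    """
    y = p.intensity
    win = max(5, y.size // 60) | 1
    ys = signal.savgol_filter(y, win, 3)
    d2 = signal.savgol_filter(ys, win, 3, deriv=2)
    if d2.min() >= 0:
        return 0
    neg_idx, _ = signal.find_peaks(-d2, prominence=thr.shoulder_rel_height * (-d2.min()))
    # keep lobes where intensity is substantial
    neg_idx = [i for i in neg_idx if ys[i] > 0.2 * ys.max()]
    return len(neg_idx)


def classify_packing_waxd(p: DiffractionPattern,
                          thresholds: WaxdThresholds | None = None) -> str:
    """Classify chain packing from the wide-angle pattern.

    * sharp reflection plus a resolvable shoulder -> ``L_beta_prime``
      (tilted pseudohexagonal gel);
    * a single sharp symmetric reflection -> ``L_beta_or_P_beta_prime``;
    * only a broad hump -> ``fluid``;
    * anything else -> ``unknown``.
    """
    if p.region != "WAXD":
        raise ValueError("expected a WAXD-region pattern")
    thr = thresholds or WaxdThresholds()
    # smooth lightly first: point noise on a broad fluid hump otherwise
    # reads as spurious sharp reflections
    win = max(5, p.intensity.size // 100) | 1
    smoothed = DiffractionPattern(
        s=p.s, intensity=np.clip(signal.savgol_filter(p.intensity, win, 3), 0.0, None),
        region="WAXD")
    peaks = pick_peaks(smoothed, 0.10 * np.ptp(smoothed.intensity))
    sharp = [pk for pk in peaks if pk.width <= thr.sharp_width]
    broad = [pk for pk in peaks if pk.width >= thr.broad_width]
    if sharp:
        others = [pk for pk in peaks if pk is not sharp[0]]
        if any(abs(pk.s_peak - sharp[0].s_peak) <= thr.shoulder_max_sep for pk in others):
            return "L_beta_prime"
        if _shoulder_components(smoothed, thr) >= 2:
            return "L_beta_prime"
        return "L_beta_or_P_beta_prime"
    if broad or (len(peaks) and not sharp):
        return "fluid"
    return "unknown"


# ---------------------------------------------------------------------------
# model fitting and derived thicknesses

class Thicknesses(NamedTuple):
    dHH: float
    dB: float
    dw: float


def derive_thickness(d: float, zH: float, sigmaH: float) -> Thicknesses:
    """Derived bilayer thicknesses: dHH = 2 zH, dB = 2 (zH + 2 sigmaH), dw = d - dB.

    Raises :class:`NegativeWaterError` when the bilayer fills (or exceeds)
    the repeat distance, leaving no water layer.
    """
    if d <= 0 or zH <= 0 or sigmaH <= 0:
        raise ValueError("d, zH and sigmaH must all be positive")
    dHH = 2.0 * zH
    dB = 2.0 * (zH + 2.0 * sigmaH)
    dw = d - dB
    if dw <= 0:
        raise NegativeWaterError(f"dB = {dB:g} A >= d = {d:g} A leaves no water layer")
    return Thicknesses(dHH=dHH, dB=dB, dw=dw)


def fit_saxs(p: DiffractionPattern, init: LamellarModelParams,
             n_starts: int = 4, seed: int = 0,
             fit_background: bool = False) -> LamellarFit:
    """Fit the Gaussian electron-density multilamellar model to a pattern.

    Nonlinear least squares over (d, zH, sigmaH, sigmaC, rho_ratio, eta,
    scale) with the stack size fixed at ``init.n_lamellae``; the first start
    uses ``init`` as-is and subsequent starts perturb it multiplicatively.
    The overall scale is profiled out analytically at each start. Residuals
    are computed on sqrt-intensity so Bragg peaks do not completely swamp
    the diffuse scatter.
    """
    init.validate()
    s, y = p.s, p.intensity
    sqrt_y = np.sqrt(np.clip(y, 0.0, None))
    rng = np.random.default_rng(seed)
    n_lam = init.n_lamellae

    def unpack(x):
        d, zH, sigmaH, sigmaC, rho, eta = x[:6]
        bg = x[6] if fit_background else 0.0
        return d, zH, sigmaH, sigmaC, rho, eta, bg

    def resid(x):
        d, zH, sigmaH, sigmaC, rho, eta, bg = unpack(x)
        model = model_intensity(s, d, zH, sigmaH, sigmaC, rho, n_lam, eta)
        denom = float(np.dot(model, model))
        scale = float(np.dot(model, y)) / denom if denom > 0 else 0.0
        scale = max(scale, 0.0)
        return np.sqrt(np.clip(scale * model + bg, 0.0, None)) - sqrt_y

    x0_base = [init.d, init.zH, init.sigmaH, init.sigmaC, init.rho_ratio, max(init.eta, 1e-6)]
    lo = [init.d * 0.8, 1.0, 0.3, 0.3, -10.0, 0.0]
    hi = [init.d * 1.2, init.d / 2, 15.0, 15.0, -1e-3, 2.0]
    if fit_background:
        x0_base.append(0.0)
        lo.append(-np.inf)
        hi.append(np.inf)

    best = None
    for k in range(n_starts):
        x0 = np.array(x0_base, dtype=float)
        if k > 0:
            x0[:4] *= rng.uniform(0.95, 1.05, size=4)
            x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("SAXS fit failed to converge from every start",
                              diagnostics={"n_starts": n_starts})

    d, zH, sigmaH, sigmaC, rho, eta, bg = unpack(best.x)
    model = model_intensity(s, d, zH, sigmaH, sigmaC, rho, n_lam, eta)
    scale = float(np.dot(model, y) / np.dot(model, model))
    rel_resid = float(np.linalg.norm(scale * model + bg - y) / np.linalg.norm(y))
    t = derive_thickness(d, zH, sigmaH)
    return LamellarFit(d=d, zH=zH, sigmaH=sigmaH, sigmaC=sigmaC,
                       dHH=t.dHH, dB=t.dB, dw=t.dw, fit_residual=rel_resid,
                       rho_ratio=rho, eta=eta, scale=scale)
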
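"""DSC thermogram analysis: baseline subtraction, transition extraction,
pretransition detection, and partial phase diagrams with an immiscibility
plateau test.

Onset and end temperatures of each endotherm are located by intersecting
the steepest leading and trailing tangents with the zero baseline — the
conventional calorimetric construction — and the transition enthalpy is
the trapezoid integral of the baseline-subtracted trace between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional
import warnings as _warnings

import numpy as np
from scipy import signal, stats

from .errors import InsufficientBaselineError, InvalidInputError
from .types import PhaseDiagramPoint, Thermogram, TransitionParams


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of first differences.

    Differencing removes slowly varying structure (baseline, peaks) so the
    MAD estimates the point noise; the 1.4826/sqrt(2) factor calibrates to
    the Gaussian standard deviation.
    """
    d = np.diff(np.asarray(x, dtype=float))
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def subtract_baseline(t: Thermogram,
                      exclusion_windows: list[tuple[float, float]] | None = None,
                      degree: int = 1) -> Thermogram:
    """Subtract a polynomial baseline fitted outside the exclusion windows.

    Points inside the windows (the transition regions) are excluded from
    the fit, so the baseline under each peak is the fitted polynomial's
    interpolation, never biased by peak intensity.
    """
    exclusion_windows = exclusion_windows or []
    temp, cp = t.temperature, t.cp
    for lo, hi in exclusion_windows:
        if hi <= lo:
            raise InvalidInputError(f"bad exclusion window ({lo}, {hi})")
    mask = np.ones(temp.size, dtype=bool)
    for lo, hi in exclusion_windows:
        mask &= ~((temp >= lo) & (temp <= hi))
    if mask.sum() < max(degree + 1, int(0.1 * temp.size)):
        raise InsufficientBaselineError(
            f"exclusion windows leave {mask.sum()}/{temp.size} points for the baseline"
        )
    coef = np.polynomial.polynomial.polyfit(temp[mask], cp[mask], degree)
    baseline = np.polynomial.polynomial.polyval(temp, coef)
    return Thermogram(temperature=temp, cp=cp - baseline, scan_rate=t.scan_rate)


def _tangent_zero_crossing(temp: np.ndarray, cp: np.ndarray, i_apex: int,
                           i_lo: int, i_hi: int, side: str) -> float:
    """Temperature where the steepest tangent on one flank crosses cp = 0."""
    dcp = np.gradient(cp, temp)
    if side == "leading":
        flank = slice(i_lo, i_apex + 1)
        j = i_lo + int(np.argmax(dcp[flank]))
    else:
        flank = slice(i_apex, i_hi + 1)
        j = i_apex + int(np.argmin(dcp[flank]))
    slope = dcp[j]
    if slope == 0:
        return float(temp[j])
    t0 = temp[j] - cp[j] / slope
    # clamp to the flank so pathological slopes cannot escape the peak
    lo, hi = temp[i_lo], temp[i_hi]
    return float(min(max(t0, lo), hi))


def find_transitions(t: Thermogram,
                     min_prominence: Optional[float] = None) -> list[TransitionParams]:
    """Detect endotherms on a baseline-subtracted thermogram.

    ``min_prominence`` defaults to 5x the robust noise estimate. Returns an
    empty list (not an error) when nothing clears the threshold.
    """
    temp, cp = t.temperature, t.cp
    if min_prominence is None:
        noise = robust_noise_sd(cp)
        min_prominence = 5.0 * noise if noise > 0 else 0.02 * max(cp.max(), 1e-12)
    # real endotherms span many grid points and rise above the baseline;
    # the width floor and height requirement reject noise maxima whose
    # peak-to-valley prominence alone can reach ~7 sigma on a long trace
    idx, props = signal.find_peaks(cp, prominence=min_prominence,
                                   height=min_prominence, width=3)
    if idx.size == 0:
        return []
    widths, _, _, _ = signal.peak_widths(cp, idx, rel_height=0.5)
    step = t.t_step
    bases_lo = props["left_bases"]
    bases_hi = props["right_bases"]
    out = []
    for k, i in enumerate(idx):
        # integration support: the peak's prominence bases, cut at the
        # midpoint toward any neighboring peak so disjoint transitions
        # integrate additively
        i_lo, i_hi = int(bases_lo[k]), int(bases_hi[k])
        if k > 0:
            i_lo = max(i_lo, (int(idx[k - 1]) + i) // 2)
        if k < idx.size - 1:
            i_hi = min(i_hi, (i + int(idx[k + 1])) // 2)
        t_on = _tangent_zero_crossing(temp, cp, i, i_lo, i_hi, "leading")
        t_end = _tangent_zero_crossing(temp, cp, i, i_lo, i_hi, "trailing")
        t_max = float(temp[i])
        t_on = min(t_on, t_max)
        t_end = max(t_end, t_max)
        # dH over the full peak support (the tangent bracket systematically
        # clips ~9% of a cooperative endotherm's tails); the unclipped trace
        # lets baseline noise average out instead of rectifying upward
        dh = float(np.trapezoid(cp[i_lo:i_hi + 1], temp[i_lo:i_hi + 1]))
        out.append(TransitionParams(t_onset=t_on, t_end=t_end, t_max=t_max,
                                    dH=max(dh, 0.0), fwhm=float(widths[k] * step)))
    return sorted(out, key=lambda tr: tr.t_max)


def detect_pretransition(transitions: list[TransitionParams], main_index: int,
                         max_fraction: float = 0.5) -> bool:
    """True iff a minor endotherm precedes the main transition.

    Minor means dH below ``max_fraction`` of the main transition's dH.
    """
    if not 0 <= main_index < len(transitions):
        raise IndexError(f"main_index {main_index} out of range")
    main = transitions[main_index]
    return any(tr.t_max < main.t_max and tr.dH < max_fraction * main.dH
               for tr in transitions[:main_index])


# ---------------------------------------------------------------------------
# phase diagram assembly

def mole_fraction(molar_ratio: float) -> float:
    """Additive mole fraction x = 1/(1+R) for a lipid:additive ratio R:1."""
    if molar_ratio <= 0:
        raise ValueError("molar ratio must be positive")
    return 1.0 / (1.0 + molar_ratio)


class PhaseDiagram(NamedTuple):
    points: list[PhaseDiagramPoint]
    immiscibility_flag: bool
    plateau_start: Optional[float]  # mole fraction where the plateau begins


def _plateau_breakpoint(x: np.ndarray, y: np.ndarray,
                        slope_p: float = 0.05) -> Optional[int]:
    """Index where a two-segment piecewise-linear fit turns flat, or None.

    Scans candidate breakpoints, fits a line to each segment, and accepts
    the best split when the second segment's slope is statistically
    indistinguishable from zero (t-test p >= ``slope_p``) while the first
    segment's is not.
    """
    n = x.size
    if n < 4:
        return None
    best_k, best_sse = None, np.inf
    for k in range(1, n - 2):
        sse = 0.0
        for seg in (slice(0, k + 1), slice(k, n)):
            res = stats.linregress(x[seg], y[seg])
            sse += float(np.sum((y[seg] - res.intercept - res.slope * x[seg]) ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    if best_k is None:
        return None
    left = stats.linregress(x[: best_k + 1], y[: best_k + 1])
    right = stats.linregress(x[best_k:], y[best_k:])
    right_flat = np.isnan(right.pvalue) or right.pvalue >= slope_p
    left_sloped = not np.isnan(left.pvalue) and left.pvalue < slope_p
    # degenerate exact-plateau data produce zero-variance segments
    if np.allclose(y[best_k:], y[best_k]) and not np.allclose(y, y[0]):
        return best_k
    return best_k if (right_flat and left_sloped) else None


def build_phase_diagram(rows: list[tuple[float, TransitionParams]],
                        transition_label: str = "main",
                        slope_p: float = 0.05) -> PhaseDiagram:
    """Assemble a partial phase diagram and test for fluid immiscibility.

    ``rows`` holds ``(molar_ratio, TransitionParams)`` pairs, one per
    composition (lipid:additive ratio R meaning R:1; use ``np.inf`` for the
    pure lipid). Duplicate compositions are averaged with a warning. The
    immiscibility flag is raised when both onset and end temperatures
    plateau beyond some composition; the plateau start is that composition.
    """
    if len(rows) < 3:
        raise InvalidInputError("need at least 3 compositions")
    by_x: dict[float, list[TransitionParams]] = {}
    for ratio, tr in rows:
        x = 0.0 if np.isinf(ratio) else mole_fraction(ratio)
        by_x.setdefault(round(x, 12), []).append(tr)
    points = []
    for x in sorted(by_x):
        trs = by_x[x]
        if len(trs) > 1:
            _warnings.warn(f"duplicate composition x={x:g}: averaging {len(trs)} rows",
                           stacklevel=2)
        points.append(PhaseDiagramPoint(
            mole_fraction_additive=x,
            t_onset=float(np.mean([tr.t_onset for tr in trs])),
            t_end=float(np.mean([tr.t_end for tr in trs])),
            transition_label=transition_label,
        ))
    xs = np.array([p.mole_fraction_additive for p in points])
    onset = np.array([p.t_onset for p in points])
    end = np.array([p.t_end for p in points])
    k_on = _plateau_breakpoint(xs, onset, slope_p)
    k_end = _plateau_breakpoint(xs, end, slope_p)
    if k_on is not None and k_end is not None:
        k = max(k_on, k_end)
        return PhaseDiagram(points, True, float(xs[k]))
    return PhaseDiagram(points, False, None)
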
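"""Trajectory analysis: per-group mass density profiles along the bilayer
normal and inter-group contact counts under the minimum-image convention.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .errors import InvalidInputError, MissingGroupError
from .types import ContactCounts, CrossRelaxationProfile, DensityProfile, GroupTrajectory

#: Conversion from Da/nm^3 to kg/m^3 (1 Da = 1.66053906660e-27 kg; 1 nm^3 = 1e-27 m^3).
DA_PER_NM3_TO_KG_M3 = 1.66053906660


def center_frames(t: GroupTrajectory, reference_group: str) -> GroupTrajectory:
    """Shift each frame so the reference group's z center of mass is 0.

    x and y are untouched; z is re-wrapped into ``[-Lz/2, Lz/2)``. Raises
    :class:`MissingGroupError` naming the first frame lacking the group.
    """
    lz = t.box[2]
    frames = []
    for i, fr in enumerate(t.frames):
        if reference_group not in fr:
            raise MissingGroupError(reference_group, i)
        ref = fr[reference_group]
        m = t.masses[reference_group]
        com_z = float(np.average(ref[:, 2], weights=m))
        new = {}
        for g, xyz in fr.items():
            shifted = xyz.copy()
            shifted[:, 2] = (shifted[:, 2] - com_z + lz / 2.0) % lz - lz / 2.0
            new[g] = shifted
        frames.append(new)
    return GroupTrajectory(frames=frames, masses=t.masses, box=t.box)


def mass_density_profile(t: GroupTrajectory, groups: Optional[list[str]] = None,
                         bin_width: float = 0.1) -> DensityProfile:
    """Frame-averaged mass density (kg/m^3) per z-bin for each group.

    Assumes a centered trajectory: bins tile ``[-Lz/2, Lz/2)``. The sum of
    density times bin volume recovers each group's total mass per frame
    exactly (up to the Da -> kg unit conversion).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lx, ly, lz = t.box
    if lx * ly <= 0:
        raise InvalidInputError("zero box cross-section")
    groups = groups if groups is not None else t.group_labels
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    actual_width = edges[1] - edges[0]
    bin_vol = lx * ly * actual_width  # nm^3

    density = {}
    for g in groups:
        acc = np.zeros(n_bins)
        for fr in t.frames:
            z = (fr[g][:, 2] + lz / 2.0) % lz - lz / 2.0
            hist, _ = np.histogram(z, bins=edges, weights=t.masses[g])
            acc += hist
        density[g] = acc / t.n_frames / bin_vol * DA_PER_NM3_TO_KG_M3
    return DensityProfile(z_bins=centers, density=density, bin_width=actual_width)


def _min_image_pair_count(a: np.ndarray, b: np.ndarray,
                          box: tuple[float, float, float], cutoff: float) -> int:
    delta = a[:, None, :] - b[None, :, :]
    for dim in range(3):
        delta[:, :, dim] -= box[dim] * np.round(delta[:, :, dim] / box[dim])
    dist2 = np.einsum("ijk,ijk->ij", delta, delta)
    return int(np.count_nonzero(dist2 < cutoff * cutoff))


def count_contacts(t: GroupTrajectory, groupA: str, groupB: str,
                   cutoff: float = 0.5) -> ContactCounts:
    """Mean number of inter-group atom pairs within ``cutoff`` nm per frame.

    Distances use the minimum-image convention in all three dimensions.
    The two groups must be disjoint atom sets (distinct labels here).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if groupA == groupB:
        raise InvalidInputError("contact groups must be disjoint atom sets")
    total = 0
    for fr in t.frames:
        total += _min_image_pair_count(fr[groupA], fr[groupB], t.box, cutoff)
    mean = total / t.n_frames
    counts = {(groupA, groupB): mean, (groupB, groupA): mean}
    return ContactCounts(cutoff=cutoff, counts=counts, n_frames=t.n_frames)


class ConcordanceResult(NamedTuple):
    correlations: dict[str, float]   # per ligand group, Spearman rho
    insufficient: dict[str, bool]    # True when < 3 shared lipid groups


def _profile_overlap(p1: np.ndarray, p2: np.ndarray, dz: float) -> float:
    """Overlap of two unit-normalized profiles: integral of their pointwise min."""
    a1, a2 = p1.sum() * dz, p2.sum() * dz
    if a1 <= 0 or a2 <= 0:
        return 0.0
    return float(np.minimum(p1 / a1, p2 / a2).sum() * dz)


def profile_noesy_concordance(dp: DensityProfile, cp: CrossRelaxationProfile,
                              ) -> ConcordanceResult:
    """Rank-correlate NOESY rates with density-profile overlaps per ligand.

    For each ligand group present in both inputs, lipid groups are ranked
    by cross-relaxation rate and by the overlap integral (of pointwise
    minima of unit-normalized profiles) with the ligand's own density
    profile; the Spearman correlation of the two rankings is reported.
    Ligands sharing fewer than 3 lipid groups get an insufficient-data
    flag instead of a correlation.
    """
    dz = dp.bin_width
    per_ligand: dict[str, dict[str, float]] = {}
    for (lig, lip), r in cp.rates.items():
        per_ligand.setdefault(lig, {})[lip] = r

    correlations, insufficient = {}, {}
    for lig, by_group in per_ligand.items():
        if lig not in dp.density:
            insufficient[lig] = True
            continue
        shared = [g for g in by_group if g in dp.density]
        if len(shared) < 3:
            insufficient[lig] = True
            continue
        sig = np.array([by_group[g] for g in shared])
        ovl = np.array([_profile_overlap(dp.density[lig], dp.density[g], dz)
                        for g in shared])
        rho = stats.spearmanr(sig, ovl).statistic
        correlations[lig] = float(rho)
        insufficient[lig] = False
    return ConcordanceResult(correlations=correlations, insufficient=insufficient)
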
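"""Synthetic NMR inputs: NOESY volume tables and 31P powder spectra."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidInputError
from ..types import DepthDistribution, NoesyVolumeTable, Spectrum31P


def gaussian_overlap(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Overlap integral of two unit Gaussians, int N1(z) N2(z) dz (1/nm).

    Closed form: a Gaussian in the mean difference with combined variance
    sd1^2 + sd2^2. Monotone decreasing in |mu1 - mu2| for fixed widths.
    """
    var = sd1 * sd1 + sd2 * sd2
    return float(np.exp(-0.5 * (mu1 - mu2) ** 2 / var) / np.sqrt(2.0 * np.pi * var))


def gen_noesy_table(
    depth: DepthDistribution,
    ligand_groups: list[str],
    tm: float,
    scale: float = 1000.0,
    seed: int = 0,
    noise_frac: float = 0.0,
) -> NoesyVolumeTable:
    """Generate a NOESY volume table from a depth distribution.

    The cross-peak volume between ligand proton i and lipid group j is
    ``scale * tm * n_i * n_j * overlap(i, j)`` where overlap is the Gaussian
    overlap integral of their depth distributions; diagonal volumes are
    ``scale * n_j``. This is a monotone contact-to-volume map, not a
    relaxation-matrix simulation: downstream rates A_ij / (A_jj * tm)
    reduce to n_i * overlap(i, j), so per-ligand rankings follow overlap.

    ``ligand_groups`` selects which labels of ``depth`` act as ligand
    protons; every other label is treated as a lipid group. Multiplicative
    lognormal noise of fractional sd ``noise_frac`` perturbs cross peaks.
    """
    if not ligand_groups:
        raise InvalidInputError("ligand group list is empty")
    labels = depth.labels
    for g in ligand_groups:
        if g not in labels:
            raise InvalidInputError(f"ligand group {g!r} not in depth distribution")
    lipid_groups = [g for g in labels if g not in ligand_groups]
    if not lipid_groups:
        raise InvalidInputError("no lipid groups remain after removing ligand groups")
    if tm <= 0:
        raise InvalidInputError("mixing time must be positive")

    rng = np.random.default_rng(seed)
    diagonal = {g.label: scale * max(g.n_atoms, 1) for g in depth}
    cross: dict[tuple[str, str], float] = {}
    for lig in ligand_groups:
        gi = depth.get(lig)
        for lip in lipid_groups:
            gj = depth.get(lip)
            vol = scale * tm * max(gi.n_atoms, 1) * max(gj.n_atoms, 1) * gaussian_overlap(
                gi.mean_z, gi.sd_z, gj.mean_z, gj.sd_z
            )
            if noise_frac > 0:
                vol *= float(rng.lognormal(0.0, noise_frac))
            cross[(lig, lip)] = vol
    return NoesyVolumeTable(tm=tm, diagonal=diagonal, cross=cross)


def gen_31p_spectrum(
    delta_sigma: float,
    phase: str = "lamellar",
    lb: float = 100.0,
    field_MHz: float = 242.9,
    seed: int = 0,
    noise_sd: float = 0.0,
    ppm_window: tuple[float, float] | None = None,
    n_points: int = 2048,
) -> Spectrum31P:
    """Generate a noisy 31P powder spectrum for a given phase.

    Delegates the (deterministic) lineshape to
    :func:`bilayerlab.nmr.simulate_31p_lineshape` and adds Gaussian noise.
    ``delta_sigma`` is the residual chemical-shielding anisotropy in ppm
    (negative for a bilayer); the hexagonal lineshape is the lamellar
    construction evaluated at -delta_sigma/2.
    """
    from ..nmr import simulate_31p_lineshape

    sp = simulate_31p_lineshape(
        delta_sigma, phase, lb=lb, field_MHz=field_MHz,
        ppm_window=ppm_window, n_points=n_points,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = sp.intensity + rng.normal(0.0, noise_sd * sp.intensity.max(), sp.ppm.size)
        sp = Spectrum31P(ppm=sp.ppm, intensity=noisy)
    return sp
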
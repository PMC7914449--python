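"""Shared domain types.

Unit conventions (fixed across the package):

* temperatures in degrees Celsius at all interfaces (kelvin only inside
  thermodynamic formulas);
* scattering vector ``s = 2 sin(theta)/lambda = 1/d`` in 1/Angstrom — no
  factor of 2*pi — and all diffraction lengths in Angstrom;
* trajectory coordinates and box lengths in nm, masses in Da;
* NMR axes in ppm with low field mapped to larger ppm (left of spectrum);
* NOESY mixing time in seconds, cross-relaxation rates in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Lipid proton groups ordered from the membrane center to the polar group.
LIPID_GROUP_ORDER: tuple[str, ...] = (
    "CH3", "(CH2)n", "CH2C=", "C3", "C2", "G1", "gamma",
)


# ---------------------------------------------------------------------------
# calorimetry

@dataclass
class Thermogram:
    """Temperature-indexed excess heat capacity trace.

    ``temperature`` is a strictly increasing grid in degC, ``cp`` the heat
    capacity in kcal/mol/degC, with the scan rate kept as metadata.
    """

    temperature: np.ndarray
    cp: np.ndarray
    scan_rate: float = 1.0

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature.shape != self.cp.shape:
            raise ValueError("temperature and cp must have equal length")
        if self.temperature.size < 10:
            raise ValueError("thermogram needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    @property
    def t_step(self) -> float:
        return float(np.median(np.diff(self.temperature)))


@dataclass
class ThermogramParams:
    """Generator parameters for a synthetic thermogram.

    ``transitions`` holds ``(Tm_degC, dH_kcal_mol, dHvH_kcal_mol)`` triples;
    the van't Hoff enthalpy sets the cooperativity (peak sharpness) and must
    be at least the calorimetric one.
    """

    transitions: list[tuple[float, float, float]]
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    noise_sd: float = 0.0
    t_range: tuple[float, float] = (10.0, 40.0)
    t_step: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for tm, dh, dhvh in self.transitions:
            if dh <= 0:
                raise ValueError(f"dH must be positive, got {dh}")
            if dhvh < dh:
                raise ValueError("van't Hoff enthalpy must be >= calorimetric dH")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        tms = [t[0] for t in self.transitions]
        if tms != sorted(tms):
            raise ValueError("transitions must be sorted by Tm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TransitionParams:
    """Parameters of one detected endotherm."""

    t_onset: float
    t_end: float
    t_max: float
    dH: float
    fwhm: float

    def __post_init__(self):
        if not (self.t_onset <= self.t_max <= self.t_end):
            raise ValueError("require t_onset <= t_max <= t_end")
        if self.dH < 0:
            raise ValueError("dH must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass
class PhaseDiagramPoint:
    mole_fraction_additive: float
    t_onset: float
    t_end: float
    transition_label: str = "main"

    def __post_init__(self):
        if not 0 <= self.mole_fraction_additive < 1:
            raise ValueError("mole fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# diffraction

@dataclass
class DiffractionPattern:
    """Scattering-vector-indexed intensity trace.

    ``region`` tags the angular window: ``"SAXD"`` (~0.0075-0.07 1/A) or
    ``"WAXD"`` (~0.20-0.29 1/A).
    """

    s: np.ndarray
    intensity: np.ndarray
    region: str = "SAXD"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be strictly increasing")
        if np.any(self.s <= 0):
            raise ValueError("s must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.region not in ("SAXD", "WAXD"):
            raise ValueError("region must be 'SAXD' or 'WAXD'")


@dataclass
class Peak:
    s_peak: float
    d: float
    height: float
    width: float


@dataclass
class PeakList:
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.s_peak)
        for p in self.peaks:
            if p.d <= 0:
                raise ValueError("peak d-spacing must be positive")

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def s_values(self) -> np.ndarray:
        return np.array([p.s_peak for p in self.peaks])

    @property
    def d_values(self) -> np.ndarray:
        return np.array([p.d for p in self.peaks])


@dataclass
class LamellarModelParams:
    """Parameters of the symmetric Gaussian electron-density bilayer model.

    Two positive headgroup Gaussians at +/- ``zH`` (width ``sigmaH``) and a
    negative methyl-trough Gaussian at the origin (width ``sigmaC``,
    relative amplitude ``rho_ratio`` < 0); ``n_lamellae`` and the disorder
    parameter ``eta`` control the interference function of the stack.
    """

    d: float
    zH: float
    sigmaH: float
    sigmaC: float
    rho_ratio: float = -1.0
    n_lamellae: int = 25
    eta: float = 0.0

    def validate(self) -> None:
        if not 0 < self.zH < self.d / 2:
            raise ValueError("require 0 < zH < d/2")
        if self.sigmaH <= 0 or self.sigmaC <= 0:
            raise ValueError("Gaussian widths must be positive")
        if self.n_lamellae < 1:
            raise ValueError("n_lamellae must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class LamellarFit:
    """Fitted electron-density model parameters plus derived thicknesses."""

    d: float
    zH: float
    sigmaH: float
    sigmaC: float
    dHH: float
    dB: float
    dw: float
    fit_residual: float
    rho_ratio: float = -1.0
    eta: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if abs(self.dHH - 2 * self.zH) > 1e-9:
            raise ValueError("dHH must equal 2*zH")
        if abs(self.dB - 2 * (self.zH + 2 * self.sigmaH)) > 1e-9:
            raise ValueError("dB must equal 2*(zH + 2*sigmaH)")
        if abs(self.dw - (self.d - self.dB)) > 1e-9:
            raise ValueError("dw must equal d - dB")
        if self.dw <= 0:
            raise ValueError("dw must be positive")


@dataclass
class PhaseAssignment:
    phase: str  # lamellar | hexagonal_II | indeterminate
    packing: str = "unknown"  # L_beta_prime | L_beta_or_P_beta_prime | fluid | unknown
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.phase not in ("lamellar", "hexagonal_II", "indeterminate"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase != "indeterminate" and not self.evidence:
            raise ValueError("evidence required for a definite phase assignment")


# ---------------------------------------------------------------------------
# NMR

@dataclass
class Spectrum31P:
    """31P spectrum on a ppm grid stored left-to-right (decreasing ppm)."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        if np.any(np.diff(self.ppm) >= 0):
            raise ValueError("ppm axis must be strictly decreasing (low field left)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class NoesyVolumeTable:
    """Diagonal and cross-peak NOESY volumes at one mixing time.

    ``diagonal`` maps a group label to its diagonal volume; ``cross`` maps
    ``(ligand_proton, lipid_group)`` pairs to cross-peak volumes.
    """

    tm: float
    diagonal: dict[str, float]
    cross: dict[tuple[str, str], float]

    def __post_init__(self):
        if self.tm <= 0:
            raise ValueError("mixing time must be positive")
        for g, v in self.diagonal.items():
            if v <= 0:
                raise ValueError(f"diagonal volume for {g!r} must be positive")
        for pair, v in self.cross.items():
            if v < 0:
                raise ValueError(f"cross volume for {pair!r} must be >= 0")

    @property
    def ligand_protons(self) -> list[str]:
        seen: dict[str, None] = {}
        for lig, _ in self.cross:
            seen.setdefault(lig, None)
        return list(seen)

    @property
    def lipid_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, lip in self.cross:
            seen.setdefault(lip, None)
        return list(seen)


@dataclass
class CrossRelaxationProfile:
    """Cross-relaxation rates per (ligand proton, lipid group) pair."""

    rates: dict[tuple[str, str], float]
    lipid_group_order: tuple[str, ...] = LIPID_GROUP_ORDER

    def __post_init__(self):
        for pair, r in self.rates.items():
            if r < 0:
                raise ValueError(f"rate for {pair!r} must be >= 0")


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class DepthGroup:
    label: str
    mean_z: float
    sd_z: float
    n_atoms: int
    atom_mass: float

    def __post_init__(self):
        if self.sd_z <= 0:
            raise ValueError("sd_z must be positive")
        if self.n_atoms < 0:
            raise ValueError("n_atoms must be >= 0")
        if self.atom_mass <= 0:
            raise ValueError("atom_mass must be positive")


@dataclass
class DepthDistribution:
    """Per-group Gaussian depth distributions along the bilayer normal (nm)."""

    groups: list[DepthGroup]

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be unique")

    def __iter__(self):
        return iter(self.groups)

    def get(self, label: str) -> DepthGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]


@dataclass
class GroupTrajectory:
    """Frames of grouped, labeled coordinates in a periodic rectangular box.

    Each frame maps a group label to an ``(n, 3)`` coordinate array (nm);
    ``masses`` maps a label to the per-atom mass array (Da). Atom counts per
    group are constant across frames.
    """

    frames: list[dict[str, np.ndarray]]
    masses: dict[str, np.ndarray]
    box: tuple[float, float, float]

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        counts = {g: arr.shape[0] for g, arr in self.frames[0].items()}
        for i, fr in enumerate(self.frames):
            if {g: a.shape[0] for g, a in fr.items()} != counts:
                raise ValueError(f"atom counts differ at frame {i}")
        for g, m in self.masses.items():
            if g in counts and len(m) != counts[g]:
                raise ValueError(f"mass array length mismatch for group {g!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def group_labels(self) -> list[str]:
        return list(self.frames[0].keys())


@dataclass
class DensityProfile:
    """Mass density (kg/m^3) per z-bin for each group; bin centers in nm."""

    z_bins: np.ndarray
    density: dict[str, np.ndarray]
    bin_width: float = 0.1

    def __post_init__(self):
        self.z_bins = np.asarray(self.z_bins, dtype=float)
        for g, rho in self.density.items():
            rho = np.asarray(rho, dtype=float)
            if rho.shape != self.z_bins.shape:
                raise ValueError(f"density shape mismatch for group {g!r}")
            if np.any(rho < 0):
                raise ValueError("densities must be >= 0")
            self.density[g] = rho


@dataclass
class ContactCounts:
    """Mean per-frame atom-pair contacts within a cutoff, symmetric in (A, B)."""

    cutoff: float
    counts: dict[tuple[str, str], float]
    n_frames: int

    def get(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.counts else (b, a)
        return self.counts[key]
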
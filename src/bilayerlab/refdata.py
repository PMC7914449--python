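"""Published experimental parameters used as generator inputs and for
printed-arithmetic checks.

These are instrument measurements for DMPC and DEPE multilamellar vesicles
with increasing diethylstilbestrol (DES) content; they are inputs to the
synthetic generators and consistency checks, never outputs of this package.
"""

from __future__ import annotations

from .saxd import derive_thickness

#: Structural parameters of the Gaussian electron-density model for
#: DMPC and DMPC/DES multilamellar stacks (all lengths in Angstrom).
#: sigmaH is not tabulated in the source and is implied via
#: dB = 2*(zH + 2*sigmaH).
STRUCTURAL_ROWS: dict[str, dict[str, float]] = {
    "DMPC (8C)":              {"d": 64.0, "zH": 19.5, "sigmaC": 5.4, "dB": 51.0},
    "DMPC/DES (15:1) (8C)":   {"d": 70.9, "zH": 19.2, "sigmaC": 5.9, "dB": 50.4},
    "DMPC/DES (7:1) (8C)":    {"d": 72.8, "zH": 19.1, "sigmaC": 6.1, "dB": 50.2},
    "DMPC (30C)":             {"d": 64.6, "zH": 18.0, "sigmaC": 6.3, "dB": 48.0},
    "DMPC/DES (15:1) (30C)":  {"d": 65.6, "zH": 17.5, "sigmaC": 6.4, "dB": 47.0},
    "DMPC/DES (7:1) (30C)":   {"d": 66.7, "zH": 17.5, "sigmaC": 6.4, "dB": 47.0},
}

#: Main-transition enthalpies (kcal/mol of phospholipid) versus
#: lipid:DES molar ratio; inf denotes the pure lipid.
DELTA_H_KCAL: dict[str, dict[float, float]] = {
    "DMPC": {
        float("inf"): 6.5812, 60: 6.3835, 30: 6.3749,
        15: 6.2677, 7: 6.198, 3: 5.4762, 1: 4.775,
    },
    "DEPE": {
        float("inf"): 7.1094, 80: 6.8634, 40: 6.5521, 20: 4.5866, 10: 2.1381,
    },
}

#: Observed lamellar d-spacings (Angstrom) for DMPC at three temperatures.
DSPACINGS_A: dict[str, list[float]] = {
    "DMPC (8C)": [64.03, 31.41, 20.40],
    "DMPC (15C)": [72.18, 37.12],
    "DMPC (30C)": [64.55, 32.30],
}

#: Wide-angle chain-packing signatures: (d_A, kind) per condition.
WAXD_FEATURES: dict[str, list[tuple[float, str]]] = {
    "DMPC (8C)": [(4.19, "sharp"), (4.10, "shoulder")],
    "DMPC (15C)": [(4.15, "sharp")],
    "DMPC (30C)": [(4.2, "broad")],
}

#: DEPE transition temperatures (degC): gel-to-fluid and lamellar-to-HII.
DEPE_TRANSITIONS_C = (35.0, 62.0)

#: NOESY mixing time (s) used for cross-relaxation rates.
NOESY_MIXING_TIME_S = 0.3


def implied_sigmaH(row: dict[str, float]) -> float:
    """Headgroup Gaussian width implied by dB = 2*(zH + 2*sigmaH)."""
    return (row["dB"] / 2.0 - row["zH"]) / 2.0


def structural_table() -> dict[str, dict[str, float]]:
    """Full structural table with derived dHH, dB, dw recomputed.

    For each condition the tabulated (d, zH) and the implied sigmaH are run
    through :func:`bilayerlab.saxd.derive_thickness`.
    """
    out = {}
    for label, row in STRUCTURAL_ROWS.items():
        t = derive_thickness(row["d"], row["zH"], implied_sigmaH(row))
        out[label] = {
            "d": row["d"], "zH": row["zH"], "sigmaC": row["sigmaC"],
            "sigmaH": implied_sigmaH(row),
            "dHH": t.dHH, "dB": t.dB, "dw": t.dw,
        }
    return out
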
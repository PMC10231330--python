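"""Physical constants, dipolar interaction strengths and named residue selections.

All coordinates in this package are in Å; nm appears only at reporting
boundaries (PCA projections, SAXS momentum transfer, radii of gyration).
"""

from __future__ import annotations

import numpy as np

# --- physical constants (SI) ---
MU0 = 4.0e-7 * np.pi            # vacuum permeability, T m / A
HBAR = 1.054571817e-34          # reduced Planck constant, J s
GAMMA_H = 2.6752218744e8        # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7116e7             # 15N
GAMMA_C = 6.728284e7            # 13C

GAMMAS = {"H": GAMMA_H, "N": GAMMA_N, "C": GAMMA_C}

# Effective internuclear distances used for the dipolar constants (Å).
# rNH is the vibrationally averaged effective N-H bond length; the two-bond
# H(i)-C'(i-1) distance is by default measured per structure (see
# rdc_analysis), with 2.05 Å as the fixed fallback.
BOND_LENGTHS = {
    "H-N": 1.041,
    "N-C": 1.329,
    "C-CA": 1.525,
    "H-C": 2.05,
}

# coupling type -> (gyromagnetic pair)
COUPLING_NUCLEI = {
    "H-N": ("H", "N"),
    "N-C": ("N", "C"),
    "H-C": ("H", "C"),
    "C-CA": ("C", "C"),
}

COUPLING_TYPES = tuple(COUPLING_NUCLEI)


def dmax(coupling_type: str, r_angstrom: float | None = None) -> float:
    """Static dipolar interaction constant D_max in Hz.

    D(theta) = D_max * <e^T S e> with S the Saupe order matrix and e the
    internuclear unit vector; D_max = -mu0 * gamma_i * gamma_j * hbar /
    (4 pi^2 r^3).  With r in Å.
    """
    if coupling_type not in COUPLING_NUCLEI:
        raise ValueError(f"unknown coupling type: {coupling_type!r}")
    gi, gj = (GAMMAS[n] for n in COUPLING_NUCLEI[coupling_type])
    if r_angstrom is None:
        r_angstrom = BOND_LENGTHS[coupling_type]
    r_m = r_angstrom * 1e-10
    return -MU0 * gi * gj * HBAR / (4.0 * np.pi**2 * r_m**3)


# --- named residue selections (deposited SHP2 numbering, 1-based inclusive) ---
N_SH2_RANGE = (3, 104)
C_SH2_RANGE = (112, 216)
LINKER_RANGE = (105, 111)
PCA_RANGE = (12, 215)       # Thr12..Pro215, flexible termini excluded

# --- approximate atomic masses (Da) for mass-weighted gyration ---
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "P": 30.974}
DEFAULT_MASS = 12.011

# --- per-residue electron counts for the SAXS bead model ---
# Total electrons of the neutral residue (backbone + side chain, no termini).
RESIDUE_ELECTRONS = {
    "GLY": 30, "ALA": 38, "SER": 46, "CYS": 54, "THR": 54,
    "PRO": 52, "VAL": 54, "ASP": 59, "ASN": 60, "ILE": 62,
    "LEU": 62, "MET": 70, "GLU": 67, "GLN": 68, "LYS": 71,
    "HIS": 72, "PHE": 78, "ARG": 85, "TYR": 86, "TRP": 98,
}
DEFAULT_RESIDUE_ELECTRONS = 62  # mean residue, used for pseudo residues

KT_KJ_MOL_300K = 2.494  # kJ/mol at 300 K
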